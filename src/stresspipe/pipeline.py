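"""End-to-end orchestration: sessions -> feature tables -> LOSO results.

Thin glue over the feature-extraction and modelling modules so that the
analysis scripts, the tests and the reproduction script all run the exact
same path.
"""

from __future__ import annotations

import logging

import pandas as pd

from .ecg_hrv import hrv_block_pipeline
from .eeg_features import extract_epoch_features
from .io_core import rows_to_frame
from .stress_model import EvaluationResult, loso_evaluate, sweep_block_counts
from .synthetic_data import GeneratorConfig, SessionData, generate_cohort

log = logging.getLogger("stresspipe")


def session_eeg_features(sess: SessionData, config: dict | None = None) -> pd.DataFrame:
    rows = extract_epoch_features(sess.eeg, sess.manifest, config)
    return rows_to_frame(rows)


def session_hrv_features(sess: SessionData, config: dict | None = None) -> pd.DataFrame:
    feats = hrv_block_pipeline(sess.rr, sess.manifest, sess.rr_times_s, config)
    recs = []
    for f in feats:
        recs.append({
            "participant": sess.participant_id,
            "task": sess.manifest.task.value,
            "block": f.block,
            "low_quality": f.low_quality,
            **f.as_dict(),
        })
    return pd.DataFrame(recs)


def cohort_features(
    sessions: list[SessionData], config: dict | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature tables (EEG epochs, HRV blocks) for a whole cohort."""
    eeg = pd.concat([session_eeg_features(s, config) for s in sessions],
                    ignore_index=True)
    hrv = pd.concat([session_hrv_features(s, config) for s in sessions],
                    ignore_index=True)
    return eeg, hrv


def run_loso(
    config: GeneratorConfig,
    k: int = 2,
    modality: str = "eeg",
    model_config: dict | None = None,
) -> EvaluationResult:
    """Simulate a cohort, extract features, and evaluate with LOSO."""
    sessions = generate_cohort(config)
    if modality == "eeg":
        features = pd.concat(
            [session_eeg_features(s, model_config) for s in sessions],
            ignore_index=True)
    elif modality == "hrv":
        features = pd.concat(
            [session_hrv_features(s, model_config) for s in sessions],
            ignore_index=True)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return loso_evaluate(features, k, modality, model_config)


def run_block_sweep(
    config: GeneratorConfig,
    k_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8),
    modalities: tuple[str, ...] = ("eeg", "hrv"),
    model_config: dict | None = None,
) -> pd.DataFrame:
    """Simulate a cohort and sweep the labelled-block count per modality."""
    sessions = generate_cohort(config)
    eeg, hrv = cohort_features(sessions, model_config)
    tables = []
    for modality in modalities:
        features = eeg if modality == "eeg" else hrv
        tables.append(sweep_block_counts(features, k_values, (modality,),
                                         model_config))
    return pd.concat(tables, ignore_index=True)
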