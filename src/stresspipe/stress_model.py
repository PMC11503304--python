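"""Block-labelled stress classification with LOSO evaluation.

The labeling premise: the opening blocks of a 40 min task session are a
"non-stress" state (label 0) and the closing blocks a "stress" state
(label 1); middle blocks are left unlabelled. A support-vector regressor
(RBF kernel) is fit on per-epoch feature vectors against the 0/1 labels
and produces a continuous stress score; epochs scoring above 0.5 indicate
stress and a block is called "stressed" when more than half of its epochs
indicate stress (an exact tie is "not stressed"). Generalization across
people is measured with leave-one-subject-out cross-validation, and a
sweep over the number of labelled blocks k finds how much of the session
is worth labelling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .ecg_hrv import ULTRA_SHORT_TERM_SUBSET
from .errors import (
    DegenerateTrainingError,
    EmptyBlockError,
    InfeasibleLabelingError,
)
from .io_core import KEY_COLUMNS, default_config

log = logging.getLogger("stresspipe")

LABEL_COLUMN = "stress_label"


@dataclass
class EvaluationResult:
    """LOSO outcome for one (k, modality) setting."""

    per_participant_accuracy: list[float]  # percent, one per participant
    mean_accuracy: float                   # percent
    sem_accuracy: float                    # percent, sd/sqrt(n)
    k_blocks: int
    modality: str
    participants: list[str]

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "k_blocks": self.k_blocks,
            "participants": self.participants,
            "per_participant_accuracy": [round(a, 6) for a in
                                         self.per_participant_accuracy],
            "mean_accuracy": round(self.mean_accuracy, 6),
            "sem_accuracy": round(self.sem_accuracy, 6),
        }


def _session_blocks(df: pd.DataFrame) -> list[int]:
    return sorted(df["block"].unique())


def label_blocks(session: pd.DataFrame, k: int) -> pd.DataFrame:
    """Label the first k blocks 0 and the last k blocks 1.

    ``session`` holds one participant-task feature table (any row
    granularity). Middle blocks get a NaN label and are excluded from
    training; they can still be scored for stress-trajectory plots.
    """
    blocks = _session_blocks(session)
    if 2 * k > len(blocks):
        raise InfeasibleLabelingError(
            f"k={k} needs >= {2 * k} blocks, session has {len(blocks)}"
        )
    lo = set(blocks[:k])
    hi = set(blocks[-k:])
    out = session.copy()
    out[LABEL_COLUMN] = np.where(
        out["block"].isin(lo), 0.0,
        np.where(out["block"].isin(hi), 1.0, np.nan),
    )
    return out


def _pivot_channels(df: pd.DataFrame) -> pd.DataFrame:
    """One row per (participant, block, epoch) with channel-suffixed features.

    The model consumes n_channels x n_features values per epoch; feature
    tables arrive in long form with one row per channel.
    """
    feature_cols = [c for c in df.columns
                    if c not in KEY_COLUMNS and c != LABEL_COLUMN]
    keys = [c for c in ("participant", "task", "block", "epoch") if c in df.columns]
    if LABEL_COLUMN in df.columns:
        keys = keys + [LABEL_COLUMN]
    wide = df.set_index(keys + ["channel"])[feature_cols].unstack("channel")
    wide.columns = [f"{feat}__{ch}" for feat, ch in wide.columns]
    return wide.reset_index()


def select_feature_columns(df: pd.DataFrame, modality: str,
                           config: dict | None = None) -> list[str]:
    """Feature columns entering the model for a modality.

    EEG uses all 15 per-channel features by default (config can restrict
    to absolute or relative powers); HRV uses the ultra-short-term subset
    {sdnn, rmssd, pnni_50, mean_hr} unless config overrides it.
    """
    cfg = default_config()
    if config:
        cfg.update(config)
    exclude = set(KEY_COLUMNS) | {LABEL_COLUMN}
    cols = [c for c in df.columns if c not in exclude
            and pd.api.types.is_numeric_dtype(df[c])]
    if modality == "hrv":
        subset = list(cfg["hrv_feature_subset"])
        chosen = [c for c in cols if c.split("__")[0] in subset]
        return chosen or cols
    mode = cfg.get("eeg_feature_set", "all")
    if mode == "absolute":
        return [c for c in cols if c.startswith("abs_")]
    if mode == "relative":
        return [c for c in cols if c.startswith("rel_")]
    return cols


def train_stress_scorer(
    train: pd.DataFrame,
    feature_cols: list[str],
    config: dict | None = None,
) -> Pipeline:
    """Fit the standardized RBF-SVR stress scorer on labelled rows.

    Standardization (per-feature mean/SD) is fit on the training rows
    only, so evaluation folds see no information from the held-out
    participant.
    """
    cfg = default_config()
    if config:
        cfg.update(config)
    labelled = train.dropna(subset=[LABEL_COLUMN])
    y = labelled[LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError(
            f"training set has labels {sorted(np.unique(y))}; need both classes"
        )
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svr", SVR(kernel=cfg["svr_kernel"], C=cfg["svr_C"],
                    epsilon=cfg["svr_epsilon"])),
    ])
    model.fit(labelled[feature_cols].to_numpy(), y)
    return model


def classify_block(scores: np.ndarray, threshold: float = 0.5) -> int:
    """Majority vote over epoch stress scores.

    An epoch indicates stress when its score exceeds ``threshold``; the
    block is stressed (1) when strictly more than half of its epochs
    indicate stress, otherwise not stressed (0) — a tie is not a majority.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise EmptyBlockError("no epoch scores to vote over")
    return int(np.sum(scores > threshold) > scores.size / 2)


def _evaluate_fold(
    train_df: pd.DataFrame,
    test_df: pd.DataFrame,
    feature_cols: list[str],
    cfg: dict,
) -> float:
    """Train on N-1 participants, return block accuracy (%) on the held-out one."""
    model = train_stress_scorer(train_df, feature_cols, cfg)
    labelled = test_df.dropna(subset=[LABEL_COLUMN])
    correct = 0
    blocks = labelled.groupby("block", sort=True)
    for _, grp in blocks:
        scores = model.predict(grp[feature_cols].to_numpy())
        pred = classify_block(scores, cfg["epoch_stress_threshold"])
        if pred == int(grp[LABEL_COLUMN].iloc[0]):
            correct += 1
    return 100.0 * correct / blocks.ngroups


def loso_evaluate(
    features: pd.DataFrame,
    k: int,
    modality: str = "eeg",
    config: dict | None = None,
) -> EvaluationResult:
    """Leave-one-subject-out block classification accuracy.

    ``features`` is a long-form multi-participant table (one task). For
    each participant a scorer is trained on every other participant's
    labelled epochs and the held-out participant's labelled blocks are
    classified by majority vote; accuracy is correct blocks over labelled
    blocks. Sessions where 2k exceeds the block count are dropped from
    this k with a warning.
    """
    cfg = default_config()
    if config:
        cfg.update(config)
    participants = sorted(features["participant"].unique())
    if len(participants) < 3:
        raise DegenerateTrainingError(
            f"LOSO needs >= 3 participants, have {len(participants)}"
        )
    labelled_parts: list[pd.DataFrame] = []
    kept: list[str] = []
    for pid in participants:
        session = features[features["participant"] == pid]
        try:
            labelled_parts.append(label_blocks(session, k))
            kept.append(pid)
        except InfeasibleLabelingError:
            log.warning("participant %s: too few blocks for k=%d, dropped", pid, k)
    df = pd.concat(labelled_parts, ignore_index=True)
    # only labelled blocks enter training and accuracy; dropping the
    # unlabelled middle here also keeps the channel pivot NaN-safe
    df = df.dropna(subset=[LABEL_COLUMN])
    if "channel" in df.columns:
        df = _pivot_channels(df)
    feature_cols = select_feature_columns(df, modality, cfg)

    accs = []
    for pid in kept:
        acc = _evaluate_fold(
            df[df["participant"] != pid],
            df[df["participant"] == pid],
            feature_cols, cfg,
        )
        accs.append(acc)
    accs_arr = np.asarray(accs)
    sem = float(accs_arr.std(ddof=1) / np.sqrt(accs_arr.size)) if accs_arr.size > 1 else 0.0
    return EvaluationResult(
        per_participant_accuracy=list(map(float, accs)),
        mean_accuracy=float(accs_arr.mean()),
        sem_accuracy=sem,
        k_blocks=k,
        modality=modality,
        participants=kept,
    )


def score_session(
    model: Pipeline,
    session: pd.DataFrame,
    feature_cols: list[str],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-block stress scores/votes across an entire session (all blocks).

    Used for stress-trajectory plots over unlabelled middle blocks; these
    predictions never enter accuracy figures.
    """
    rows = []
    for block, grp in session.groupby("block", sort=True):
        scores = model.predict(grp[feature_cols].to_numpy())
        rows.append({
            "block": block,
            "mean_score": float(np.mean(scores)),
            "stressed": classify_block(scores, threshold),
        })
    return pd.DataFrame(rows)


def sweep_block_counts(
    features: pd.DataFrame,
    k_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8),
    modalities: tuple[str, ...] = ("eeg",),
    config: dict | None = None,
) -> pd.DataFrame:
    """Full LOSO evaluation at every labelled-block count k.

    Returns one row per (k, modality) with mean and SEM accuracy, plus a
    ``best`` flag at the argmax mean accuracy per modality (ties go to the
    smaller k, the cheaper labelling assumption).
    """
    rows = []
    results: dict[tuple[str, int], EvaluationResult] = {}
    for modality in modalities:
        for k in k_values:
            res = loso_evaluate(features, k, modality, config)
            results[(modality, k)] = res
            rows.append({
                "modality": modality, "k_blocks": k,
                "mean_accuracy": res.mean_accuracy,
                "sem_accuracy": res.sem_accuracy,
                "n_participants": len(res.participants),
            })
    table = pd.DataFrame(rows)
    table["best"] = False
    for modality in modalities:
        sub = table[table["modality"] == modality]
        best_idx = sub.sort_values(["mean_accuracy", "k_blocks"],
                                   ascending=[False, True]).index[0]
        table.loc[best_idx, "best"] = True
    return table


def write_evaluation(result: EvaluationResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=1) + "\n")


def read_evaluation(path: str | Path) -> EvaluationResult:
    obj = json.loads(Path(path).read_text())
    return EvaluationResult(
        per_participant_accuracy=obj["per_participant_accuracy"],
        mean_accuracy=obj["mean_accuracy"],
        sem_accuracy=obj["sem_accuracy"],
        k_blocks=obj["k_blocks"],
        modality=obj["modality"],
        participants=obj["participants"],
    )
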