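#!/usr/bin/env python
"""Fit the stress classifier and evaluate it across participants.

Trains the block-labelled RBF-SVR stress scorer (first 2 blocks = not
stressed, last 2 = stressed) and evaluates with leave-one-subject-out
majority voting, separately for EEG epoch features and the
ultra-short-term HRV subset, on the high-effect cohort and on a
null-effect control cohort (the chance-level sanity check).
"""

import json
from dataclasses import replace
from pathlib import Path

from stresspipe.pipeline import cohort_features
from stresspipe.stress_model import loso_evaluate
from stresspipe.synthetic_data import generate_cohort

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "sim", Path(__file__).with_name("01_simulate_cohort.py"))
_sim = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_sim)
CONFIG = _sim.CONFIG

ROOT = Path(__file__).resolve().parents[1]
K = 2


def main() -> None:
    out = {}
    for label, cfg in (
        ("high_effect", CONFIG),
        ("null_effect", replace(CONFIG, stress_effect_eeg=0.0,
                                stress_effect_hrv=0.0)),
    ):
        eeg, hrv = cohort_features(generate_cohort(cfg))
        for modality, feats in (("eeg", eeg), ("hrv", hrv)):
            res = loso_evaluate(feats, k=K, modality=modality)
            out[f"{label}_{modality}"] = res.to_dict()
            print(f"{label:>11} {modality}: {res.mean_accuracy:5.1f} "
                  f"± {res.sem_accuracy:.1f}% (mean ± SEM over "
                  f"{len(res.participants)} participants, k={K})")
    path = ROOT / "results" / "loso_results.json"
    path.parent.mkdir(exist_ok=True)
    path.write_text(json.dumps(out, indent=1) + "\n")
    print(f"\nwrote {path}")


if __name__ == "__main__":
    main()
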