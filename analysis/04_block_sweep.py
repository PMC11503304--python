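#!/usr/bin/env python
"""Sweep the number of labelled blocks used to train the classifier.

On a cohort whose stress effect is confined to the terminal blocks (late
steep sigmoid ramp), evaluates LOSO accuracy for k = 1..8 labelled
blocks from each session end, for both modalities. The expectation:
labelling only the extreme 1-2 blocks gives the cleanest labels, and
accuracy falls as more (transition-contaminated) blocks are added.
"""

from dataclasses import replace
from pathlib import Path

from stresspipe.pipeline import cohort_features
from stresspipe.stress_model import sweep_block_counts
from stresspipe.synthetic_data import generate_cohort

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location(
    "sim", Path(__file__).with_name("01_simulate_cohort.py"))
_sim = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_sim)

ROOT = Path(__file__).resolve().parents[1]

CONFIG = replace(_sim.CONFIG, stress_ramp="sigmoid", ramp_center=0.85,
                 ramp_steepness=25.0)


def main() -> None:
    eeg, hrv = cohort_features(generate_cohort(CONFIG))
    tables = []
    for modality, feats in (("eeg", eeg), ("hrv", hrv)):
        tables.append(sweep_block_counts(
            feats, k_values=(1, 2, 3, 4, 5, 6, 7, 8), modalities=(modality,)))
    import pandas as pd
    table = pd.concat(tables, ignore_index=True)
    out = ROOT / "results" / "block_sweep.csv"
    out.parent.mkdir(exist_ok=True)
    table.round(3).to_csv(out, index=False)
    print(table.round(2).to_string(index=False))
    for modality in ("eeg", "hrv"):
        sub = table[table["modality"] == modality]
        best = sub.loc[sub["best"]].iloc[0]
        print(f"\nbest {modality}: k={int(best.k_blocks)} at "
              f"{best.mean_accuracy:.1f} ± {best.sem_accuracy:.1f}%")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
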