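#!/usr/bin/env python
"""Generate the four preset synthetic cohorts and write them as CSV.

Each preset reproduces its cohort's size and class balance exactly and
its vitals scale approximately (the calibration inverts the indicator
formulas at the published group means).  Seed 1 throughout.
"""

from pathlib import Path

from cardioindex.datasets import write_csv_cohort
from cardioindex.synthetic import PRESET_NAMES, generate_cohort, preset

OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"
OUT.mkdir(parents=True, exist_ok=True)

for name in PRESET_NAMES:
    cohort = generate_cohort(preset(f"{name}-like", seed=1))
    path = OUT / f"{name}_like.csv"
    write_csv_cohort(cohort, path)
    print(f"{name:12s} n={len(cohort):4d} positives={int(cohort.y.sum()):4d} -> {path}")
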