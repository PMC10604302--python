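#!/usr/bin/env python
"""Run the six selection criteria on a cleveland-like scenario-1 cohort.

Shows which of the ten scenario-1 features (age, gender, hypertension
history + the seven indicators) each criterion keeps, and writes the
kept lists.  The VIF step is where the heavily collinear indicator set
(PBPI, PBPIRC, RC, ALPHA... all transforms of the same three vitals)
gets thinned.
"""

import json
from pathlib import Path

from cardioindex.feature_selection import CRITERIA, select
from cardioindex.synthetic import generate_cohort, preset

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cohort = generate_cohort(preset("cleveland-like", seed=1))
results = {}
for crit in CRITERIA:
    res = select(crit, cohort, scenario=1)
    results[crit] = res.kept
    print(f"{crit:10s} kept {len(res.kept):2d}: {', '.join(res.kept)}")

(OUT / "selection_scenario1.json").write_text(json.dumps(results, indent=2))
print(f"\nwrote {OUT / 'selection_scenario1.json'}")
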