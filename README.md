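# cardioindex

Non-invasive hemodynamic indicators for ischemic heart-disease
classification: compute the seven Campello de Souza (CS) indicators from
cuff vitals, rank them with a between-group consistency measure, and
evaluate feature-selection + classifier pipelines with a repeated
stratified holdout. A seeded synthetic cohort generator stands in for
clinical records, so every stage is testable offline.

## The science

All a clinician needs is a tensiometer and a clock: systolic blood
pressure (SBP), diastolic blood pressure (DBP), both in mmHg, and heart
rate (HR, beats/min). Modelling the diastolic pressure as a windkessel
decay `P(t) = SBP · exp(−t/RC)` that reaches DBP after one beat period
fixes the time constant and the cycle-averaged pressure in closed form,
and a triangular-wave approximation of the pressure pulse yields an
ejection-time fraction. The seven derived indicators are

| Indicator | Formula | Meaning |
|---|---|---|
| MAP | (SBP − DBP)/(ln SBP − ln DBP) | mean arterial pressure (log-mean of SBP, DBP) |
| RC | 1/(HR · ln(SBP/DBP)) | peripheral-resistance × compliance product |
| PBPI | (SBP − DBP)/DBP | pulse pressure normalised by DBP |
| PBPIRC | PBPI/RC | pulsatility per unit time constant |
| HM | (1000·HR/60)²/(SBP − MAP)³ | Kepler-inspired "harmony measure" |
| α | ½ − (1/2τ)·√(τ² − 4(SBP−DBP)²), τ = 60000/HR ms | ejection-time fraction of the cycle |
| α2 | −ln α | log transform of α |

For a binary disease label Y, each indicator S is ranked by the adapted
consistency measure

```
d(S) = |μ̂0 − μ̂1| / √(σ̂0² + σ̂1²)
```

(group means μ̂ and sample SDs σ̂ of S among non-cardiac / cardiac
subjects); medians are compared with the two-sided
Wilcoxon–Mann–Whitney test. Downstream, six selection criteria
(InfoGain, VIF, ANOVA, ANOVA+VIF, AIC, AIC+VIF) feed five classifiers
(naive Bayes, random forest with 500 trees, logistic regression,
AdaBoost with 10 rounds, polynomial-kernel SVM with cost 100), each
evaluated by a 100-iteration stratified 70/30 multiple holdout reporting
mean/SD accuracy and the averaged sensitivity (ASe), specificity (ASp)
and positive predictive value (ATPP).

## Worked example

```python
>>> from cardioindex import VitalSigns, compute_all
>>> vec = compute_all(VitalSigns(sbp=120, dbp=80, hr=70))
>>> {k: round(v, 4) for k, v in vec.as_dict().items()}
{'MAP': 98.6521, 'RC': 0.0352, 'PBPI': 0.5, 'PBPIRC': 14.1913,
 'HM': 139.9041, 'ALPHA': 0.0022, 'ALPHA2': 6.1273}
```

A cuff reading of 120/80 at 70 bpm gives a mean arterial pressure of
98.65 mmHg (the logarithmic mean, slightly below the arithmetic 100), a
decay time constant RC ≈ 0.035 (HR in beats/min), a pulse pressure 50%
of DBP, and an ejection fraction of about 0.22% of the cycle on the
triangular model (α2 ≈ 6.13). Invalid vitals (SBP ≤ DBP, zeros,
sentinels) yield NaN fields rather than errors.

The full pipeline on a synthetic cohort:

```python
>>> from cardioindex import generate_cohort, preset, run_experiment
>>> cohort = generate_cohort(preset("switzerland-like", seed=1))
>>> res = run_experiment(cohort, scenario=1, criterion="vif",
...                      classifier="rf", iterations=100, seed=1)
>>> round(res.mu_accuracy, 2), round(res.asp, 2)
(94.59, 0.0)
```

— with 115 cases against 8 controls the forest predicts nearly everyone
positive: accuracy looks excellent while specificity is exactly zero.
That pathology is why the holdout reports ASe/ASp/ATPP alongside
accuracy.

## Analysis scripts

The `analysis/` drivers run the pipeline end to end and write tables
under `results/`:

1. `01_published_consistency.py` — recompute the consistency matrix from
   the published per-group indicator summaries of the four UCI
   heart-disease cohorts.
2. `02_simulate_cohorts.py` — generate the four preset synthetic cohorts.
3. `03_indicator_reports.py` — descriptive tables, WMW tests and d per cohort.
4. `04_feature_selection.py` — the six criteria on scenario 1.
5. `05_holdout_evaluation.py` — classifier × criterion holdout sweep.

A CLI mirrors the stages: `cardioindex simulate|indicators|report|select|evaluate`.

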