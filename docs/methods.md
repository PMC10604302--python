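# Methods

## The pressure-decay model and the indicator conventions

The indicator set treats one cardiac cycle as an impulse (systolic
ejection) followed by a passive exponential decay through the arterial
windkessel: `dP/dt + P/RC = (1/C)·Σ δ(t − τᵢ)`, whose between-impulse
solution is `P(t) = SBP·exp(−t/RC)`. Requiring the decay to reach DBP
after one beat period τ = 1/HR identifies the time constant
`RC = 1/(HR·ln(SBP/DBP))`, and averaging P(t) over the cycle gives the
logarithmic-mean MAP `(SBP − DBP)/(ln SBP − ln DBP)`. These two
identities are enforced as oracles in the test suite: MAP must equal
the adaptive quadrature of the decay over one period (rel. err ≤ 1e−8)
and the decay must hit DBP at the period end (rel. err ≤ 1e−10). All
logarithms are natural — any other base would break the
integral-equals-closed-form identity.

The defining formulas do not carry units, so the package pins
conventions numerically and exposes them in one frozen configuration
object (`UnitConventions`):

* **RC** uses HR in beats/min (`rc_rate_scale = 1`), putting RC on the
  ~0.03 scale of resting vitals.
* **α** uses the beat period in milliseconds (τ = 60000/HR), putting α
  on the ~0.003 scale; α is defined as the *smaller* root of
  `α(1−α)τ² = (SBP−DBP)²` (the larger root 1−α is the same geometry
  relabelled) and is verified against that quadratic to 1e−8. A
  negative discriminant (pulse pressure above τ/2 in model units) is
  reported as missing with a logged warning, never clamped to 0.5:
  clamping would bias group statistics toward the boundary.
* **HM** uses the factor `(1000·HR/60)²` over `(SBP − MAP)³`, with MAP
  the logarithmic-mean MAP of the decay model (the triangular-wave
  section of the source material redefines MAP as the arithmetic mean,
  but HM is introduced in terms of "the MAP" already defined, and only
  the log-mean reading lands HM on its conventional tens-to-hundreds
  scale). This parenthesisation is the only one of the typographically
  possible readings with that property.

Invalid vitals (SBP ≤ DBP, non-positive pressures or rates, missing
components) make the affected indicators missing, never zero, and
`compute_all` never raises on a single bad record. Rate-independent
indicators (MAP, PBPI) remain defined when only HR is invalid.

## The consistency measure and the group tables

Indicators are ranked by `d(S) = |μ̂0 − μ̂1| / √(σ̂0² + σ̂1²)` with
sample SDs (n−1). The square-root denominator is deliberate: the
alternate reading `|μ̂0 − μ̂1| / (σ̂0² + σ̂1²)` misses every published
reference cell by roughly an order of magnitude, while the root form
reproduces all ten rounding-robust cells to 4 decimal places (an
acceptance test). d is invariant under group swap and common positive
rescaling, and undefined when both SDs vanish.

Reference values (per-group means/medians/SDs, WMW p-values, published
d) for the four UCI heart-disease cohorts live in
`cardioindex.reference`. Recomputing d from the *rounded* published
summaries cannot reproduce every published d cell to ±0.001: for
small-scale indicators such as RC (~0.03), the 4-dp rounding of the
inputs alone induces errors up to ~0.007 in d. The corresponding test
therefore propagates the worst-case ±5·10⁻⁵ input rounding through d
analytically and asserts agreement within that bound; only the ten
cells whose printed mean differences are far from the rounding floor
are held to exact 4-dp agreement.

Median differences use the two-sided Wilcoxon–Mann–Whitney test: exact
null distribution when the combined sample is ≤ 30 and tie-free,
otherwise the normal approximation with tie and continuity corrections
(scipy). The two paths agree to about 0.01 in p at n = 8 per group
(the property test allows 0.015, the measured worst case being 0.011).
Rendered tables star p-values at the 10%/5%/1% levels. No
multiple-testing correction is applied across indicators, matching the
descriptive intent of the table.

## Feature selection

* **InfoGain** — mutual information of Y with each feature in bits,
  continuous features discretised by equal-frequency binning (10 bins,
  configurable; ties share a bin). The criterion returns the full
  ranking: no retention cutoff is claimed because the analysis consumes
  the ordering, and any top-k truncation is a caller choice.
* **VIF** — iteratively remove the feature with the largest
  variance-inflation factor (1/(1−R²) of that column regressed on the
  rest plus an intercept) while any exceeds 10. Exact collinearity is
  treated as infinite VIF and removed first. Categorical features are
  one-hot encoded and removed whole if any encoded column offends.
* **ANOVA** — keep features with one-way ANOVA p < 0.05 against Y;
  with binary Y this is the two-sample equal-variance F test.
  Zero-variance features are excluded with a trace note.
* **AIC** — backward stepwise logistic regression (GLM–binomial),
  AIC = −2·loglik + 2(k+1); remove the single feature whose removal
  lowers AIC the most, stop when none does. Backward is the default
  because the composite criteria are phrased as removals; a forward
  mode exists. Separation is handled by an iteration cap and a warning
  rather than penalisation, keeping AICs comparable across steps.
* **Compositions** (ANOVA+VIF, AIC+VIF) run the stages in order with
  concatenated traces.

All criteria are deterministic and seed-free.

## The multiple holdout

Each of J iterations (default 100) draws a stratified 70/30 train/test
split (the split fraction is unstated in the source analysis; 70/30 is
the common holdout convention and is exposed as a parameter). Feature
selection runs once on the full cohort by default — matching the
presentation of fixed per-model variable lists — with a `nested` mode
that re-selects inside every iteration for leakage-sensitivity checks.
Per-iteration confusion counts (TN/FP/FN/TP, class-0 row first) yield
accuracy, and the aggregates are the mean accuracy, its SD with the
(J−1) denominator (undefined — not zero — at J = 1), and the averaged
sensitivity/specificity/positive predictive value as percentages. An
iteration with a zero denominator (e.g. no positives in the test set)
contributes a missing value to that average and is counted, never
silently averaged as zero; a defined-but-zero specificity (the
all-positive-prediction regime under severe imbalance) still shows up
as exactly 0.

Classifier configurations follow the fixed grid: GaussianNB; random
forest with 500 trees; logistic regression with logit link thresholded
at 0.5; AdaBoost with 10 rounds; SVM with polynomial kernel and cost
100, no internal feature scaling. One host-ecosystem deviation: the
naive Bayes implementation here cannot consume missing feature values,
so NB uses the same complete-case training policy as the other
classifiers instead of passing NaNs through. Test rows with missing
features are median-imputed from training so every row is predicted.
Iteration seeds derive from one master seed via `SeedSequence`; the
whole experiment is bit-reproducible.

## The synthetic cohort generator

Per disease group, the generator draws DBP, pulse pressure and HR from
truncated normals (DBP ∈ [30, 140], PP ∈ [20, 130], HR ∈ [30, 160] —
the PP floor is the physiological lower bound of cuff pulse pressures)
and sets SBP = DBP + PP, making the vitals invariants structural. Group
separation enters *only* through these raw-vitals (and covariate)
parameters, so indicator-level effects are emergent, exactly as they
are in real cohorts. Covariates are age (normal), gender (shared
Bernoulli), hypertension history (per-group Bernoulli); extra columns
are standard-normal noise; missingness is MCAR and only ever applied to
covariate/noise columns (the list-wise deletion policy downstream
assumes no more structure than MCAR).

The four presets reproduce the published cohort sizes and class counts
exactly (282/125, 294/106, 200/149, 123/115) and were calibrated once
against the published group summaries: DBP, PP and HR group means are
exactly identified by inverting the MAP, PBPI and RC formulas at the
published means, and the SDs were matched to first order by the delta
method. At large n the simulated MAP/PBPI/RC group means land within a
few percent of the published ones (within 25% is property-tested) and
ALPHA/ALPHA2/PBPIRC are close. **What the generator does not emulate:**
HM's published moments — HM is a cube-inverse transform with an extreme
right tail, and a truncated-normal pulse-pressure model inflates its
mean well above the published value even though the scale (tens to
hundreds) and skew are qualitatively right; the real cohorts' skewed,
heaped vitals distributions (cuff readings heap on multiples of 5/10);
any vitals–age/gender correlation; and informative missingness. Tests
passing on these cohorts therefore validate the *machinery* (effects
propagate, rankings respond, imbalance pathologies reproduce), not
clinical effect sizes.

For parameter-recovery checks, the spec-implied MAP effect is computed
analytically by the first-order delta method (numerical partials of the
indicator formulas at the group means, independence of DBP/PP/HR), and
a "1-pooled-SD MAP shift" spec is constructed by root-finding the DBP
offset whose delta-method MAP gap equals the pooled delta-method SD.
Across 50 replicates at n = 300 the mean estimated d lands within a few
percent of the analytic value (±15% is the test band); identical-group
null specs give all indicator d < 0.05 at n = 10⁴.

## Problem sizes and determinism

Test and analysis runs use cohorts of n = 123–300 (presets up to
n = 10⁴–10⁵ for invariant and null checks), 100 holdout iterations for
headline checks and 4–20 for bookkeeping tests, and 20–50 replicates
for recovery checks — sizes at which every claimed property is stable
under reseeding. All randomness flows through explicit integer seeds
(`numpy.random.default_rng` / `SeedSequence`); fixed-seed runs are
byte-reproducible, including CSV output.

## Known limitations

* Only the RC *product* is identifiable; R and C are never separated.
* The raw-dialect reader's vitals mapping (resting systolic V10,
  resting diastolic V37, resting heart rate V33) is the only triple on
  the published RC scale, but users with differently laid-out files
  should pass an explicit column map.
* Published classification accuracies on the real UCI cohorts depend on
  undocumented curation of those files and are not reproduction targets;
  the pipeline reports whatever a user-supplied cohort yields.
* The exact/asymptotic WMW switch at combined n = 30 is a convention;
  near the boundary with heavy ties the asymptotic p is used even when
  an exact tie-aware enumeration would differ slightly.
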