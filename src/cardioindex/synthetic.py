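"""Synthetic labelled cohorts with the structure the analysis assumes.

The generator draws, per disease group, diastolic pressure, pulse
pressure and heart rate from truncated normal distributions and sets
``SBP = DBP + pulse pressure``, which makes ``SBP > DBP > 0`` and
``HR > 0`` structural.  Group separation is encoded only through the
vitals (and covariate) parameters, so indicator-level effects are
emergent nonlinear transforms of the raw-vitals shifts — the same logic
by which the indicators are derived from cuff measurements on real
subjects.

The four named presets emulate the size, class balance and
indicator-summary scale of the four UCI heart-disease cohorts.  Their
vitals parameters were calibrated by inverting the indicator formulas
at the published group means (DBP, pulse pressure and HR are exactly
identified by the MAP, PBPI and RC group means) and matching published
SDs to first order by the delta method; they are frozen constants, not
tuning knobs.

Covariates: age (normal), gender (Bernoulli, shared), hypertension
history (Bernoulli, per group); extra columns are pure standard-normal
noise.  Missingness is missing-completely-at-random on covariate and
noise columns only.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .datasets import Cohort, Variable
from .indicators import INDICATOR_ORDER, add_indicators, compute_map

PRESET_NAMES = ("cleveland", "hungarian", "longbeach", "switzerland")


@dataclass(frozen=True)
class TruncNormal:
    """Truncated normal: mean/sd on the latent scale, hard bounds (lo, hi)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi and self.sd > 0):
            raise ValueError(f"infeasible truncation bounds or sd: {self}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


@dataclass(frozen=True)
class GroupVitals:
    """Per-group generative parameters for (DBP, pulse pressure, HR)."""

    dbp: TruncNormal
    pp: TruncNormal
    hr: TruncNormal


def _gv(dbp, dbp_sd, pp, pp_sd, hr, hr_sd) -> GroupVitals:
    return GroupVitals(
        dbp=TruncNormal(dbp, dbp_sd, 30.0, 140.0),
        pp=TruncNormal(pp, pp_sd, 20.0, 130.0),
        hr=TruncNormal(hr, hr_sd, 30.0, 160.0),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort; deterministic given ``seed``."""

    n: int
    prevalence: float
    vitals0: GroupVitals
    vitals1: GroupVitals
    age_mean: float = 54.0
    age_sd: float = 9.0
    gender_p: float = 0.68
    htn_p0: float = 0.35
    htn_p1: float = 0.55
    noise_features: int = 0
    missing_rate: float = 0.0
    seed: int = 0
    name: str = "custom"


# Vitals parameters frozen from the published-summary calibration
# (DBP mean/sd, pulse-pressure mean/sd, HR mean/sd per group).
_PRESET_VITALS: dict[str, tuple[GroupVitals, GroupVitals]] = {
    "cleveland": (_gv(83.95, 9.71, 45.66, 14.37, 67.92, 13.77),
                  _gv(85.57, 9.83, 48.71, 13.98, 65.28, 14.37)),
    "hungarian": (_gv(83.62, 10.16, 47.15, 11.18, 75.80, 12.97),
                  _gv(85.16, 9.50, 50.85, 17.81, 71.20, 3.00)),
    "longbeach": (_gv(79.38, 11.23, 50.84, 14.91, 61.79, 12.22),
                  _gv(80.87, 9.70, 55.33, 14.79, 64.16, 10.12)),
    "switzerland": (_gv(77.57, 14.83, 46.32, 16.45, 60.16, 19.21),
                    _gv(81.85, 11.99, 48.91, 18.39, 59.62, 11.37)),
}
_PRESET_SIZES = {
    "cleveland": (282, 125), "hungarian": (294, 106),
    "longbeach": (200, 149), "switzerland": (123, 115),
}


def preset(name: str, seed: int = 0, noise_features: int = 0,
           missing_rate: float = 0.0) -> CohortSpec:
    """A named cohort spec (``cleveland-like``, ``switzerland-like``, ...)."""
    key = name.lower().removesuffix("-like")
    if key not in _PRESET_VITALS:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    n, n1 = _PRESET_SIZES[key]
    v0, v1 = _PRESET_VITALS[key]
    return CohortSpec(
        n=n, prevalence=n1 / n, vitals0=v0, vitals1=v1,
        noise_features=noise_features, missing_rate=missing_rate,
        seed=seed, name=f"{key}-like",
    )


def spec_to_yaml(spec: CohortSpec) -> str:
    """Serialise a cohort spec as YAML (round-trips via spec_from_yaml)."""
    return yaml.safe_dump(asdict(spec), sort_keys=False)


def spec_from_yaml(text: str) -> CohortSpec:
    """Rebuild a CohortSpec from its YAML serialisation."""
    raw = yaml.safe_load(text)
    for key in ("vitals0", "vitals1"):
        raw[key] = GroupVitals(**{k: TruncNormal(**v) for k, v in raw[key].items()})
    return CohortSpec(**raw)


def generate_cohort(spec: CohortSpec, indicators: bool = True) -> Cohort:
    """Draw one cohort; byte-identical across runs for a fixed spec.

    The label count is exact to the prevalence within rounding
    (``n1 = round(n * prevalence)``).  Indicator columns are appended
    unless ``indicators=False``.
    """
    if not (0.0 < spec.prevalence < 1.0) or spec.n < 2:
        raise ValueError("need n >= 2 and prevalence strictly inside (0, 1)")
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n * spec.prevalence))
    n1 = min(max(n1, 1), spec.n - 1)
    sizes = {0: spec.n - n1, 1: n1}
    frames = []
    for group, params in ((0, spec.vitals0), (1, spec.vitals1)):
        m = sizes[group]
        dbp = params.dbp.draw(rng, m)
        pp = params.pp.draw(rng, m)
        hr = params.hr.draw(rng, m)
        htn_p = spec.htn_p0 if group == 0 else spec.htn_p1
        frames.append(pd.DataFrame({
            "V3": np.round(rng.normal(spec.age_mean, spec.age_sd, m)).clip(18, 95),
            "V4": rng.binomial(1, spec.gender_p, m).astype(float),
            "V11": rng.binomial(1, htn_p, m).astype(float),
            "sbp": dbp + pp,
            "dbp": dbp,
            "hr": hr,
            "Y": float(group),
        }))
    df = pd.concat(frames, ignore_index=True)
    for k in range(spec.noise_features):
        df[f"N{k + 1}"] = rng.standard_normal(spec.n)
    df = df.iloc[rng.permutation(spec.n)].reset_index(drop=True)
    if spec.missing_rate > 0:
        maskable = ["V3", "V11"] + [f"N{k + 1}" for k in range(spec.noise_features)]
        for col in maskable:
            hole = rng.random(spec.n) < spec.missing_rate
            df.loc[hole, col] = np.nan
    registry = {
        "V3": Variable("V3", "age"), "V4": Variable("V4", "gender", "binary"),
        "V11": Variable("V11", "hypertension history", "binary"),
        "sbp": Variable("sbp", "systolic blood pressure (mmHg)"),
        "dbp": Variable("dbp", "diastolic blood pressure (mmHg)"),
        "hr": Variable("hr", "heart rate (beats/min)"),
    }
    for k in range(spec.noise_features):
        registry[f"N{k + 1}"] = Variable(f"N{k + 1}", "noise feature")
    cohort = Cohort(df, registry, provenance=f"synthetic:{spec.name}:seed={spec.seed}")
    if indicators:
        cohort = cohort.with_data(add_indicators(cohort.data))
        for ind in INDICATOR_ORDER:
            cohort.registry[ind] = Variable(ind, ind)
    return cohort


# ---------------------------------------------------------------------------
# Delta-method moments and parameter-recovery checking
# ---------------------------------------------------------------------------

def delta_map_moments(params: GroupVitals) -> tuple[float, float]:
    """First-order (delta-method) mean and SD of MAP under a vitals spec.

    MAP = f(DBP, PP) is evaluated at the group means; the SD combines
    the independent DBP and pulse-pressure variances through numerical
    partial derivatives.  Truncation is ignored (bounds sit several SDs
    out for all presets).
    """
    D, P = params.dbp.mean, params.pp.mean
    f = lambda d, p: compute_map(d + p, d)
    eps = 1e-5
    fD = (f(D + eps, P) - f(D - eps, P)) / (2 * eps)
    fP = (f(D, P + eps) - f(D, P - eps)) / (2 * eps)
    var = (fD * params.dbp.sd) ** 2 + (fP * params.pp.sd) ** 2
    return float(f(D, P)), float(np.sqrt(var))


def analytic_map_d(spec: CohortSpec) -> float:
    """Spec-implied consistency measure for MAP, |Δμ| / sqrt(σ0² + σ1²)."""
    m0, s0 = delta_map_moments(spec.vitals0)
    m1, s1 = delta_map_moments(spec.vitals1)
    return abs(m0 - m1) / float(np.hypot(s0, s1))


def map_shifted_spec(base: CohortSpec, shift_sds: float = 1.0) -> CohortSpec:
    """A spec whose group-1 DBP mean is offset so the implied MAP gap
    equals ``shift_sds`` pooled (delta-method) MAP SDs.

    The offset is found by root-finding on the delta-method MAP mean,
    keeping every other parameter at the group-0 values — so the MAP
    effect size is analytically known from the spec itself.
    """
    m0, s0 = delta_map_moments(base.vitals0)
    # pooled SD sqrt((s0^2+s1^2)/2) ~ s0: both groups share spread params
    target_gap = shift_sds * s0

    def gap(delta: float) -> float:
        shifted = replace(base.vitals0, dbp=replace(base.vitals0.dbp,
                                                    mean=base.vitals0.dbp.mean + delta))
        return delta_map_moments(shifted)[0] - m0 - target_gap

    delta = optimize.brentq(gap, 0.0, 60.0)
    v1 = replace(base.vitals0, dbp=replace(base.vitals0.dbp,
                                           mean=base.vitals0.dbp.mean + delta))
    return replace(base, vitals1=v1, name=f"{base.name}+map_shift{shift_sds:g}sd")


def null_spec(n: int = 10_000, seed: int = 0) -> CohortSpec:
    """Identical group parameters: every indicator effect is pure noise."""
    v = _gv(82.0, 10.0, 47.0, 14.0, 68.0, 12.0)
    return CohortSpec(n=n, prevalence=0.5, vitals0=v, vitals1=v,
                      htn_p0=0.4, htn_p1=0.4, seed=seed, name="null")


def recovery_check(spec: CohortSpec, replicates: int = 50,
                   seed: int | None = None) -> pd.DataFrame:
    """Empirical indicator-level d across replicate cohorts vs the spec.

    Generates ``replicates`` cohorts (seeds derived from ``seed``),
    computes each indicator's consistency measure per replicate, and
    reports the mean and SD of d.  For MAP the spec-implied analytic d
    (delta method) and the relative bias of the mean estimate are
    included.
    """
    from .group_stats import indicator_report

    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    ss = np.random.SeedSequence(seed if seed is not None else spec.seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(replicates)]
    d_vals = {ind: [] for ind in INDICATOR_ORDER}
    for s in seeds:
        cohort = generate_cohort(replace(spec, seed=s))
        for summ in indicator_report(cohort):
            d_vals[summ.indicator].append(summ.d)
    rows = {}
    target = analytic_map_d(spec)
    for ind, vals in d_vals.items():
        arr = np.asarray(vals)
        row = {"mean_d": float(np.nanmean(arr)), "sd_d": float(np.nanstd(arr, ddof=1))}
        if ind == "MAP":
            row["analytic_d"] = target
            row["rel_bias"] = (row["mean_d"] - target) / target if target > 0 else np.nan
        rows[ind] = row
    return pd.DataFrame.from_dict(rows, orient="index")
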