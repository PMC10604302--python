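"""Feature-selection criteria and the scenario variable presets.

Six criteria are supported, matching the model-selection stage of the
analysis: information-gain ranking, iterative VIF filtering, per-feature
one-way ANOVA screening, backward-stepwise AIC on the logistic model,
and the two compositions ANOVA+VIF and AIC+VIF.

Scenario presets fix the candidate variables:

* Scenario 1 — the low-collection-cost set: age (V3), gender (V4),
  hypertension history (V11) plus the seven indicators (10 features).
* Scenario 2 — every registry variable except the response and
  identifier fields, plus the seven indicators.

All criteria are deterministic: given the same cohort they return the
same result on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datasets import Cohort, SchemaError, UCI_DISEASE_CODE, UCI_IDENTIFIER_CODES
from .indicators import INDICATOR_ORDER

logger = logging.getLogger(__name__)

SCENARIO1_COVARIATES = ("V3", "V4", "V11")
CRITERIA = ("infogain", "vif", "anova", "anova+vif", "aic", "aic+vif")


@dataclass
class SelectionResult:
    """Outcome of one criterion: the kept features plus a step trace."""

    criterion: str
    kept: list[str]
    trace: list[dict] = field(default_factory=list)


def scenario_features(scenario: int, cohort: Cohort) -> list[str]:
    """Candidate feature list for scenario 1 or 2.

    Raises :class:`~cardioindex.datasets.SchemaError` when a required
    code is absent from the cohort.
    """
    columns = set(cohort.data.columns)
    missing_ind = [c for c in INDICATOR_ORDER if c not in columns]
    if missing_ind:
        raise SchemaError(
            f"indicator column(s) absent: {', '.join(missing_ind)}; "
            "run add_indicators first"
        )
    if scenario == 1:
        absent = [c for c in SCENARIO1_COVARIATES if c not in columns]
        if absent:
            raise SchemaError(f"scenario 1 code(s) absent: {', '.join(absent)}")
        return list(SCENARIO1_COVARIATES) + list(INDICATOR_ORDER)
    if scenario == 2:
        skip = set(UCI_IDENTIFIER_CODES) | {UCI_DISEASE_CODE, "Y"} | set(INDICATOR_ORDER)
        # vitals convenience aliases duplicate their V-code sources
        skip |= {"sbp", "dbp", "hr", "id"}
        feats = [c for c in cohort.data.columns if c not in skip]
        return feats + list(INDICATOR_ORDER)
    raise ValueError(f"scenario must be 1 or 2, got {scenario!r}")


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _discretize(col: pd.Series, bins: int) -> pd.Series:
    """Equal-frequency binning for continuous features; ties share a bin."""
    vals = col.dropna()
    if vals.nunique() <= bins:
        return col
    try:
        return pd.qcut(col, q=bins, duplicates="drop", labels=False)
    except ValueError:
        return col


def info_gain_rank(
    df: pd.DataFrame, y: pd.Series, features: list[str], bins: int = 10
) -> list[tuple[str, float]]:
    """Mutual information of Y with each (discretized) feature, in bits.

    gain(f) = H(Y) - H(Y | f), computed on the rows where both the
    feature and Y are observed.  Descending by gain, ties broken by
    feature name.  A constant Y yields all-zero gains with a warning.
    """
    if y.dropna().nunique() <= 1:
        logger.warning("response is constant; all information gains are 0")
        return sorted(((f, 0.0) for f in features), key=lambda t: t[0])
    out = []
    for f in features:
        binned = _discretize(df[f], bins)
        mask = binned.notna() & y.notna()
        fb, yb = binned[mask], y[mask]
        if fb.empty:
            out.append((f, 0.0))
            continue
        hy = _entropy_bits(yb.value_counts().to_numpy(dtype=float))
        h_cond = 0.0
        n = len(fb)
        for _, sub in yb.groupby(fb, observed=True):
            h_cond += (len(sub) / n) * _entropy_bits(
                sub.value_counts().to_numpy(dtype=float)
            )
        out.append((f, hy - h_cond))
    return sorted(out, key=lambda t: (-t[1], t[0]))


def _encode_design(df: pd.DataFrame, features: list[str]) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Numeric design matrix; categorical text columns one-hot encoded.

    Returns (design, mapping original feature -> its encoded columns).
    """
    cols = {}
    origin: dict[str, list[str]] = {}
    for f in features:
        col = df[f]
        if pd.api.types.is_numeric_dtype(col):
            cols[f] = col.astype(float)
            origin[f] = [f]
        else:
            dummies = pd.get_dummies(col, prefix=f, drop_first=True, dtype=float)
            origin[f] = list(dummies.columns)
            for c in dummies.columns:
                cols[c] = dummies[c]
    return pd.DataFrame(cols), origin


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF = 1/(1-R^2) of each column regressed on the others (+intercept).

    Exactly collinear columns get +inf.
    """
    n, p = X.shape
    vifs = np.empty(p)
    for j in range(p):
        xj = X[:, j]
        others = np.column_stack([np.delete(X, j, axis=1), np.ones(n)])
        beta, _, _, _ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((xj - xj.mean()) ** 2).sum())
        if ss_tot == 0.0:
            vifs[j] = np.inf
        else:
            r2 = 1.0 - ss_res / ss_tot
            vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_filter(
    df: pd.DataFrame, features: list[str], threshold: float = 10.0
) -> SelectionResult:
    """Iteratively drop the feature with the highest VIF above threshold.

    Categorical features are one-hot encoded; a feature is removed
    whole if any of its encoded columns has the maximal offending VIF.
    Exact collinearity counts as infinite VIF and is removed first.
    """
    kept = list(features)
    trace: list[dict] = []
    design, origin = _encode_design(df.dropna(subset=features), features)
    step = 0
    while len(kept) > 1:
        enc_cols = [c for f in kept for c in origin[f]]
        X = design[enc_cols].to_numpy(dtype=float)
        vifs = _vif_values(X)
        worst_idx = int(np.argmax(vifs))
        worst = vifs[worst_idx]
        if not (worst > threshold):
            break
        enc_name = enc_cols[worst_idx]
        victim = next(f for f in kept if enc_name in origin[f])
        kept.remove(victim)
        step += 1
        trace.append(
            {"step": step, "feature": victim, "statistic": float(worst), "action": "removed"}
        )
    for f in kept:
        trace.append({"step": None, "feature": f, "statistic": None, "action": "kept"})
    return SelectionResult("vif", kept, trace)


def anova_select(
    df: pd.DataFrame, y: pd.Series, features: list[str], alpha: float = 0.05
) -> SelectionResult:
    """Keep features whose one-way ANOVA against the binary Y has p < alpha.

    With a binary response this is the two-sample equal-variance F test.
    Zero-variance features are excluded with a trace note.
    """
    kept, trace = [], []
    for f in features:
        mask = df[f].notna() & y.notna()
        g0 = df.loc[mask & (y == 0), f].astype(float)
        g1 = df.loc[mask & (y == 1), f].astype(float)
        pooled = pd.concat([g0, g1])
        if pooled.nunique() <= 1 or g0.empty or g1.empty:
            trace.append({"feature": f, "statistic": None, "action": "excluded_degenerate"})
            continue
        _, p = stats.f_oneway(g0, g1)
        if p < alpha:
            kept.append(f)
            trace.append({"feature": f, "statistic": float(p), "action": "kept"})
        else:
            trace.append({"feature": f, "statistic": float(p), "action": "dropped"})
    return SelectionResult("anova", kept, trace)


def _logit_aic(X: pd.DataFrame, y: pd.Series) -> float:
    """AIC of the logistic model, -2 loglik + 2 (k+1) with k features."""
    design = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.GLM(y.astype(float), design, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        res = model.fit(maxiter=100)
    if not res.converged:
        logger.warning("logistic fit did not converge (possible separation); AIC kept comparable")
    return float(res.aic)


def aic_stepwise(
    df: pd.DataFrame, y: pd.Series, features: list[str], direction: str = "backward"
) -> SelectionResult:
    """Stepwise logistic-model selection minimising AIC.

    Backward (default): start from the full model, repeatedly remove
    the single feature whose removal lowers AIC the most; stop when no
    removal lowers it.  Fitting uses complete cases over Y and the
    current candidates.  Separation is handled by an iteration cap with
    a warning; the likelihood stays unpenalised so AICs are comparable.
    """
    if direction not in ("backward", "forward"):
        raise ValueError("direction must be 'backward' or 'forward'")
    if not features:
        return SelectionResult("aic", [], [])
    data = pd.concat([df[features], y.rename("__y__")], axis=1).dropna()
    yy = data["__y__"]
    trace: list[dict] = []

    if direction == "forward":
        kept: list[str] = []
        current = _logit_aic(data[[]], yy)
        trace.append({"step": 0, "feature": None, "statistic": current, "action": "start"})
        pool = list(features)
        while pool:
            cand = [(_logit_aic(data[kept + [f]], yy), f) for f in pool]
            best_aic, best_f = min(cand)
            if best_aic >= current:
                break
            kept.append(best_f)
            pool.remove(best_f)
            current = best_aic
            trace.append({"step": len(trace), "feature": best_f, "statistic": current, "action": "added"})
        return SelectionResult("aic", kept, trace)

    kept = list(features)
    current = _logit_aic(data[kept], yy)
    trace.append({"step": 0, "feature": None, "statistic": current, "action": "start"})
    while kept:
        cand = [(_logit_aic(data[[g for g in kept if g != f]], yy), f) for f in kept]
        best_aic, best_f = min(cand)
        if best_aic >= current:
            break
        kept.remove(best_f)
        current = best_aic
        trace.append({"step": len(trace), "feature": best_f, "statistic": current, "action": "removed"})
    return SelectionResult("aic", kept, trace)


def composite(criterion: str, df: pd.DataFrame, y: pd.Series, features: list[str],
              vif_threshold: float = 10.0, anova_alpha: float = 0.05) -> SelectionResult:
    """Run one of the six named criteria; compositions concatenate traces."""
    criterion = criterion.lower()
    if criterion == "infogain":
        ranked = info_gain_rank(df, y, features)
        trace = [{"feature": f, "statistic": g, "action": "ranked"} for f, g in ranked]
        return SelectionResult("infogain", [f for f, _ in ranked], trace)
    if criterion == "vif":
        res = vif_filter(df, features, vif_threshold)
        return SelectionResult("vif", res.kept, res.trace)
    if criterion == "anova":
        return anova_select(df, y, features, anova_alpha)
    if criterion == "aic":
        return aic_stepwise(df, y, features)
    if criterion in ("anova+vif", "aic+vif"):
        first = composite(criterion.split("+")[0], df, y, features,
                          vif_threshold, anova_alpha)
        second = vif_filter(df, first.kept, vif_threshold) if first.kept else \
            SelectionResult("vif", [], [])
        trace = [dict(t, stage=first.criterion) for t in first.trace]
        trace += [dict(t, stage="vif") for t in second.trace]
        return SelectionResult(criterion, second.kept, trace)
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")


def select(criterion: str, cohort: Cohort, scenario: int, **kwargs) -> SelectionResult:
    """Scenario preset + criterion in one call, on the cohort's table."""
    features = scenario_features(scenario, cohort)
    return composite(criterion, cohort.data, cohort.y, features, **kwargs)
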