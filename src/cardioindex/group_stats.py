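"""Per-group descriptive statistics, WMW tests, and the consistency measure d.

The consistency measure ranks indicators by how far the cardiac and
non-cardiac group means sit apart relative to the combined spread:

    d = |mu0 - mu1| / sqrt(s0^2 + s1^2)

with group means mu and sample SDs s (n-1 denominator).  d is invariant
under swapping the groups and under common positive rescaling of the
values.  Group medians are compared with the two-sided
Wilcoxon-Mann-Whitney test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import Cohort
from .indicators import INDICATOR_ORDER

logger = logging.getLogger(__name__)

#: Combined sample size up to which the WMW p-value is computed exactly.
EXACT_WMW_THRESHOLD = 30


class DegenerateGroupError(ValueError):
    """A group is empty, or both group SDs are zero."""


class GroupMoments(NamedTuple):
    mu0: float
    mu1: float
    m0: float
    m1: float
    s0: float
    s1: float


@dataclass(frozen=True)
class GroupSummary:
    """One indicator's row of the descriptive-statistics table."""

    indicator: str
    mu0: float
    mu1: float
    m0: float
    m1: float
    s0: float
    s1: float
    p_wmw: float
    d: float


def _drop_missing(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def summarize_groups(values0, values1) -> GroupMoments:
    """Means, medians (midpoint convention) and sample SDs per group.

    Missing values are removed first; an empty group raises
    :class:`DegenerateGroupError`.
    """
    g0, g1 = _drop_missing(values0), _drop_missing(values1)
    if g0.size == 0 or g1.size == 0:
        raise DegenerateGroupError("a group is empty after missing-value removal")
    sd = lambda g: float(np.std(g, ddof=1)) if g.size > 1 else 0.0
    return GroupMoments(
        mu0=float(np.mean(g0)),
        mu1=float(np.mean(g1)),
        m0=float(np.median(g0)),
        m1=float(np.median(g1)),
        s0=sd(g0),
        s1=sd(g1),
    )


def consistency_d(mu0: float, mu1: float, s0: float, s1: float) -> float:
    """Consistency measure ``|mu0 - mu1| / sqrt(s0^2 + s1^2)``.

    Raises
    ------
    DegenerateGroupError
        If both SDs are zero (the measure is undefined).
    """
    if s0 < 0 or s1 < 0:
        raise ValueError("standard deviations must be non-negative")
    denom = math.hypot(s0, s1)
    if denom == 0.0:
        raise DegenerateGroupError("both group SDs are zero; d undefined")
    return abs(mu0 - mu1) / denom


def wmw_pvalue(values0, values1, exact_threshold: int = EXACT_WMW_THRESHOLD) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value for a median difference.

    Uses the exact null distribution when the combined sample is small
    (<= ``exact_threshold``) and tie-free; otherwise the normal
    approximation with tie and continuity corrections.  Degenerate data
    (every value identical across both groups) returns p = 1 with a
    warning.
    """
    g0, g1 = _drop_missing(values0), _drop_missing(values1)
    if g0.size == 0 or g1.size == 0:
        raise DegenerateGroupError("a group is empty; WMW undefined")
    combined = np.concatenate([g0, g1])
    if np.unique(combined).size == 1:
        logger.warning("all values identical across groups; WMW p set to 1")
        return 1.0
    has_ties = np.unique(combined).size < combined.size
    small = combined.size <= exact_threshold
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        g0, g1, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def significance_stars(p: float) -> str:
    """Rendered significance markers: * at 10%, ** at 5%, *** at 1%."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def indicator_report(
    cohort: Cohort | pd.DataFrame,
    indicators: Iterable[str] = INDICATOR_ORDER,
) -> list[GroupSummary]:
    """Per-indicator group summaries + WMW p + d for a labelled cohort.

    The cohort table must carry ``Y`` and the indicator columns (see
    :func:`cardioindex.indicators.add_indicators`).  Degenerate groups
    (e.g. a single-class cohort) yield NaN-filled rows rather than
    aborting the report.
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    out: list[GroupSummary] = []
    y = df["Y"]
    for ind in indicators:
        try:
            v0 = df.loc[y == 0, ind]
            v1 = df.loc[y == 1, ind]
            mom = summarize_groups(v0, v1)
            d = consistency_d(mom.mu0, mom.mu1, mom.s0, mom.s1)
            p = wmw_pvalue(v0, v1)
            out.append(GroupSummary(ind, *mom, p_wmw=p, d=d))
        except (DegenerateGroupError, KeyError) as exc:
            logger.warning("indicator %s: %s", ind, exc)
            nan = float("nan")
            out.append(GroupSummary(ind, nan, nan, nan, nan, nan, nan, nan, nan))
    return out


def report_frame(summaries: list[GroupSummary], stars: bool = False) -> pd.DataFrame:
    """Render summaries as a descriptive-statistics table (one indicator/row)."""
    rows = {}
    for s in summaries:
        p = f"{s.p_wmw:.4f}{significance_stars(s.p_wmw)}" if stars else s.p_wmw
        rows[s.indicator] = {
            "mu0": s.mu0, "mu1": s.mu1, "m0": s.m0, "m1": s.m1,
            "s0": s.s0, "s1": s.s1, "p": p, "d": s.d,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def d_matrix(reports: dict[str, list[GroupSummary]]) -> pd.DataFrame:
    """Consistency-measure matrix: one row per cohort, one column per indicator."""
    return pd.DataFrame(
        {name: {s.indicator: s.d for s in summaries} for name, summaries in reports.items()}
    ).T.reindex(columns=list(INDICATOR_ORDER))


def published_d_matrix(round_to: int | None = 4) -> pd.DataFrame:
    """Recompute the consistency matrix from the published group statistics.

    Applies :func:`consistency_d` to each (cohort, indicator) quadruple
    of published means/SDs; with ``round_to=4`` the result is directly
    comparable to the published d table.
    """
    from .reference import PUBLISHED_GROUP_STATS

    rows = {}
    for name, tbl in PUBLISHED_GROUP_STATS.items():
        rows[name] = {
            ind: consistency_d(r.mu0, r.mu1, r.s0, r.s1)
            for ind, r in tbl.iterrows()
        }
    out = pd.DataFrame(rows).T.reindex(columns=list(INDICATOR_ORDER))
    return out.round(round_to) if round_to is not None else out
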