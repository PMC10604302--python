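"""Campello de Souza (CS) hemodynamic indicators from cuff vitals.

Seven indicators are derived from a subject's systolic blood pressure
(SBP, mmHg), diastolic blood pressure (DBP, mmHg) and heart rate
(HR, beats/min):

``MAP``
    Mean arterial pressure as the time-average of an exponentially
    decaying pressure waveform over one beat, which has the closed form
    of the logarithmic mean, ``(SBP - DBP) / (ln SBP - ln DBP)``.
``RC``
    Time constant of the exponential decay — the product of peripheral
    resistance and arterial compliance, ``1 / (HR * ln(SBP/DBP))``.
    Only the product is identifiable from cuff vitals.
``PBPI``
    Pulsatile blood pressure index, pulse pressure normalised by DBP.
``PBPIRC``
    PBPI divided by RC.
``HM``
    A Kepler-law-inspired "harmony measure": squared beat frequency over
    the cubed gap between SBP and MAP.
``ALPHA``
    Ejection-time fraction of the cardiac cycle under a triangular
    pressure-wave model; the smaller root of
    ``alpha * (1 - alpha) * tau^2 = (SBP - DBP)^2`` with the beat period
    ``tau`` in milliseconds.
``ALPHA2``
    ``-ln(ALPHA)``, a variance-stabilising transform of ALPHA.

All functions are NumPy-vectorised; invalid inputs (``SBP <= DBP``,
non-positive pressures or rates, negative ALPHA discriminant) yield NaN
rather than raising, so that dirty clinical records flow through as
missing values.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order used throughout reports (the conventional table order).
INDICATOR_ORDER = ("ALPHA", "ALPHA2", "HM", "MAP", "PBPI", "PBPIRC", "RC")


@dataclass(frozen=True)
class UnitConventions:
    """Unit conventions for the indicator formulas.

    The defining formulas leave the time units open; these defaults are
    the ones under which the indicators have their conventional
    magnitudes (RC ~ 0.03, ALPHA ~ 0.003, HM ~ 30-200 on resting
    vitals).

    Parameters
    ----------
    rc_rate_scale
        Multiplier applied to HR (beats/min) in the RC denominator.
        1.0 means RC uses HR in beats/min directly.
    alpha_period_ms
        Numerator of the beat period used by ALPHA: tau = this / HR.
        60000.0 gives tau in milliseconds.
    hm_rate_scale
        Multiplier applied to HR inside the squared numerator of HM.
        1000/60 converts beats/min to beats-per-millisecond * 1000.
    """

    rc_rate_scale: float = 1.0
    alpha_period_ms: float = 60000.0
    hm_rate_scale: float = 1000.0 / 60.0


DEFAULT_UNITS = UnitConventions()


@dataclass(frozen=True)
class VitalSigns:
    """One subject's cuff vitals: SBP/DBP in mmHg, HR in beats/min."""

    sbp: float
    dbp: float
    hr: float

    @property
    def valid(self) -> bool:
        """True when the indicator math is defined (SBP > DBP > 0, HR > 0)."""
        return bool(
            np.isfinite(self.sbp)
            and np.isfinite(self.dbp)
            and np.isfinite(self.hr)
            and self.sbp > self.dbp > 0
            and self.hr > 0
        )

    @property
    def pulse_pressure(self) -> float:
        return self.sbp - self.dbp

    @property
    def period_minutes(self) -> float:
        """Beat period in minutes (the time unit of the default RC convention)."""
        return 1.0 / self.hr

    @property
    def period_ms(self) -> float:
        """Beat period tau in milliseconds, as used by the ALPHA model."""
        return DEFAULT_UNITS.alpha_period_ms / self.hr


@dataclass(frozen=True)
class IndicatorVector:
    """The seven CS indicators for one subject; undefined entries are NaN."""

    map: float
    rc: float
    pbpi: float
    pbpirc: float
    hm: float
    alpha: float
    alpha2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "MAP": self.map,
            "RC": self.rc,
            "PBPI": self.pbpi,
            "PBPIRC": self.pbpirc,
            "HM": self.hm,
            "ALPHA": self.alpha,
            "ALPHA2": self.alpha2,
        }


def _valid_mask(sbp, dbp, hr=None):
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    ok = np.isfinite(sbp) & np.isfinite(dbp) & (dbp > 0) & (sbp > dbp)
    if hr is not None:
        hr = np.asarray(hr, dtype=float)
        ok = ok & np.isfinite(hr) & (hr > 0)
    return ok


def _masked(values, ok):
    out = np.where(ok, values, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def compute_map(sbp, dbp):
    """Mean arterial pressure: the logarithmic mean of SBP and DBP (mmHg).

    Equals the time average of ``SBP * exp(-t/RC)`` over one beat.
    Undefined (NaN) unless ``sbp > dbp > 0``; equal pressures are a
    limit of the formula, not a valid input.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    ok = _valid_mask(sbp, dbp)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (sbp - dbp) / (np.log(sbp) - np.log(dbp))
    return _masked(val, ok)


def rc_product(sbp, dbp, hr, units: UnitConventions = DEFAULT_UNITS):
    """Resistance-compliance product ``1 / (HR * ln(SBP/DBP))``.

    HR is in beats/min under the default convention, which puts RC on
    its conventional ~0.03 scale for resting vitals.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    hr = np.asarray(hr, dtype=float)
    ok = _valid_mask(sbp, dbp, hr)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = 1.0 / (units.rc_rate_scale * hr * np.log(sbp / dbp))
    return _masked(val, ok)


def pressure_decay(vitals: VitalSigns, t, units: UnitConventions = DEFAULT_UNITS):
    """Windkessel-style diastolic decay ``P(t) = SBP * exp(-t / RC)``.

    ``t`` is in the RC convention's time unit (minutes by default, so
    one beat period is ``1/HR``).  By construction ``P(0) = SBP`` and
    ``P(1/HR) = DBP``.

    Raises
    ------
    ValueError
        If the vitals are invalid (SBP <= DBP, non-positive values) or
        ``t < 0``.
    """
    if not vitals.valid:
        raise ValueError(f"indicator math undefined for vitals {vitals}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    rc = rc_product(vitals.sbp, vitals.dbp, vitals.hr, units)
    out = vitals.sbp * np.exp(-t / rc)
    if out.ndim == 0:
        return float(out)
    return out


def compute_pbpi(sbp, dbp):
    """Pulsatile blood pressure index ``(SBP - DBP) / DBP`` (dimensionless)."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    ok = _valid_mask(sbp, dbp)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (sbp - dbp) / dbp
    return _masked(val, ok)


def compute_pbpirc(sbp, dbp, hr, units: UnitConventions = DEFAULT_UNITS):
    """PBPI divided by the RC product."""
    return _masked(
        compute_pbpi(sbp, dbp) / rc_product(sbp, dbp, hr, units),
        _valid_mask(sbp, dbp, hr),
    )


def compute_hm(sbp, dbp, hr, units: UnitConventions = DEFAULT_UNITS):
    """Harmony measure ``(1000 * HR / 60)^2 / (SBP - MAP)^3``.

    The Kepler-harmonic analogue: squared beat frequency over the cubed
    "semi-axis" SBP - MAP, with MAP the logarithmic-mean MAP.  The
    parenthesisation and rate scale are the ones under which the measure
    has its conventional magnitude (tens to hundreds on resting vitals).
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    hr = np.asarray(hr, dtype=float)
    ok = _valid_mask(sbp, dbp, hr)
    m = compute_map(sbp, dbp)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (units.hm_rate_scale * hr) ** 2 / (sbp - m) ** 3
    return _masked(val, ok)


def compute_alpha(sbp, dbp, hr, units: UnitConventions = DEFAULT_UNITS):
    """Ejection-time fraction from the triangular pressure-wave model.

    The smaller root of ``alpha * (1 - alpha) * tau^2 = (SBP - DBP)^2``
    with tau = 60000/HR milliseconds:

        alpha = 1/2 - (1/(2 tau)) * sqrt(tau^2 - 4 (SBP - DBP)^2)

    A negative discriminant (pulse pressure exceeding tau/2 in model
    units — physiologically extreme) yields NaN with a logged warning,
    never a clamped 0.5.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    hr = np.asarray(hr, dtype=float)
    ok = _valid_mask(sbp, dbp, hr)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = units.alpha_period_ms / hr
        disc = tau**2 - 4.0 * (sbp - dbp) ** 2
        neg = ok & (disc < 0)
        if np.any(neg):
            logger.warning(
                "alpha undefined for %d record(s): pulse pressure too large "
                "for the beat period (negative discriminant)",
                int(np.count_nonzero(neg)),
            )
        val = 0.5 - np.sqrt(np.where(disc >= 0, disc, np.nan)) / (2.0 * tau)
    return _masked(val, ok)


def compute_alpha2(alpha):
    """``-ln(alpha)`` for alpha in (0, 0.5]; NaN passes through as NaN.

    Raises
    ------
    ValueError
        If any finite alpha lies outside (0, 0.5].
    """
    alpha = np.asarray(alpha, dtype=float)
    finite = np.isfinite(alpha)
    if np.any(finite & ((alpha <= 0) | (alpha > 0.5))):
        raise ValueError("alpha must lie in (0, 0.5]")
    with np.errstate(divide="ignore", invalid="ignore"):
        val = -np.log(alpha)
    if val.ndim == 0:
        return float(val)
    return val


def compute_all(vitals: VitalSigns, units: UnitConventions = DEFAULT_UNITS) -> IndicatorVector:
    """All seven indicators for one subject; never raises on bad vitals.

    Invalid vitals, or a negative ALPHA discriminant, produce NaN in the
    affected fields (ALPHA2 inherits ALPHA's missingness).
    """
    if not vitals.valid:
        logger.debug("invalid vitals %s -> all-missing indicator vector", vitals)
        nan = float("nan")
        return IndicatorVector(nan, nan, nan, nan, nan, nan, nan)
    s, d, h = vitals.sbp, vitals.dbp, vitals.hr
    alpha = compute_alpha(s, d, h, units)
    alpha2 = compute_alpha2(alpha) if math.isfinite(alpha) else float("nan")
    return IndicatorVector(
        map=compute_map(s, d),
        rc=rc_product(s, d, h, units),
        pbpi=compute_pbpi(s, d),
        pbpirc=compute_pbpirc(s, d, h, units),
        hm=compute_hm(s, d, h, units),
        alpha=alpha,
        alpha2=alpha2,
    )


def add_indicators(
    df: pd.DataFrame,
    sbp: str = "sbp",
    dbp: str = "dbp",
    hr: str = "hr",
    units: UnitConventions = DEFAULT_UNITS,
) -> pd.DataFrame:
    """Return a copy of ``df`` with the seven indicator columns appended.

    Columns are named per :data:`INDICATOR_ORDER`; rows with invalid
    vitals get NaN indicators.
    """
    out = df.copy()
    s = out[sbp].to_numpy(dtype=float)
    d = out[dbp].to_numpy(dtype=float)
    h = out[hr].to_numpy(dtype=float)
    alpha = compute_alpha(s, d, h, units)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        alpha2 = np.where(np.isfinite(alpha), -np.log(alpha), np.nan)
    out["ALPHA"] = alpha
    out["ALPHA2"] = alpha2
    out["HM"] = compute_hm(s, d, h, units)
    out["MAP"] = compute_map(s, d)
    out["PBPI"] = compute_pbpi(s, d)
    out["PBPIRC"] = compute_pbpirc(s, d, h, units)
    out["RC"] = rc_product(s, d, h, units)
    return out
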