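"""Indicator math: worked examples, model-consistency oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from cardioindex.indicators import (
    VitalSigns,
    add_indicators,
    compute_all,
    compute_alpha,
    compute_alpha2,
    compute_hm,
    compute_map,
    compute_pbpi,
    compute_pbpirc,
    pressure_decay,
    rc_product,
)

import pandas as pd


def valid_vitals():
    """Physiologically plausible vitals; the alpha discriminant is positive."""
    return st.tuples(
        st.floats(25.0, 130.0),   # dbp
        st.floats(10.0, 120.0),   # pulse pressure
        st.floats(40.0, 140.0),   # hr
    ).map(lambda t: VitalSigns(sbp=t[0] + t[1], dbp=t[0], hr=t[2]))


class TestWorkedExamples:
    @pytest.mark.parametrize("sbp,dbp,expected", [
        (120, 80, 40 / math.log(1.5)),
        (150, 100, 50 / math.log(1.5)),
    ])
    def test_map_closed_form(self, sbp, dbp, expected):
        assert compute_map(sbp, dbp) == pytest.approx(expected, rel=1e-12)

    def test_map_equal_pressures_is_a_limit_not_an_input(self):
        assert math.isnan(compute_map(100, 100))
        # the logarithmic-mean limit: MAP -> x as dbp -> sbp = x
        assert compute_map(100, 100 - 1e-6) == pytest.approx(100, rel=1e-6)

    @pytest.mark.parametrize("sbp,dbp,hr,expected", [
        (120, 80, 70, 1 / (70 * math.log(1.5))),
        (120, 80, 140, 1 / (140 * math.log(1.5))),  # doubling HR halves RC
        (160, 80, 60, 1 / (60 * math.log(2))),
    ])
    def test_rc_product(self, sbp, dbp, hr, expected):
        assert rc_product(sbp, dbp, hr) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("sbp,dbp,expected", [
        (120, 80, 0.5), (180, 90, 1.0), (100, 100 - 1e-9, 1e-11),
    ])
    def test_pbpi(self, sbp, dbp, expected):
        assert compute_pbpi(sbp, dbp) == pytest.approx(expected, abs=1e-9)

    def test_pbpirc_is_linear_in_hr(self):
        assert compute_pbpirc(120, 80, 70) == pytest.approx(14.1913, abs=1e-4)
        assert compute_pbpirc(120, 80, 140) == pytest.approx(
            2 * compute_pbpirc(120, 80, 70), rel=1e-12)

    @pytest.mark.parametrize("sbp,dbp,hr,expected", [
        (120, 80, 70, 139.904), (140, 90, 60, 51.748),
    ])
    def test_hm_magnitude(self, sbp, dbp, hr, expected):
        assert compute_hm(sbp, dbp, hr) == pytest.approx(expected, abs=1e-3)

    def test_hm_monotonicity(self):
        # decreasing in pulse pressure at fixed hr, increasing in hr
        hms_pp = [compute_hm(100 + pp, 100, 70) for pp in (20, 40, 60)]
        assert hms_pp[0] > hms_pp[1] > hms_pp[2]
        hms_hr = [compute_hm(120, 80, hr) for hr in (50, 70, 90)]
        assert hms_hr[0] < hms_hr[1] < hms_hr[2]

    def test_alpha_reference_value(self):
        assert compute_alpha(120, 80, 70) == pytest.approx(0.0021825, abs=1e-6)

    def test_alpha_boundaries(self):
        # vanishing pulse pressure -> alpha -> 0
        assert compute_alpha(100.001, 100, 70) == pytest.approx(0.0, abs=1e-6)
        # tau = 2*(sbp-dbp): zero discriminant -> alpha = 0.5
        hr = 60000 / (2 * 40)  # tau = 80 ms
        assert compute_alpha(120, 80, hr) == pytest.approx(0.5, abs=1e-12)

    def test_alpha_negative_discriminant_is_missing(self):
        # pulse pressure 300 mmHg vs tau 400 ms: discriminant < 0
        assert math.isnan(compute_alpha(400, 100, 150))

    def test_alpha2(self):
        assert compute_alpha2(0.0021825) == pytest.approx(-math.log(0.0021825))
        assert compute_alpha2(0.5) == pytest.approx(math.log(2), rel=1e-12)
        with pytest.raises(ValueError):
            compute_alpha2(0.6)
        with pytest.raises(ValueError):
            compute_alpha2(0.0)


class TestPressureDecay:
    def test_endpoints(self):
        v = VitalSigns(120, 80, 70)
        assert pressure_decay(v, 0.0) == pytest.approx(120, rel=1e-12)
        assert pressure_decay(v, v.period_minutes) == pytest.approx(80, rel=1e-10)

    def test_half_period(self):
        v = VitalSigns(120, 80, 70)
        assert pressure_decay(v, v.period_minutes / 2) == pytest.approx(
            120 / math.sqrt(1.5), rel=1e-10)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            pressure_decay(VitalSigns(80, 120, 70), 0.0)
        with pytest.raises(ValueError):
            pressure_decay(VitalSigns(120, 80, 70), -1.0)


class TestModelConsistency:
    """The defining relations tie the indicators to the decay model."""

    @settings(max_examples=200, deadline=None)
    @given(valid_vitals())
    def test_map_is_time_average_of_decay(self, v):
        tau = v.period_minutes
        integral, _ = quad(lambda t: pressure_decay(v, t), 0, tau, epsrel=1e-12)
        assert compute_map(v.sbp, v.dbp) == pytest.approx(integral / tau, rel=1e-8)

    @settings(max_examples=200, deadline=None)
    @given(valid_vitals())
    def test_decay_reaches_dbp_at_period_end(self, v):
        assert pressure_decay(v, v.period_minutes) == pytest.approx(v.dbp, rel=1e-10)

    @settings(max_examples=300, deadline=None)
    @given(valid_vitals())
    def test_map_ordering(self, v):
        m = compute_map(v.sbp, v.dbp)
        assert v.dbp < m < v.sbp
        assert m <= (v.sbp + v.dbp) / 2 + 1e-9

    @settings(max_examples=300, deadline=None)
    @given(valid_vitals())
    def test_alpha_satisfies_its_quadratic_and_is_the_smaller_root(self, v):
        a = compute_alpha(v.sbp, v.dbp, v.hr)
        tau = v.period_ms
        assert a * (1 - a) * tau**2 == pytest.approx(
            (v.sbp - v.dbp) ** 2, rel=1e-8)
        assert 0 < a <= 0.5  # the larger root is 1 - a >= 0.5

    @settings(max_examples=100, deadline=None)
    @given(valid_vitals())
    def test_alpha2_round_trip(self, v):
        a = compute_alpha(v.sbp, v.dbp, v.hr)
        assert math.exp(-compute_alpha2(a)) == pytest.approx(a, rel=1e-12)


class TestComposition:
    def test_compute_all_composes_the_pieces(self):
        vec = compute_all(VitalSigns(120, 80, 70))
        assert vec.map == pytest.approx(40 / math.log(1.5))
        assert vec.rc == pytest.approx(1 / (70 * math.log(1.5)))
        assert vec.pbpi == pytest.approx(0.5)
        assert vec.pbpirc == pytest.approx(vec.pbpi / vec.rc)
        assert vec.hm == pytest.approx(139.904, abs=1e-3)
        assert vec.alpha == pytest.approx(0.0021825, abs=1e-6)
        assert vec.alpha2 == pytest.approx(-math.log(vec.alpha))

    @pytest.mark.parametrize("vitals", [
        VitalSigns(0, 0, 0),
        VitalSigns(80, 120, 70),   # inverted pressures
        VitalSigns(120, 80, -5),   # negative rate
        VitalSigns(float("nan"), 80, 70),
    ])
    def test_invalid_vitals_give_all_missing_never_raise(self, vitals):
        vec = compute_all(vitals)
        assert all(math.isnan(x) for x in vec.as_dict().values())

    def test_median_equivariance_of_alpha2(self):
        # alpha2 = -ln(alpha) is strictly decreasing, so on odd samples
        # median(alpha2) = -ln(median(alpha)) exactly
        rng = np.random.default_rng(5)
        dbp = rng.uniform(60, 100, 201)
        pp = rng.uniform(20, 80, 201)
        hr = rng.uniform(50, 110, 201)
        a = compute_alpha(dbp + pp, dbp, hr)
        a2 = compute_alpha2(a)
        assert np.median(a2) == -np.log(np.median(a))

    def test_add_indicators_columns_and_missingness(self):
        df = pd.DataFrame({
            "sbp": [120.0, 80.0, 150.0], "dbp": [80.0, 120.0, 100.0],
            "hr": [70.0, 70.0, 0.0],
        })
        out = add_indicators(df)
        for col in ("MAP", "RC", "PBPI", "PBPIRC", "HM", "ALPHA", "ALPHA2"):
            assert col in out.columns
        assert out.loc[0, "MAP"] == pytest.approx(40 / math.log(1.5))
        assert math.isnan(out.loc[1, "MAP"])         # inverted pressures
        # hr = 0 invalidates the rate-dependent indicators only
        assert out.loc[2, "MAP"] == pytest.approx(50 / math.log(1.5))
        assert math.isnan(out.loc[2, "RC"])
        assert math.isnan(out.loc[2, "ALPHA"])
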