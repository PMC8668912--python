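"""Unit and property tests for the dialyzer transport model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dialflux import (
    DialyzerParams,
    FlowSetting,
    clearance,
    estimate_sieving,
    percent_change,
    single_pass,
)
from dialflux.exceptions import InvalidInputError, UndefinedInputError

from .conftest import random_flows, random_params
from .oracles import bvp_countercurrent_clearance


class TestFlowSetting:
    def test_unit_conversion_is_exact(self):
        fs = FlowSetting(qb=150.0, qd_ml_h=2000.0)
        assert fs.qd == 2000.0 / 60.0

    @pytest.mark.parametrize("qb,qd_h", [(0, 1000), (-10, 1000), (100, 0), (100, -5)])
    def test_nonpositive_flows_rejected(self, qb, qd_h):
        with pytest.raises(InvalidInputError):
            FlowSetting(qb=qb, qd_ml_h=qd_h)

    def test_arbitrary_positive_flows_accepted(self):
        FlowSetting(qb=37.2, qd_ml_h=123.4)


class TestDialyzerParams:
    def test_symmetric_membrane_default(self):
        p = DialyzerParams(k0a=100.0)
        assert p.alpha_backfiltration == 1.0
        assert p.permeability_reduction == 0.0

    def test_effective_k0a_scaling(self):
        p = DialyzerParams(k0a=100.0, permeability_reduction=0.25)
        assert p.effective_k0a == 75.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k0a": -1.0},
            {"k0a": 10, "sieving_membrane": 0.0},
            {"k0a": 10, "sieving_membrane": 1.5},
            {"k0a": 10, "alpha_backfiltration": 0.0},
            {"k0a": 10, "permeability_reduction": 1.0},
            {"k0a": 10, "geometry": "crosscurrent"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(InvalidInputError):
            DialyzerParams(**kwargs)


class TestClearance:
    def test_zero_k0a_gives_zero_clearance(self):
        fs = FlowSetting(qb=100.0, qd_ml_h=1000.2)  # qd ~ 16.67 ml/min
        assert clearance(fs, DialyzerParams(k0a=0.0)) == 0.0

    def test_infinite_k0a_saturates_at_min_flow(self):
        fs = FlowSetting(qb=200.0, qd_ml_h=1000.2)
        k = clearance(fs, DialyzerParams(k0a=1e6))
        assert k == pytest.approx(min(fs.qb, fs.qd), rel=1e-9)

    def test_midgrid_value_matches_bvp_oracle(self):
        # frozen from the countercurrent two-stream BVP at qb=150 ml/min,
        # qd=2000 ml/h, k0a=50 ml/min (oracles.bvp_countercurrent_clearance)
        fs = FlowSetting(qb=150.0, qd_ml_h=2000.0)
        k = clearance(fs, DialyzerParams(k0a=50.0))
        assert k == pytest.approx(24.659694387995764, rel=1e-12)

    def test_bvp_oracle_agreement_on_grid(self):
        """Closed form vs numerical countercurrent BVP on a 5x5x5 grid."""
        qbs = np.linspace(50.0, 400.0, 5)
        qds = np.linspace(10.0, 80.0, 5)  # ml/min
        k0as = np.geomspace(5.0, 500.0, 5)
        for qb in qbs:
            for qd in qds:
                for k0a in k0as:
                    fs = FlowSetting(qb=qb, qd_ml_h=qd * 60.0)
                    k_closed = clearance(fs, DialyzerParams(k0a=k0a))
                    k_bvp = bvp_countercurrent_clearance(qb, qd, k0a)
                    assert k_closed == pytest.approx(k_bvp, rel=1e-6)

    def test_small_k0a_limit(self):
        # relative deviation from the linear limit K -> k0a*(1-pr)*s is O(N),
        # N = k0a(1-pr)/qb, so the limit is checked deep in the linear regime
        for qb, qd_h in [(100.0, 2000.0), (200.0, 1000.0), (150.0, 3000.0)]:
            fs = FlowSetting(qb=qb, qd_ml_h=qd_h)
            k0a = 1e-8 * qb
            p = DialyzerParams(k0a=k0a, sieving_membrane=0.9, permeability_reduction=0.1)
            expected = k0a * (1 - 0.1) * 0.9
            assert clearance(fs, p) == pytest.approx(expected, rel=1e-6)

    def test_continuity_at_equal_flows(self):
        qb = 100.0
        p = DialyzerParams(k0a=80.0)
        k_eq = clearance(FlowSetting(qb=qb, qd_ml_h=qb * 60.0), p)
        for sign in (+1, -1):
            fs = FlowSetting(qb=qb, qd_ml_h=qb * 60.0 * (1 + sign * 1e-6))
            assert abs(clearance(fs, p) - k_eq) < 1e-6 * qb

    def test_monotone_in_flows_and_k0a(self, rng):
        for _ in range(200):
            qb = rng.uniform(50, 300)
            qd_h = rng.uniform(500, 6000)
            k0a = rng.uniform(1, 500)
            base = clearance(FlowSetting(qb, qd_h), DialyzerParams(k0a=k0a))
            up_qb = clearance(FlowSetting(qb * 1.3, qd_h), DialyzerParams(k0a=k0a))
            up_qd = clearance(FlowSetting(qb, qd_h * 1.3), DialyzerParams(k0a=k0a))
            up_k = clearance(FlowSetting(qb, qd_h), DialyzerParams(k0a=k0a * 1.3))
            assert up_qb >= base - 1e-12
            assert up_qd >= base - 1e-12
            assert up_k >= base - 1e-12

    def test_bounds_zero_to_min_flow(self, rng):
        for _ in range(300):
            fs = random_flows(rng)
            p = random_params(rng)
            k = clearance(fs, p)
            assert 0.0 <= k <= min(fs.qb, fs.qd) * (1 + 1e-12)

    def test_no_overflow_at_extreme_k0a(self):
        fs = FlowSetting(qb=100.0, qd_ml_h=60000.0)  # qd = 1000 ml/min, R << 1
        k = clearance(fs, DialyzerParams(k0a=1e9))
        assert k == pytest.approx(100.0)
        assert math.isfinite(k)

    def test_cocurrent_saturates_at_harmonic_flow(self):
        fs = FlowSetting(qb=100.0, qd_ml_h=6000.0)  # qd = 100 ml/min
        k = clearance(fs, DialyzerParams(k0a=1e7, geometry="cocurrent"))
        assert k == pytest.approx(fs.qb * fs.qd / (fs.qb + fs.qd), rel=1e-9)

    def test_countercurrent_beats_cocurrent(self, rng):
        for _ in range(50):
            fs = random_flows(rng)
            k0a = float(rng.uniform(10, 300))
            kc = clearance(fs, DialyzerParams(k0a=k0a))
            kp = clearance(fs, DialyzerParams(k0a=k0a, geometry="cocurrent"))
            assert kc >= kp - 1e-12


class TestSinglePass:
    @settings(max_examples=300, derandomize=True)
    @given(
        qb=st.floats(20.0, 500.0),
        qd_h=st.floats(200.0, 10000.0),
        k0a=st.floats(0.0, 1000.0),
        s=st.floats(0.3, 1.0),
        alpha=st.floats(0.2, 3.0),
        c_al=st.floats(0.0, 100.0),
        cd=st.floats(0.0, 100.0),
    )
    def test_mass_balance_property(self, qb, qd_h, k0a, s, alpha, c_al, cd):
        """qb*(c_al - c_rl) == qd*(c_el - cd_in) to 1e-12 relative."""
        fs = FlowSetting(qb=qb, qd_ml_h=qd_h)
        p = DialyzerParams(k0a=k0a, sieving_membrane=s, alpha_backfiltration=alpha)
        r = single_pass(c_al, cd, fs, p)
        lhs = fs.qb * (r.c_al - r.c_rl)
        rhs = fs.qd * (r.c_el - r.cd_in)
        # normalized by the stream mass flows: the flux itself can be
        # arbitrarily small relative to float resolution of the streams
        scale = max(fs.qb * c_al, fs.qd * cd, abs(lhs), abs(rhs), 1e-300)
        assert abs(lhs - rhs) <= 1e-12 * scale

    def test_return_line_between_inlet_and_dialysate(self, rng):
        for _ in range(300):
            fs = random_flows(rng)
            p = random_params(rng)
            c_al, cd = rng.uniform(0, 80, size=2)
            r = single_pass(float(c_al), float(cd), fs, p)
            lo, hi = min(c_al, cd), max(c_al, cd)
            assert lo - 1e-12 <= r.c_rl <= hi + 1e-12
            assert lo - 1e-12 <= r.c_el <= hi + 1e-12

    def test_equilibrium_dialysate_eliminates_loss(self, default_params):
        """Enriching the dialysate to the circulating level removes the gradient."""
        for qb in (100.0, 150.0, 200.0):
            for qd_h in (1000.0, 2000.0, 3000.0):
                r = single_pass(16.0, 16.0, FlowSetting(qb, qd_h), default_params)
                assert r.c_rl == 16.0
                assert r.c_el == 16.0

    def test_zero_clearance_is_identity(self, mid_flows):
        r = single_pass(5.0, 3.0, mid_flows, DialyzerParams(k0a=0.0))
        assert r.c_rl == 5.0
        assert r.c_el == 3.0

    def test_published_maximum_loss_reproduces_end_concentration(self):
        """A 35.6% per-pass loss takes 16 mg/L to ~10 mg/L."""
        fs = FlowSetting(qb=100.0, qd_ml_h=3000.0)
        # K/qb = 0.356 -> K = 35.6 ml/min at qb = 100
        from dialflux import invert_clearance

        k0a = invert_clearance(35.6, fs)
        r = single_pass(16.0, 0.0, fs, DialyzerParams(k0a=k0a))
        assert r.c_rl == pytest.approx(10.304, abs=1e-9)
        assert round(r.c_rl) == 10

    def test_backfiltration_asymmetry_only_affects_gain_direction(self, mid_flows):
        sym = DialyzerParams(k0a=20.0)
        asym = DialyzerParams(k0a=20.0, alpha_backfiltration=1.2)
        loss_s = single_pass(16.0, 0.0, mid_flows, sym)
        loss_a = single_pass(16.0, 0.0, mid_flows, asym)
        assert loss_a.c_rl == loss_s.c_rl
        gain_s = single_pass(16.0, 64.0, mid_flows, sym)
        gain_a = single_pass(16.0, 64.0, mid_flows, asym)
        assert gain_a.c_rl > gain_s.c_rl
        assert gain_a.clearance == pytest.approx(1.2 * gain_s.clearance)

    def test_backfiltration_clearance_capped_at_min_flow(self, mid_flows):
        p = DialyzerParams(k0a=1e5, alpha_backfiltration=10.0)
        r = single_pass(16.0, 64.0, mid_flows, p)
        assert r.clearance <= min(mid_flows.qb, mid_flows.qd) + 1e-9

    def test_zero_inlet_extraction_undefined_not_zero(self, mid_flows, default_params):
        r = single_pass(0.0, 16.0, mid_flows, default_params)
        assert r.extraction is None
        with pytest.raises(UndefinedInputError):
            percent_change(r)

    def test_negative_concentration_rejected(self, mid_flows, default_params):
        with pytest.raises(InvalidInputError):
            single_pass(-1.0, 0.0, mid_flows, default_params)


class TestPercentChange:
    @pytest.mark.parametrize(
        "c_al,c_rl,expected",
        [
            (16.0, 10.304, -35.6),  # published maximum per-pass loss
            (16.0, 16.0, 0.0),  # equilibrium dialysate
            (16.0, 28.608, 78.8),  # published maximum enrichment gain
            (16.0, 18.992, 18.7),  # published minimum enrichment gain
        ],
    )
    def test_signed_percent_convention(self, c_al, c_rl, expected):
        from dialflux import PassResult

        r = PassResult(c_al=c_al, c_rl=c_rl, c_el=0.0, cd_in=0.0, clearance=0.0)
        assert percent_change(r) == pytest.approx(expected, abs=1e-9)


class TestEstimateSieving:
    def test_saturation_regime_unhindered(self):
        """Effluent equilibrates fully with inlet blood: apparent sieving ~ 1.0."""
        fs = FlowSetting(qb=200.0, qd_ml_h=1000.0)
        r = single_pass(16.0, 0.0, fs, DialyzerParams(k0a=1e4, sieving_membrane=1.0))
        assert estimate_sieving(r.c_el, r.c_al) == pytest.approx(1.0, abs=1e-3)

    def test_saturation_regime_hindered_membrane(self):
        fs = FlowSetting(qb=200.0, qd_ml_h=1000.0)
        r = single_pass(16.0, 0.0, fs, DialyzerParams(k0a=1e4, sieving_membrane=0.93))
        assert estimate_sieving(r.c_el, r.c_al) == pytest.approx(0.93, abs=1e-3)

    def test_identity_ratio(self):
        assert estimate_sieving(12.0, 12.0) == 1.0

    def test_zero_inlet_rejected(self):
        with pytest.raises(UndefinedInputError):
            estimate_sieving(1.0, 0.0)
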