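"""Unit and property tests for the EPG/isochromat signal engine."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ulfmt.signal_model import (
    ConvergenceError,
    EPGState,
    FieldConditions,
    SequenceProtocol,
    TissueParams,
    bound_pool_saturation_factor,
    default_flip_angles,
    default_pulse_widths,
    epg_rf_rotation,
    flip_angle_sweep,
    isochromat_oracle,
    predict_mtr,
    pulse_width_sweep,
    relax_exchange_interval,
    ssfp_steady_state,
)


def random_state(rng, n_states=8):
    state = EPGState.equilibrium(TissueParams(t1_free=500, t2_free=100), n_states)
    shape = state.f_plus.shape
    fp = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    fm = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    fm[0] = fp[0]
    z = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    z[0] = rng.standard_normal()  # order-0 longitudinal stays real
    return EPGState(fp, fm, z, 0.0)


class TestRFRotation:
    def test_zero_flip_is_identity(self, rng):
        state = random_state(rng)
        out = epg_rf_rotation(state, 0.0)
        np.testing.assert_allclose(out.f_plus, state.f_plus)
        np.testing.assert_allclose(out.z_free, state.z_free)

    def test_inversion_from_equilibrium(self, single_pool):
        state = EPGState.equilibrium(single_pool, 8)
        out = epg_rf_rotation(state, 180.0)
        assert out.z_free[0] == pytest.approx(-single_pool.m0_free, abs=1e-12)
        assert np.allclose(out.f_plus, 0.0)
        assert np.allclose(out.f_minus, 0.0)

    def test_matches_explicit_rotation_matrix(self, rng):
        """Per-order mixing equals a 3x3 matrix built from the Cartesian rotation."""
        alpha = math.radians(37.0)
        # basis change (Mx, My, Mz) -> (M+, M-, Mz) conjugating a rotation about x
        b = np.array([[1, 1j, 0], [1, -1j, 0], [0, 0, 1]], dtype=complex)
        rx = np.array(
            [
                [1, 0, 0],
                [0, math.cos(alpha), math.sin(alpha)],
                [0, -math.sin(alpha), math.cos(alpha)],
            ]
        )
        t_oracle = b @ rx @ np.linalg.inv(b)

        state = random_state(rng)
        out = epg_rf_rotation(state, 37.0)
        for k in range(state.n_states + 1):
            vec = np.array([state.f_plus[k], np.conj(state.f_minus[k]), state.z_free[k]])
            expected = t_oracle @ vec
            np.testing.assert_allclose(out.f_plus[k], expected[0], atol=1e-12)
            np.testing.assert_allclose(np.conj(out.f_minus[k]), expected[1], atol=1e-12)
            np.testing.assert_allclose(out.z_free[k], expected[2], atol=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(a=st.floats(-360, 360), b=st.floats(-360, 360))
    def test_rotation_composition(self, a, b):
        rng = np.random.default_rng(7)
        state = random_state(rng)
        seq = epg_rf_rotation(epg_rf_rotation(state, a), b)
        direct = epg_rf_rotation(state, a + b)
        np.testing.assert_allclose(seq.f_plus, direct.f_plus, atol=1e-9)
        np.testing.assert_allclose(seq.z_free, direct.z_free, atol=1e-9)

    def test_bound_pool_untouched(self, rng):
        state = random_state(rng)
        state.z_bound = 0.37
        out = epg_rf_rotation(state, 123.0)
        assert out.z_bound == 0.37


class TestSaturationFactor:
    def test_no_flip_no_saturation(self, wm_like):
        assert bound_pool_saturation_factor(0.0, 220.0, wm_like) == 1.0

    def test_quadratic_in_flip_angle(self, wm_like):
        f1 = bound_pool_saturation_factor(45.0, 220.0, wm_like)
        f2 = bound_pool_saturation_factor(90.0, 220.0, wm_like)
        assert math.log(f2) == pytest.approx(4.0 * math.log(f1), rel=1e-12)

    @pytest.mark.parametrize("flip,expected", [(300.0, 0.2098), (60.0, 0.9394)])
    def test_gaussian_lineshape_values(self, flip, expected):
        """Frozen values of exp(-pi (a/tau)^2 (T2b/sqrt(2 pi)) tau) for T2b = 10 us."""
        tissue = TissueParams(
            t1_free=500, t2_free=100, bound_fraction=0.1, exchange_rate=20, t2_bound=10.0
        )
        assert bound_pool_saturation_factor(flip, 220.0, tissue) == pytest.approx(
            expected, abs=5e-4
        )

    def test_super_lorentzian_finite_and_stronger(self):
        gauss = TissueParams(t1_free=500, t2_free=100, bound_fraction=0.1,
                             exchange_rate=20, lineshape="gaussian")
        sl = TissueParams(t1_free=500, t2_free=100, bound_fraction=0.1,
                          exchange_rate=20, lineshape="super_lorentzian")
        fg = bound_pool_saturation_factor(300.0, 220.0, gauss)
        fs = bound_pool_saturation_factor(300.0, 220.0, sl)
        assert 0 < fs <= 1 and 0 < fg <= 1
        # on-resonance super-Lorentzian (cutoff-evaluated) exceeds the Gaussian G(0)
        assert fs < fg

    def test_rejects_bad_inputs(self, wm_like):
        with pytest.raises(ValueError):
            bound_pool_saturation_factor(60.0, 0.0, wm_like)
        with pytest.raises(ValueError):
            bound_pool_saturation_factor(-5.0, 220.0, wm_like)


class TestRelaxExchange:
    def test_zero_interval_is_identity(self, rng, wm_like):
        state = random_state(rng)
        state.z_bound = 0.05
        out = relax_exchange_interval(state, 0.0, wm_like)
        np.testing.assert_allclose(out.f_plus, state.f_plus, atol=1e-12)
        np.testing.assert_allclose(out.z_free, state.z_free, atol=1e-12)
        assert out.z_bound == pytest.approx(0.05, abs=1e-12)

    def test_equilibrium_is_fixed_point(self, wm_like):
        state = EPGState.equilibrium(wm_like, 8)
        out = relax_exchange_interval(state, 57.0, wm_like)
        assert out.z_free[0] == pytest.approx(wm_like.m0_free, rel=1e-12)
        assert complex(out.z_bound).real == pytest.approx(wm_like.m0_bound, rel=1e-12)

    def test_monoexponential_recovery_without_exchange(self):
        tissue = TissueParams(t1_free=500, t2_free=100, bound_fraction=0.0)
        state = EPGState.equilibrium(tissue, 8)
        state.z_free[0] = 0.0
        dt = 123.0
        out = relax_exchange_interval(state, dt, tissue)
        expected = tissue.m0_free * (1.0 - math.exp(-dt / tissue.t1_free))
        assert complex(out.z_free[0]).real == pytest.approx(expected, rel=1e-12)

    def test_negative_dt_rejected(self, wm_like):
        with pytest.raises(ValueError):
            relax_exchange_interval(EPGState.equilibrium(wm_like, 8), -1.0, wm_like)


class TestSteadyState:
    def test_vanishing_flip_gives_vanishing_signal(self, single_pool):
        """Both observables vanish with the excitation (FID ~ alpha, echo faster)."""
        alpha = 1e-3
        sig = ssfp_steady_state(SequenceProtocol(flip_angle=alpha), single_pool)
        assert sig.s_fid <= 2.0 * math.radians(alpha) * single_pool.proton_density
        assert sig.s_echo < 1e-10

    @pytest.mark.parametrize("alpha", [30.0, 60.0, 150.0])
    def test_single_pool_mirror_symmetry(self, single_pool, alpha):
        lo = ssfp_steady_state(SequenceProtocol(flip_angle=alpha), single_pool)
        hi = ssfp_steady_state(SequenceProtocol(flip_angle=360.0 - alpha), single_pool)
        assert lo.s_echo == pytest.approx(hi.s_echo, rel=1e-9)

    def test_two_pool_matches_isochromat_oracle(self, wm_like):
        protocol = SequenceProtocol(flip_angle=60.0)
        epg = ssfp_steady_state(protocol, wm_like)
        oracle = isochromat_oracle(protocol, wm_like, n_isochromats=2000)
        assert epg.s_echo == pytest.approx(oracle.s_echo, rel=1e-3)
        assert epg.s_fid == pytest.approx(oracle.s_fid, rel=1e-3)

    def test_steady_state_unique_from_random_states(self, wm_like, rng):
        protocol = SequenceProtocol(flip_angle=80.0)
        ref = ssfp_steady_state(protocol, wm_like)
        for _ in range(2):
            init = random_state(rng, protocol.n_epg_states)
            init.z_bound = abs(rng.standard_normal()) * 0.1
            sig = ssfp_steady_state(protocol, wm_like, initial_state=init)
            assert sig.s_echo == pytest.approx(ref.s_echo, rel=1e-9)
            assert sig.s_fid == pytest.approx(ref.s_fid, rel=1e-9)

    def test_oracle_null_at_180_single_pool(self, single_pool):
        sig = isochromat_oracle(SequenceProtocol(flip_angle=180.0), single_pool,
                                n_isochromats=500)
        ref = isochromat_oracle(SequenceProtocol(flip_angle=60.0), single_pool,
                                n_isochromats=500)
        assert sig.s_echo <= 1e-8 * ref.s_echo

    def test_oracle_convergence_with_isochromat_count(self, wm_like):
        """Oracle-EPG agreement improves as the isochromat count grows.

        With n isochromats the dephasing circle is sampled at n points, so
        configuration orders alias with period n; once n exceeds the retained
        EPG orders the error is at the numerical floor.
        """
        protocol = SequenceProtocol(flip_angle=70.0)
        epg = ssfp_steady_state(protocol, wm_like)
        errs = []
        for n in (8, 64, 2000):
            o = isochromat_oracle(protocol, wm_like, n_isochromats=n)
            errs.append(abs(o.s_echo - epg.s_echo) / epg.s_echo)
        assert errs[0] > errs[1] >= errs[2] or errs[1] < 1e-9
        assert errs[2] < 1e-9

    def test_truncation_insensitive(self, wm_like):
        base = ssfp_steady_state(SequenceProtocol(flip_angle=60.0), wm_like)
        fine = ssfp_steady_state(
            SequenceProtocol(flip_angle=60.0, n_epg_states=80), wm_like
        )
        assert base.s_echo == pytest.approx(fine.s_echo, rel=1e-6)


class TestSweeps:
    def test_default_flip_angle_grid_has_43_entries(self):
        assert default_flip_angles().size == 43

    def test_default_pulse_width_grid_has_10_entries(self):
        assert default_pulse_widths().size == 10

    def test_water_curve_symmetric(self, presets):
        curve = flip_angle_sweep(None, presets.protocol, presets.tissues["water"])
        x, s = curve.x_values, curve.signals
        smax = s.max()
        for a in np.arange(10.0, 351.0, 10.0):
            i = np.nonzero(x == a)[0][0]
            j = np.nonzero(x == 360.0 - a)[0][0]
            assert abs(s[i] - s[j]) / smax < 1e-6

    def test_bound_pool_curve_asymmetric(self, presets):
        curve = flip_angle_sweep(None, presets.protocol,
                                 presets.tissues["conditioner_like"])
        x, s = curve.x_values, curve.signals
        s60 = s[np.nonzero(x == 60.0)[0][0]]
        s300 = s[np.nonzero(x == 300.0)[0][0]]
        assert s60 > s300

    def test_pulse_width_invariance_without_bound_pool(self, protocol, single_pool):
        curve = pulse_width_sweep(None, protocol, single_pool)
        spread = (curve.signals.max() - curve.signals.min()) / curve.signals.max()
        assert spread < 1e-6

    def test_pulse_width_monotone_with_bound_pool(self, presets):
        curve = pulse_width_sweep(None, presets.protocol,
                                  presets.tissues["conditioner_like"])
        assert np.all(np.diff(curve.signals) > 0)

    def test_pulse_width_must_stay_below_tr(self, protocol, single_pool):
        with pytest.raises(ValueError, match="< TR"):
            pulse_width_sweep([40.0, 13000.0], protocol, single_pool)


class TestPredictMtr:
    def test_zero_for_single_pool(self, protocol, single_pool):
        assert predict_mtr((60.0, 300.0), protocol, single_pool) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_matches_isochromat_oracle(self, protocol, wm_like):
        mtr = predict_mtr((60.0, 300.0), protocol, wm_like)
        o_low = isochromat_oracle(
            replace(protocol, flip_angle=60.0), wm_like, n_isochromats=2000
        )
        o_high = isochromat_oracle(
            replace(protocol, flip_angle=300.0), wm_like, n_isochromats=2000
        )
        oracle_mtr = (o_low.s_echo - o_high.s_echo) / o_low.s_echo * 100.0
        assert mtr == pytest.approx(oracle_mtr, abs=0.1)


class TestValidation:
    def test_tissue_invariants(self):
        with pytest.raises(ValueError, match="t1_free"):
            TissueParams(t1_free=-1, t2_free=100)
        with pytest.raises(ValueError, match="bound_fraction"):
            TissueParams(t1_free=500, t2_free=100, bound_fraction=1.0)

    def test_protocol_invariants(self):
        with pytest.raises(ValueError, match="flip_angle"):
            SequenceProtocol(flip_angle=421.0)
        with pytest.raises(ValueError, match="pulse_width"):
            SequenceProtocol(pulse_width=13000.0)
        with pytest.raises(ValueError, match="integer"):
            SequenceProtocol(fov=(181.0, 220.0, 200.0))

    def test_field_invariants(self):
        with pytest.raises(ValueError):
            FieldConditions(b1_scale=0.0)

    def test_matrix_size(self):
        assert SequenceProtocol().matrix == (90, 110, 40)
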