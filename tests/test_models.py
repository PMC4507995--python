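import numpy as np
import pytest

from ocufit import (
    IRFCurve,
    LensDecay,
    TimeAxis,
    apply_incomplete_decay,
    evaluate_model,
    evaluate_spectral_global,
    lens_time_shift,
    shift_curve,
)
from ocufit.models import ModelSpec, ParamVector


class TestLensTimeShift:
    def test_gullstrand_eye(self):
        # d = 22.2 mm lens-retina distance, vitreous n = 1.3668
        assert lens_time_shift(22.2, 1.3668) == pytest.approx(202.3, abs=0.1)

    def test_zero_distance(self):
        assert lens_time_shift(0.0, 1.3668) == 0.0

    def test_linear_in_distance(self):
        assert lens_time_shift(44.4, 1.3668) == pytest.approx(
            2 * lens_time_shift(22.2, 1.3668)
        )

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            lens_time_shift(-1.0, 1.3668)


class TestShiftCurve:
    def test_zero_shift_identity(self, exact_axis):
        curve = np.random.default_rng(0).random(exact_axis.n_channels)
        np.testing.assert_allclose(shift_curve(curve, 0.0, exact_axis), curve)

    def test_integer_channel_shift_moves_delta(self, exact_axis):
        curve = np.zeros(exact_axis.n_channels)
        curve[10] = 1.0
        shifted = shift_curve(curve, exact_axis.channel_width_ps, exact_axis)
        assert shifted[11] == pytest.approx(1.0)
        assert shifted.sum() == pytest.approx(1.0)

    def test_half_channel_shift_splits_delta(self, exact_axis):
        curve = np.zeros(exact_axis.n_channels)
        curve[10] = 1.0
        shifted = shift_curve(curve, 0.5 * exact_axis.channel_width_ps, exact_axis)
        assert shifted[10] == pytest.approx(0.5)
        assert shifted[11] == pytest.approx(0.5)

    def test_shifted_in_samples_are_zero(self, exact_axis):
        curve = np.ones(exact_axis.n_channels)
        shifted = shift_curve(curve, 2 * exact_axis.channel_width_ps, exact_axis)
        np.testing.assert_allclose(shifted[:2], 0.0)


class TestEvaluateModel:
    def test_delta_irf_gives_pure_exponential(self, exact_axis, delta_irf):
        pv = ParamVector(alpha=[2.0], tau=[1500.0])
        curve = evaluate_model(ModelSpec("multiexp", 1), pv, delta_irf, exact_axis)
        t = exact_axis.centers_ps()
        np.testing.assert_allclose(curve, 2.0 * np.exp(-t / 1500.0), rtol=1e-12)

    def test_value_at_half_life(self, exact_axis, delta_irf):
        tau = 2000.0
        pv = ParamVector(alpha=[1.0], tau=[tau])
        curve = evaluate_model(ModelSpec("multiexp", 1), pv, delta_irf, exact_axis)
        t_half = tau * np.log(2.0)
        val = np.interp(t_half, exact_axis.centers_ps(), curve)
        assert val == pytest.approx(0.5, rel=1e-4)

    def test_stretched_beta_one_equals_multiexp(self, exact_axis, delta_irf):
        pv = ParamVector(alpha=[1.0, 0.5], tau=[500.0, 2500.0], beta=1.0)
        a = evaluate_model(ModelSpec("multiexp", 2), pv, delta_irf, exact_axis)
        b = evaluate_model(ModelSpec("stretched", 2), pv, delta_irf, exact_axis)
        assert np.abs(a - b).max() < 1e-12

    def test_lens_corrected_degenerates_to_multiexp(self, exact_axis, delta_irf):
        lens = LensDecay(values=np.ones(exact_axis.n_channels), time=exact_axis)
        pv = ParamVector(alpha=[1.0], tau=[1000.0], alpha_lens=0.0, beta=1.0)
        a = evaluate_model(ModelSpec("multiexp", 1), pv, delta_irf, exact_axis)
        b = evaluate_model(
            ModelSpec("lens_corrected", 1, fix_beta=1.0, lens=lens), pv, delta_irf, exact_axis
        )
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_linearity_in_amplitude_and_background(self, exact_axis, delta_irf):
        spec = ModelSpec("multiexp", 1)
        c1 = evaluate_model(spec, ParamVector(alpha=[1.0], tau=[800.0]), delta_irf, exact_axis)
        c3 = evaluate_model(spec, ParamVector(alpha=[3.0], tau=[800.0]), delta_irf, exact_axis)
        np.testing.assert_allclose(c3, 3.0 * c1, rtol=1e-12)
        cb = evaluate_model(
            spec, ParamVector(alpha=[1.0], tau=[800.0], background=2.5), delta_irf, exact_axis
        )
        np.testing.assert_allclose(cb, c1 + 2.5, rtol=1e-12)

    def test_shift_equivalence_integer_channels(self, exact_axis, delta_irf):
        s = 4 * exact_axis.channel_width_ps
        spec = ModelSpec("layered", 1)
        shifted_model = evaluate_model(
            spec, ParamVector(alpha=[1.0], tau=[900.0], tc=[s]), delta_irf, exact_axis
        )
        unshifted = evaluate_model(
            spec, ParamVector(alpha=[1.0], tau=[900.0], tc=[0.0]), delta_irf, exact_axis
        )
        np.testing.assert_allclose(
            shifted_model, shift_curve(unshifted, s, exact_axis), atol=1e-9
        )

    def test_unit_sum_irf_preserves_integral(self, time_axis, irf):
        # convolution with a unit-sum kernel conserves the decay integral
        # up to the tail truncated at the grid end
        pv = ParamVector(alpha=[1.0], tau=[300.0])
        curve = evaluate_model(ModelSpec("multiexp", 1), pv, irf, time_axis)
        t = time_axis.centers_ps()
        decay = np.exp(-t / 300.0)
        tail = decay[-1] * 300.0 / time_axis.channel_width_ps
        assert abs(curve.sum() - decay.sum()) <= tail + 1e-6

    def test_monotone_decay_after_peak(self, exact_axis, delta_irf):
        for j in (0, 1):
            spec = ModelSpec("multiexp", 1, incomplete_j=j)
            curve = evaluate_model(
                spec, ParamVector(alpha=[1.0], tau=[2000.0]), delta_irf, exact_axis
            )
            peak = int(np.argmax(curve))
            assert np.all(np.diff(curve[peak:]) < 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ParamVector(alpha=[1.0], tau=[-5.0])
        with pytest.raises(ValueError):
            ParamVector(alpha=[1.0], tau=[100.0], beta=1.5)


class TestIncompleteDecay:
    def test_j_zero_is_identity(self, exact_axis, delta_irf):
        spec = ModelSpec("multiexp", 1)
        assert apply_incomplete_decay(spec, 0) == spec

    def test_j_one_matches_two_term_sum(self, exact_axis, delta_irf):
        tau, t_r = 2000.0, exact_axis.rep_period_ps
        pv = ParamVector(alpha=[1.0], tau=[tau])
        spec = apply_incomplete_decay(ModelSpec("multiexp", 1), 1)
        curve = evaluate_model(spec, pv, delta_irf, exact_axis)
        t = exact_axis.centers_ps()
        expected = np.exp(-t / tau) + np.exp(-(t + t_r) / tau)
        np.testing.assert_allclose(curve, expected, rtol=1e-10)

    def test_large_j_matches_geometric_series(self, exact_axis, delta_irf):
        tau, t_r = 2000.0, exact_axis.rep_period_ps
        pv = ParamVector(alpha=[1.0], tau=[tau])
        base = evaluate_model(ModelSpec("multiexp", 1), pv, delta_irf, exact_axis)
        folded = evaluate_model(
            apply_incomplete_decay(ModelSpec("multiexp", 1), 12), pv, delta_irf, exact_axis
        )
        target = 1.0 / (1.0 - np.exp(-t_r / tau))
        assert np.abs(folded / base / target - 1.0).max() < 1e-6

    def test_wraparound_raises_channel_zero(self, exact_axis, delta_irf):
        # a 2 ns lifetime leaves a tail at t_R that folds into channel 0
        pv = ParamVector(alpha=[1.0], tau=[2000.0])
        plain = evaluate_model(ModelSpec("multiexp", 1), pv, delta_irf, exact_axis)
        folded = evaluate_model(ModelSpec("multiexp", 1, incomplete_j=1), pv, delta_irf, exact_axis)
        assert folded[0] > plain[0]
        assert folded[0] - plain[0] == pytest.approx(
            np.exp(-(exact_axis.centers_ps()[0] + exact_axis.rep_period_ps) / 2000.0),
            rel=1e-9,
        )


class TestSpectralGlobal:
    def _setup(self, exact_axis, delta_irf):
        specs = [ModelSpec("spectral_global", 2)] * 2
        p1 = ParamVector(alpha=[1.0, 0.5], tau=[400.0, 2000.0])
        p2 = ParamVector(alpha=[0.8, 0.7], tau=[400.0, 2600.0])
        return specs, [p1, p2], [delta_irf, delta_irf]

    def test_identical_channels_give_identical_curves(self, exact_axis, delta_irf):
        specs, params, irfs = self._setup(exact_axis, delta_irf)
        curves = evaluate_spectral_global(
            specs, [0, 1], [params[0], params[0]], irfs, exact_axis
        )
        np.testing.assert_allclose(curves[0], curves[1])

    def test_shared_lifetime_propagates(self, exact_axis, delta_irf):
        specs, params, irfs = self._setup(exact_axis, delta_irf)
        a = evaluate_spectral_global(specs, [0], params, irfs, exact_axis)
        perturbed = ParamVector(alpha=[1.0, 0.5], tau=[600.0, 2000.0])
        b = evaluate_spectral_global(specs, [0], [perturbed, params[1]], irfs, exact_axis)
        assert not np.allclose(a[0], b[0])
        assert not np.allclose(a[1], b[1])

    def test_empty_shared_set_reduces_to_independent_models(self, exact_axis, delta_irf):
        specs, params, irfs = self._setup(exact_axis, delta_irf)
        curves = evaluate_spectral_global(specs, [], params, irfs, exact_axis)
        for spec, p, c in zip(specs, params, curves):
            np.testing.assert_allclose(c, evaluate_model(spec, p, delta_irf, exact_axis))

    def test_inconsistent_shared_index_rejected(self, exact_axis, delta_irf):
        specs = [ModelSpec("spectral_global", 1), ModelSpec("spectral_global", 2)]
        params = [ParamVector(alpha=[1.0], tau=[500.0]), ParamVector(alpha=[1.0, 1.0], tau=[500.0, 2000.0])]
        with pytest.raises(ValueError):
            evaluate_spectral_global(specs, [1], params, [delta_irf] * 2, exact_axis)
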