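import numpy as np
import pytest

from ocufit import (
    DegenerateDofError,
    compute_weights,
    detect_reflection_artifacts,
    fit_image,
    global_init,
    minimize_pixel,
    neighborhood_chi2,
    reduced_chi2,
    simulate_cube,
    solve_amplitudes,
    treat_outliers,
    uniform_truth,
)
from ocufit.fitting import FitConfig, estimate_background_preexcitation
from ocufit.models import ModelSpec, ParamVector, evaluate_model


class TestWeights:
    def test_neyman_floors_zero_counts(self):
        np.testing.assert_array_equal(
            compute_weights(np.array([4, 9, 0]), "neyman"), [4.0, 9.0, 1.0]
        )

    def test_pearson_uses_model_counts(self):
        np.testing.assert_array_equal(
            compute_weights(np.array([5, 5]), "pearson", model=np.array([2.0, 8.0])),
            [2.0, 8.0],
        )

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(np.array([1]), "warren")


class TestReducedChi2:
    def test_perfect_fit_is_zero(self):
        m = np.array([10.0, 20.0, 5.0])
        assert reduced_chi2(m, m, compute_weights(m, "neyman"), p=1) == 0.0

    def test_hand_example(self):
        # residuals 2 and 2, Neyman weights 10 and 10, one free parameter
        m = np.array([10.0, 10.0])
        c = np.array([8.0, 12.0])
        assert reduced_chi2(m, c, compute_weights(m, "neyman"), p=1) == pytest.approx(0.8)

    def test_masking_large_residual_decreases_value(self):
        m = np.array([10.0, 10.0, 10.0])
        c = np.array([9.0, 10.0, 100.0])
        w = compute_weights(m, "neyman")
        full = reduced_chi2(m, c, w, p=1)
        masked = reduced_chi2(m, c, w, p=1, channel_mask=np.array([True, True, False]))
        assert masked < full

    def test_degenerate_dof_rejected(self):
        m = np.array([1.0, 2.0])
        with pytest.raises(DegenerateDofError):
            reduced_chi2(m, m, np.ones(2), p=2)


class TestNeighborhoodChi2:
    def test_zero_center_leaves_neighbor_mean(self):
        assert neighborhood_chi2(0.0, [2.0, 4.0]) == pytest.approx(3.0)

    def test_center_squared_plus_mean(self):
        assert neighborhood_chi2(1.0, [1.0, 1.0, 1.0, 1.0]) == pytest.approx(2.0)
        assert neighborhood_chi2(2.0, [0.0]) == pytest.approx(4.0)

    def test_empty_neighbors_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_chi2(1.0, [])


class TestSolveAmplitudes:
    def test_exact_single_basis(self):
        basis = np.exp(-np.arange(64) / 10.0)[None, :]
        alphas, a_lens, b, model = solve_amplitudes(
            basis, None, basis[0], np.ones(64)
        )
        assert alphas[0] == pytest.approx(1.0, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_two_component_exact_recovery(self):
        t = np.arange(128, dtype=float)
        bases = np.vstack([np.exp(-t / 8.0), np.exp(-t / 40.0)])
        measured = 2.0 * bases[0] + 3.0 * bases[1]
        alphas, _, b, _ = solve_amplitudes(bases, None, measured, np.ones(128))
        np.testing.assert_allclose(alphas, [2.0, 3.0], atol=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_nonnegativity_clamps_at_zero(self):
        t = np.arange(32, dtype=float)
        bases = np.exp(-t / 5.0)[None, :]
        measured = -bases[0]  # anti-correlated with the basis
        alphas, _, _, _ = solve_amplitudes(bases, None, measured, np.ones(32), fit_background=False)
        assert alphas[0] == 0.0

    def test_all_zero_basis_rejected(self):
        with pytest.raises(ValueError):
            solve_amplitudes(np.zeros((1, 16)), None, np.ones(16), np.ones(16))

    def test_optimal_among_grid_of_nonnegative_combinations(self):
        rng = np.random.default_rng(0)
        t = np.arange(48, dtype=float)
        bases = np.vstack([np.exp(-t / 6.0), np.exp(-t / 25.0)])
        measured = 1.3 * bases[0] + 0.4 * bases[1] + rng.normal(0, 0.05, 48)
        w = np.full(48, 2.0)
        alphas, _, _, model = solve_amplitudes(bases, None, measured, w, fit_background=False)
        best = np.sum((measured - model) ** 2 / w)
        for a1 in np.linspace(0, 3, 61):
            for a2 in np.linspace(0, 2, 41):
                cand = a1 * bases[0] + a2 * bases[1]
                assert best <= np.sum((measured - cand) ** 2 / w) + 1e-9


class TestMinimizePixel:
    def test_noiseless_single_exponential_recovery(self, time_axis, irf):
        spec = ModelSpec("multiexp", 1)
        truth = ParamVector(alpha=[1000.0], tau=[2000.0])
        hist = np.round(evaluate_model(spec, truth, irf, time_axis)).astype(int)
        res = minimize_pixel(
            hist, spec, FitConfig(), ParamVector(alpha=[1.0], tau=[1000.0]), irf, time_axis
        )
        assert res.params.tau[0] == pytest.approx(2000.0, rel=1e-3)

    def test_parameters_respect_bounds(self, time_axis, irf):
        spec = ModelSpec("multiexp", 1)
        cfg = FitConfig(bounds={"tau1": (100.0, 1500.0)})
        truth = ParamVector(alpha=[1000.0], tau=[3000.0])
        hist = np.round(evaluate_model(spec, truth, irf, time_axis)).astype(int)
        res = minimize_pixel(hist, spec, cfg, ParamVector(alpha=[1.0], tau=[800.0]), irf, time_axis)
        assert 100.0 <= res.params.tau[0] <= 1500.0

    def test_pearson_weighting_also_recovers(self, time_axis, irf):
        spec = ModelSpec("multiexp", 1)
        truth = ParamVector(alpha=[1000.0], tau=[1200.0])
        hist = np.round(evaluate_model(spec, truth, irf, time_axis)).astype(int)
        res = minimize_pixel(
            hist, spec, FitConfig(weighting="pearson"),
            ParamVector(alpha=[1.0], tau=[600.0]), irf, time_axis,
        )
        assert res.params.tau[0] == pytest.approx(1200.0, rel=0.01)


class TestGlobalInit:
    def _total_hist(self, time_axis, irf, seed=0):
        truth = uniform_truth(
            (8, 8), time_axis, irf, tau_ps=(500.0, 2500.0), alpha=(0.6, 0.4),
            n_photons=16_000, seed=seed,
        )
        from ocufit import sum_all_pixels

        return sum_all_pixels(simulate_cube(truth))

    def test_lifetimes_within_ten_percent_of_truth(self, time_axis, irf):
        total = self._total_hist(time_axis, irf)  # ~1e6 photons
        spec = ModelSpec("multiexp", 2)
        init = global_init(total, spec, FitConfig(seed=4), irf, time_axis)
        assert init.tau[0] == pytest.approx(500.0, rel=0.10)
        assert init.tau[1] == pytest.approx(2500.0, rel=0.10)

    def test_seed_reproducibility_and_bounds(self, time_axis, irf):
        total = self._total_hist(time_axis, irf, seed=1)
        spec = ModelSpec("multiexp", 2)
        cfg = FitConfig(seed=12)
        a = global_init(total, spec, cfg, irf, time_axis)
        b = global_init(total, spec, cfg, irf, time_axis)
        np.testing.assert_array_equal(a.tau, b.tau)
        assert np.all(a.tau >= 10.0) and np.all(a.tau <= 8000.0)


class TestArtifactDetection:
    def _bumped(self, start, peak, height=3000.0):
        t = np.arange(400, dtype=float)
        decay = 10_000 * np.exp(-t / 80.0)
        bump = np.zeros(400)
        rise = np.linspace(0, height, peak - start + 1)
        bump[start : peak + 1] = rise
        fall = height * np.exp(-(t[peak + 1 : peak + 40] - peak) / 8.0)
        bump[peak + 1 : peak + 40] = fall
        return np.round(decay + bump).astype(int)

    def test_monotone_decay_yields_no_artifacts(self):
        t = np.arange(400, dtype=float)
        hist = np.round(10_000 * np.exp(-t / 80.0)).astype(int)
        assert detect_reflection_artifacts(hist) == []

    def test_three_times_rise_rule(self):
        hist = self._bumped(100, 110)
        assert detect_reflection_artifacts(hist) == [(100, 130)]

    def test_two_disjoint_bumps_sorted_nonoverlapping(self):
        hist = self._bumped(100, 110) + self._bumped(250, 258) - np.round(
            10_000 * np.exp(-np.arange(400) / 80.0)
        ).astype(int)
        ivs = detect_reflection_artifacts(hist)
        assert len(ivs) == 2
        assert ivs == sorted(ivs)
        assert ivs[0][1] <= ivs[1][0]

    def test_mask_changes_figure_of_merit_not_model(self, time_axis, irf):
        spec = ModelSpec("multiexp", 1)
        truth = ParamVector(alpha=[1000.0], tau=[1500.0])
        hist = np.round(evaluate_model(spec, truth, irf, time_axis)).astype(int)
        res_full = minimize_pixel(
            hist, spec, FitConfig(), truth, irf, time_axis, artifact_intervals=[]
        )
        res_masked = minimize_pixel(
            hist, spec, FitConfig(), truth, irf, time_axis, artifact_intervals=[(150, 170)]
        )
        # model curves are evaluated over all channels either way
        assert not res_masked.channel_mask[150:170].any()
        assert res_masked.channel_mask.size == time_axis.n_channels


class TestBackgroundEstimate:
    def test_preexcitation_mean(self):
        hist = np.concatenate([np.full(50, 4.0), np.full(50, 0.0)])
        hist[60] = 1000.0  # pulse far after the flat pre-excitation interval
        est = estimate_background_preexcitation(hist)
        assert est == pytest.approx(4.0, abs=0.5)


@pytest.fixture(scope="module")
def fitted():
    from ocufit import TimeAxis, gaussian_irf

    time_axis = TimeAxis(256, 48.8, 12.5)
    irf = gaussian_irf(time_axis, 172.0, 1000.0)
    truth = uniform_truth(
        (6, 6), time_axis, irf, tau_ps=(500.0, 2500.0), alpha=(0.6, 0.4),
        n_photons=100_000, seed=21,
    )
    cube = simulate_cube(truth)
    spec = ModelSpec("multiexp", 2)
    cfg = FitConfig(seed=2, de_maxiter=40)
    return cube, spec, cfg, irf, fit_image(cube, spec, cfg, irf)


class TestFitImage:
    def test_median_lifetime_recovery_within_ten_percent(self, fitted):
        *_, res = fitted
        assert np.median(np.abs(res["tau1"] - 500.0) / 500.0) < 0.10
        assert np.median(np.abs(res["tau2"] - 2500.0) / 2500.0) < 0.10

    def test_tau_m_consistent_with_amplitude_weighting(self, fitted):
        *_, res = fitted
        expected = (res["alpha1"] * res["tau1"] + res["alpha2"] * res["tau2"]) / (
            res["alpha1"] + res["alpha2"]
        )
        np.testing.assert_allclose(res["tau_m"], expected, rtol=1e-9)

    def test_rerun_same_seed_identical(self, fitted):
        cube, spec, cfg, irf, res = fitted
        res2 = fit_image(cube, spec, cfg, irf)
        np.testing.assert_array_equal(res["tau1"], res2["tau1"])
        np.testing.assert_array_equal(res["chi2"], res2["chi2"])

    def test_provenance_records_settings(self, fitted):
        *_, res = fitted
        assert res.provenance["seed"] == 2
        assert res.provenance["model_kind"] == "multiexp"
        assert res.provenance["fit_interval"] == "decay_only"


class TestTreatOutliers:
    def _results(self, maps):
        from ocufit import FitResultMaps

        return FitResultMaps(maps={k: np.asarray(v, dtype=float) for k, v in maps.items()})

    def _dummy_cube(self, shape, time_axis, irf):
        truth = uniform_truth(shape, time_axis, irf, n_photons=2000, seed=0)
        return simulate_cube(truth)

    def test_constant_maps_no_outliers(self, time_axis, irf):
        cube = self._dummy_cube((5, 5), time_axis, irf)
        res = self._results(
            {"alpha1": np.ones((5, 5)), "tau1": np.full((5, 5), 500.0),
             "tau_m": np.full((5, 5), 500.0), "background": np.zeros((5, 5)),
             "chi2": np.ones((5, 5))}
        )
        _, n_det, n_imp = treat_outliers(
            res, cube, ModelSpec("multiexp", 1), FitConfig(), irf, window=3
        )
        assert (n_det, n_imp) == (0, 0)

    @pytest.mark.parametrize("factor,expected", [(1.4, True), (1.2, False)])
    def test_relative_threshold_rule(self, time_axis, irf, factor, expected):
        cube = self._dummy_cube((7, 7), time_axis, irf)
        tau = np.full((7, 7), 1000.0)
        tau[3, 3] = factor * 1000.0
        res = self._results(
            {"alpha1": np.ones((7, 7)), "tau1": tau, "tau_m": tau,
             "background": np.zeros((7, 7)), "chi2": np.ones((7, 7))}
        )
        _, n_det, _ = treat_outliers(
            res, cube, ModelSpec("multiexp", 1), FitConfig(), irf, window=7
        )
        assert (n_det > 0) is expected

    def test_accepted_refits_never_worsen_chi2(self, time_axis, irf):
        truth = uniform_truth((6, 6), time_axis, irf, tau_ps=(1500.0,), alpha=(1.0,), n_photons=3000, seed=5)
        cube = simulate_cube(truth)
        spec = ModelSpec("multiexp", 1)
        cfg = FitConfig(seed=1, de_maxiter=20, outlier_iterations=0)
        res = fit_image(cube, spec, cfg, irf)
        # poison one pixel so it is flagged and refit
        res.maps["tau1"][2, 2] = 5000.0
        res.maps["chi2"][2, 2] = 50.0
        out, n_det, n_imp = treat_outliers(res, cube, spec, cfg, irf, window=5)
        assert n_det >= 1
        assert np.all(out["chi2"] <= res["chi2"] + 1e-12)
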