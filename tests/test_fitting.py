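import math

import numpy as np
import pytest
from scipy import stats

from placefields.cue_model import CueParams, SubsetMask, posterior_sigma, size_profile
from placefields.fitting import (
    GaussianFit,
    PlaceField,
    RateMap,
    adjusted_r_squared,
    chi2_gof_normal,
    cross_env_predict,
    field_from_spikes,
    fit_gamma,
    fit_gaussian_ratemap,
    fit_subset,
    flag_asymmetric,
    moving_average,
    r_squared,
    residual_tests,
    zscore,
)
from placefields.geometry import CircularTrack, Point2D, RectEnvironment
from placefields.synthetic import (
    SyntheticSpec,
    fields_from_table,
    gen_circular_track,
    gen_linear_track,
    gen_openfield,
)


class TestFieldFromSpikes:
    def test_population_std_on_track(self):
        f = field_from_spikes([10.0, 20.0, 30.0])
        assert f.centroid == pytest.approx(20.0)
        assert f.size == pytest.approx(math.sqrt(200.0 / 3.0))

    def test_identical_spikes_zero_size(self):
        assert field_from_spikes([5.0, 5.0, 5.0]).size == 0.0

    def test_translation_invariance(self, rng):
        x = rng.normal(0, 3, size=50)
        a = field_from_spikes(x)
        b = field_from_spikes(x + 17.0)
        assert b.centroid == pytest.approx(a.centroid + 17.0)
        assert b.size == pytest.approx(a.size)

    def test_2d_per_axis(self, rng):
        pos = rng.normal([10, 20], [2, 4], size=(500, 2))
        f = field_from_spikes(pos)
        assert isinstance(f.centroid, Point2D)
        sx, sy = f.size
        assert sx == pytest.approx(2.0, rel=0.2)
        assert sy == pytest.approx(4.0, rel=0.2)

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError):
            field_from_spikes([1.0])


class TestMovingAverage:
    def test_constant_unchanged(self):
        assert np.allclose(moving_average([3.0] * 7, 3), 3.0)

    def test_window_one_identity(self):
        x = [1.0, 4.0, 2.0]
        assert np.allclose(moving_average(x, 1), x)

    def test_documented_even_window_convention(self):
        out = moving_average([1.0, 2.0, 3.0, 4.0], window=2)
        assert np.allclose(out, [1.5, 2.5, 3.5, 4.0])

    def test_circular_wraps(self):
        out = moving_average([1.0, 0.0, 0.0, 0.0], window=3, circular=True)
        assert np.allclose(out, [1 / 3, 1 / 3, 0.0, 1 / 3])

    def test_oversized_window_rejected_when_linear(self):
        with pytest.raises(ValueError):
            moving_average([1.0, 2.0], window=5)


class TestZscore:
    def test_two_points(self):
        assert np.allclose(zscore([0.0, 2.0]), [-1.0, 1.0])

    def test_idempotent_and_affine_invariant(self, rng):
        x = rng.normal(5, 3, size=40)
        z = zscore(x)
        assert np.allclose(zscore(z), z)
        assert np.allclose(zscore(4.0 * x - 7.0), z)
        assert abs(z.mean()) < 1e-12 and z.std() == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscore([2.0, 2.0])


class TestRSquared:
    def test_perfect_and_mean_baselines(self):
        obs = [1.0, 2.0, 3.0]
        assert r_squared(obs, obs) == pytest.approx(1.0)
        assert r_squared([2.0] * 3, obs) == pytest.approx(0.0)

    def test_hand_computed(self):
        assert r_squared([1.0, 2.0, 4.0], [1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_adjusted(self):
        assert adjusted_r_squared(1.0, 20, 3) == pytest.approx(1.0)
        assert adjusted_r_squared(0.7, 15, 0) == pytest.approx(0.7)
        assert adjusted_r_squared(0.5, 11, 1) == pytest.approx(1 - 0.5 * 10 / 9)
        with pytest.raises(ValueError):
            adjusted_r_squared(0.5, 4, 3)


class TestResidualTests:
    def test_near_perfect_model(self, rng):
        model = np.sin(np.linspace(0, 3, 60))
        data = model + rng.normal(0, 1e-4, 60)
        out = residual_tests(data, model)
        assert out["pearson_r"] > 0.999

    def test_anticorrelated_toy(self):
        x = np.tile([1.0, 2.0, 3.0], 4)
        out = residual_tests(np.repeat([3.0, 2.0, 1.0], 4), np.repeat([1.0, 2.0, 3.0], 4))
        assert out["pearson_r"] == pytest.approx(-1.0)

    def test_gof_pvalues_calibrated_under_null(self, rng):
        # data = model + Gaussian noise: residual GOF p-values ~ Uniform(0,1)
        pvals = []
        model = np.linspace(0, 10, 100)
        for _ in range(300):
            data = model + rng.normal(0, 1.0, size=100)
            pvals.append(residual_tests(data, model)["chi2_resid_p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3

    def test_chi2_detects_structure(self, rng):
        structured = np.concatenate([rng.normal(-4, 0.3, 100), rng.normal(4, 0.3, 100)])
        _, p = chi2_gof_normal(structured)
        assert p < 1e-4


class TestFlagAsymmetric:
    def test_symmetric_cloud_passes(self, rng):
        assert not flag_asymmetric(rng.normal(0, 2, size=2000))

    def test_skewed_cloud_flagged(self, rng):
        assert flag_asymmetric(rng.lognormal(0, 1.2, size=2000))


class TestFitGamma:
    def test_noiseless_linear_track_recovery(self, linear_track):
        spec = SyntheticSpec(gamma_true=0.25, noise_cv=0.0, n_cells=40, seed=3)
        res = fit_gamma(fields_from_table(gen_linear_track(spec)), linear_track)
        assert res.params.gamma == pytest.approx(0.25, rel=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_circular_recovery(self, circular_track):
        spec = SyntheticSpec(gamma_true=0.15, noise_cv=0.0, n_cells=40, seed=4)
        fields, _ = gen_circular_track(spec)
        res = fit_gamma(fields_from_table(fields), circular_track)
        assert res.params.gamma == pytest.approx(0.15, rel=1e-6)

    def test_single_field_closed_form(self):
        # one observation (the barrier), alpha = 0: gamma = size / distance
        track = CircularTrack(60.0, 10.0)
        fields = [PlaceField("c", 0, 30.0, 6.0, "std"),
                  PlaceField("c", 1, 30.0, 6.0, "std")]
        res = fit_gamma(fields, track)
        assert res.params.gamma == pytest.approx(6.0 / 30.0, rel=1e-6)

    def test_size_scaling_scales_gamma(self, circular_track):
        spec = SyntheticSpec(gamma_true=0.15, noise_cv=0.1, n_cells=30, seed=5)
        fields, _ = gen_circular_track(spec)
        df = fields.copy()
        base = fit_gamma(fields_from_table(df), circular_track).params.gamma
        df["size_value"] *= 3.0
        scaled = fit_gamma(fields_from_table(df), circular_track).params.gamma
        assert scaled == pytest.approx(3.0 * base, rel=1e-5)

    def test_bound_curves_cover_noiseless_fields(self, linear_track):
        spec = SyntheticSpec(gamma_true=0.2, noise_cv=0.0, n_cells=50, seed=6)
        res = fit_gamma(fields_from_table(gen_linear_track(spec)), linear_track)
        extras = res.extras
        assert np.all(extras["bound_upper"] >= extras["bound_lower"])
        assert extras["coverage_fraction"] >= 0.9

    def test_coverage_monotone_as_bounds_separate(self, linear_track):
        # moving the near-wall trajectory closer to the wall widens the band
        spec = SyntheticSpec(gamma_true=0.2, noise_cv=0.3, n_cells=60, seed=7)
        fields = fields_from_table(gen_linear_track(spec))
        fracs = [fit_gamma(fields, linear_track, trajectory_offset_cm=off)
                 .extras["coverage_fraction"] for off in (8.0, 4.0, 1.0, 0.25)]
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_dialect_mismatch_rejected(self, circular_track):
        fields = [PlaceField("c", 0, 30.0, 6.0, "std")] * 2
        with pytest.raises(ValueError, match="dialect"):
            fit_gamma(fields, circular_track, mode="area")


class TestFitSubset:
    def test_toy_track_enumerates_all_masks(self, toy_track, params):
        arcs, sig = size_profile(toy_track, params, resolution_cm=2.0)
        res = fit_subset(sig, toy_track, arcs=arcs)
        assert res.mask.delta == (1, 1, 1, 1)
        assert res.r2 == pytest.approx(1.0)

    def test_known_submask_recovered_at_zero_noise(self, circular_track):
        mask_true = SubsetMask((1, 0, 1, 1, 0, 1, 0, 1, 1))
        spec = SyntheticSpec(gamma_true=0.2, noise_cv=0.0, n_cells=150, seed=8,
                             mask_true=mask_true, multi_field_prob=0.0)
        fields, _ = gen_circular_track(spec)
        res = fit_subset(fields["size_value"].to_numpy(), circular_track,
                         arcs=fields["arc_cm"].to_numpy())
        assert res.mask == mask_true
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.r2_adj <= res.r2

    def test_matches_independent_reenumeration(self, toy_track, rng):
        # independent oracle: loop over masks, score with the public pieces
        arcs = np.sort(rng.uniform(0, toy_track.circumference_cm, 60))
        p = CueParams(gamma=0.3)
        truth = SubsetMask((0, 1, 1, 0))
        sizes = np.array([
            posterior_sigma([o.distance_cm for o in
                             __import__("placefields.geometry", fromlist=["track_distances"])
                             .track_distances(s, toy_track)], p, truth)
            for s in arcs
        ]) * rng.lognormal(0, 0.05, arcs.size)
        res = fit_subset(sizes, toy_track, arcs=arcs)
        n_obs = 4
        best_mask, best_score = None, -np.inf
        from placefields.geometry import track_distances

        z_obs = zscore(sizes)
        for bits in range(1, 2**n_obs):
            mask = SubsetMask.from_index(bits, n_obs)
            prof = np.array([
                max(posterior_sigma([o.distance_cm for o in track_distances(s, toy_track)],
                                    p, mask), 1e-6)
                for s in arcs
            ])
            if prof.std() == 0:
                continue
            score = r_squared(zscore(prof), z_obs)
            if score > best_score:
                best_mask, best_score = mask, score
        assert res.mask == best_mask
        assert res.r2 == pytest.approx(best_score, rel=1e-9)

    def test_all_ones_mask_scores_like_base_profile(self, toy_track, params):
        arcs, sig = size_profile(toy_track, params, resolution_cm=2.0)
        noisy = sig + 0.01 * np.sin(arcs)
        res = fit_subset(noisy, toy_track, arcs=arcs)
        all_ones_bits = 2 ** 4 - 1
        base_score = r_squared(zscore(np.maximum(sig, 1e-6)), zscore(noisy))
        assert res.extras.get("n_masks", None) is None  # scores live on estimator
        from placefields.estimators import ObjectSubsetRegressor
        est = ObjectSubsetRegressor(track=toy_track).fit(arcs[:, None], noisy)
        assert est.scores_[all_ones_bits - 1] == pytest.approx(base_score, rel=1e-9)

    def test_enumeration_guard(self):
        track = CircularTrack(200.0, 10.0,
                              object_arcs_cm=tuple(np.linspace(5, 600, 25)))
        with pytest.raises(ValueError, match="guard"):
            fit_subset(np.ones(50), track, max_observations=20)


class TestGaussianRateMapFit:
    @staticmethod
    def _make_map(mu_x, mu_y, sx, sy, amp, bins=1.9, L=122.0, W=122.0, base=0.0):
        nx, ny = int(round(L / bins)), int(round(W / bins))
        xs = (np.arange(nx) + 0.5) * bins
        ys = (np.arange(ny) + 0.5) * bins
        rates = base + amp * np.outer(
            np.exp(-0.5 * ((ys - mu_y) / sy) ** 2),
            np.exp(-0.5 * ((xs - mu_x) / sx) ** 2))
        return RateMap(bins, Point2D(0, 0), rates)

    def test_noiseless_recovery(self):
        m = self._make_map(40.0, 70.0, 8.0, 12.0, 6.0)
        fit = fit_gaussian_ratemap(m)
        assert fit.mu_x == pytest.approx(40.0, rel=0.01)
        assert fit.mu_y == pytest.approx(70.0, rel=0.01)
        assert fit.sigma_x == pytest.approx(8.0, rel=0.01)
        assert fit.sigma_y == pytest.approx(12.0, rel=0.01)
        assert fit.amplitude == pytest.approx(6.0, rel=0.01)

    def test_symmetric_map_isotropic(self):
        fit = fit_gaussian_ratemap(self._make_map(61.0, 61.0, 10.0, 10.0, 5.0))
        assert fit.sigma_x == pytest.approx(fit.sigma_y, rel=1e-3)

    def test_baseline_moves_offset_not_stds(self):
        a = fit_gaussian_ratemap(self._make_map(50.0, 60.0, 9.0, 11.0, 5.0))
        b = fit_gaussian_ratemap(self._make_map(50.0, 60.0, 9.0, 11.0, 5.0, base=2.0))
        assert b.baseline == pytest.approx(a.baseline + 2.0, abs=0.05)
        assert b.sigma_x == pytest.approx(a.sigma_x, rel=0.01)
        assert b.amplitude == pytest.approx(a.amplitude, rel=0.01)

    def test_flat_map_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_ratemap(RateMap(1.9, Point2D(0, 0), np.zeros((10, 10))))


class TestCrossEnvPredict:
    def test_noiseless_closure(self):
        spec = SyntheticSpec(gamma_true=0.25, n_cells=6, seed=9)
        maps, _ = gen_openfield(spec)
        envs = {"C": RectEnvironment(61.0, 122.0), "D": RectEnvironment(122.0, 61.0),
                "B": RectEnvironment(122.0, 122.0)}
        fits_cd = {c: (fit_gaussian_ratemap(maps["C"][c]), fit_gaussian_ratemap(maps["D"][c]))
                   for c in maps["C"]}
        res = cross_env_predict(fits_cd, maps["B"], envs["C"], envs["D"], envs["B"])
        assert res.mean_r2_model > 0.999
        assert res.mean_r2_optimal >= res.mean_r2_model - 1e-6
        assert res.p_value > 0.01  # model fit statistically indistinguishable

    def test_identity_target_matches_optimal(self):
        spec = SyntheticSpec(gamma_true=0.25, n_cells=4, seed=10)
        maps, _ = gen_openfield(spec)
        envs = {"C": RectEnvironment(61.0, 122.0), "D": RectEnvironment(122.0, 61.0)}
        fits_cd = {c: (fit_gaussian_ratemap(maps["C"][c]), fit_gaussian_ratemap(maps["D"][c]))
                   for c in maps["C"]}
        res = cross_env_predict(fits_cd, maps["C"], envs["C"], envs["D"], envs["C"])
        assert res.mean_r2_model == pytest.approx(res.mean_r2_optimal, abs=1e-3)

    def test_paired_t_on_identical_vectors(self):
        # identical per-field scores -> t = 0, p = 1 by convention
        spec = SyntheticSpec(gamma_true=0.25, n_cells=3, seed=11)
        maps, _ = gen_openfield(spec)
        envs = {"C": RectEnvironment(61.0, 122.0), "D": RectEnvironment(122.0, 61.0)}
        fits_cd = {c: (fit_gaussian_ratemap(maps["C"][c]), fit_gaussian_ratemap(maps["D"][c]))
                   for c in maps["C"]}
        res = cross_env_predict(fits_cd, maps["C"], envs["C"], envs["D"], envs["C"])
        if np.allclose(res.t_stat, 0.0):
            assert res.p_value == pytest.approx(1.0)

    def test_doubling_dimensions_doubles_sigma(self):
        fit = GaussianFit(30.0, 20.0, 5.0, 4.0, 6.0, 0.0, 1.0)
        env1 = RectEnvironment(61.0, 61.0)
        env2 = RectEnvironment(122.0, 122.0)
        spec = SyntheticSpec(gamma_true=0.3, n_cells=1, seed=12)
        maps1, _ = gen_openfield(spec, {"T": env1})
        maps2, _ = gen_openfield(spec, {"T": env2})
        f1 = fit_gaussian_ratemap(maps1["T"]["cell000"])
        f2 = fit_gaussian_ratemap(maps2["T"]["cell000"])
        assert f2.sigma_x == pytest.approx(2 * f1.sigma_x, rel=0.02)
        assert f2.sigma_y == pytest.approx(2 * f1.sigma_y, rel=0.02)
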