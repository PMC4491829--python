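"""Metastable detection, GMM decomposition, density-ratio comparison."""

import numpy as np
import pytest

from cmacdyn.preprocess import process_table
from cmacdyn.subpops import (area_density_ratio, fit_gmm,
                             pooled_subpopulation_means, select_k_by_aic,
                             stable_areas_empirical, stable_areas_synthetic)


class _Track:
    def __init__(self, areas):
        self.area_raw = np.asarray(areas, dtype=float)


class TestStableEmpirical:
    def test_single_repeat_emits_one_event(self):
        out = stable_areas_empirical([_Track([1.0, 1.0, 2.0])], tol=0.0)
        assert out.tolist() == [1.0]

    def test_monotone_track_emits_nothing(self):
        out = stable_areas_empirical([_Track([1.0, 1.2, 1.5, 2.0])], tol=0.0)
        assert out.size == 0

    def test_run_of_three_counts_each_consecutive_pair(self):
        out = stable_areas_empirical([_Track([2.0, 2.0, 2.0])], tol=0.0)
        assert out.tolist() == [2.0, 2.0]

    def test_tolerance_widens_matches(self):
        track = _Track([1.0, 1.05, 2.0])
        assert stable_areas_empirical([track], tol=0.0).size == 0
        assert stable_areas_empirical([track], tol=0.1).tolist() == [1.0]

    def test_pixel_quantized_fixture_by_hand(self):
        # integer-pixel areas: exact-match counting is reproducible by hand
        tracks = [_Track([3, 3, 4, 4, 4, 5]), _Track([2, 3, 2, 2])]
        out = stable_areas_empirical(tracks, tol=0.0)
        assert sorted(out.tolist()) == [2.0, 3.0, 4.0, 4.0]

    def test_generator_cohort_clusters_at_planted_modes(self, cohort_table,
                                                        cohort_config):
        tracks = process_table(cohort_table)
        stable = stable_areas_empirical(tracks, tol=0.0)
        assert stable.size > 50
        planted = np.asarray(cohort_config.stable_modes)
        dist = np.min(np.abs(stable[:, None] - planted[None, :]), axis=1)
        assert np.mean(dist < 0.05) > 0.9


class _Traj:
    def __init__(self, termination, final_area):
        from cmacdyn.simulate import SimState
        self.termination = termination
        self.states = [SimState(A=final_area, dA=0, T=0, dT=0)]


class TestStableSynthetic:
    def test_no_type_iv_gives_empty(self):
        assert stable_areas_synthetic([_Traj("I", 0.2)]).size == 0

    def test_counts_match_type_iv(self):
        pop = [_Traj("IV", 1.5), _Traj("II", 3.0), _Traj("IV", 2.5)]
        out = stable_areas_synthetic(pop)
        assert sorted(out.tolist()) == [1.5, 2.5]

    def test_all_zero_maps_population_stalls_near_seed_area(self):
        from cmacdyn.probmaps import constant_map
        from cmacdyn.simulate import ModelParams, simulate_population
        amap = constant_map(0.0)
        tmap = constant_map(0.0, grid=((-5.0, 5.0, 21), (-1.0, 1.0, 11)),
                            names=("v_tension", "d_tension"))
        p = ModelParams(mu1=0.005, mu2=0.05, nu=0.25, tau1=2, tau2=2, tau3=2)
        trajs, freqs = simulate_population(amap, tmap, p, n=50, seed=3)
        assert freqs["IV"] == 1.0
        areas = stable_areas_synthetic(trajs)
        assert areas == pytest.approx(np.full(50, 0.2))


class TestGmm:
    def test_single_component_consistency(self, rng):
        x = rng.normal(3.0, 0.2, size=500)
        fit = fit_gmm(x, k=1, seed=0)
        assert fit.k == 1
        assert fit.means[0] == pytest.approx(3.0, abs=3 * 0.2 / np.sqrt(500))
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)

    def test_two_separated_modes_recovered(self, rng):
        x = np.concatenate([rng.normal(1.0, 0.2, 300), rng.normal(6.0, 0.2, 300)])
        fit = fit_gmm(x, k=2, seed=0)
        assert fit.means == pytest.approx([1.0, 6.0], abs=0.2)
        assert fit.weights == pytest.approx([0.5, 0.5], abs=0.1)

    def test_identical_values_flagged_degenerate(self):
        fit = fit_gmm(np.full(30, 2.0), k=1, seed=0)
        assert fit.degenerate
        assert fit.sds[0] > 0    # variance floor keeps the fit finite

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_gmm([1.0, 2.0], k=1)

    def test_weights_sum_to_one(self, rng):
        x = rng.normal(2.0, 0.5, 200)
        fit = fit_gmm(x, k=3, seed=1)
        assert fit.weights.sum() == pytest.approx(1.0)


class TestSelectK:
    def test_gaussian_null_prefers_one_component(self, rng):
        x = rng.normal(2.0, 0.4, size=500)
        modal_k, chosen, _ = select_k_by_aic(x, k_max=3, repeats=20, seed=0)
        assert modal_k == 1
        # type-I selection of extra structure stays limited
        assert np.mean(chosen > 1) <= 0.2

    def test_kmax_one_is_trivial(self, rng):
        x = rng.normal(2.0, 0.4, size=100)
        modal_k, chosen, _ = select_k_by_aic(x, k_max=1, repeats=5, seed=0)
        assert modal_k == 1 and set(chosen) == {1}

    def test_three_planted_modes_resolved(self, rng):
        x = np.concatenate([rng.normal(m, 0.25, 200) for m in (1.0, 3.0, 6.0)])
        modal_k, chosen, fits = select_k_by_aic(x, k_max=5, repeats=20, seed=0)
        assert set(np.unique(chosen)) <= {2, 3, 4}
        assert modal_k in (2, 3)
        means = pooled_subpopulation_means(fits)
        for m in (1.0, 3.0, 6.0):
            assert np.min(np.abs(means - m)) < 0.3


class TestDensityRatio:
    def test_identical_samples_ratio_one(self, rng):
        x = rng.normal(3.0, 1.0, size=400)
        curve = area_density_ratio(x, x)
        assert curve.ratio[~curve.floored] == pytest.approx(1.0)

    def test_added_mass_peaks_at_its_location(self, rng):
        a = rng.uniform(0.5, 6.0, size=2000)
        b = np.concatenate([rng.uniform(0.5, 6.0, size=2000),
                            rng.normal(3.0, 0.15, size=700)])
        curve = area_density_ratio(a, b, bandwidth=0.2)
        inner = (curve.grid > 1.0) & (curve.grid < 5.5)
        peak = curve.grid[inner][np.argmax(curve.ratio[inner])]
        assert peak == pytest.approx(3.0, abs=0.25)

    def test_disjoint_supports_flagged(self, rng):
        a = rng.normal(1.0, 0.1, size=200)
        b = rng.normal(6.0, 0.1, size=200)
        curve = area_density_ratio(a, b)
        assert curve.floored.any()
        assert np.all(curve.ratio >= 0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            area_density_ratio([], [1.0, 2.0])

    def test_subsampling_stability(self, rng):
        x = rng.normal(3.0, 1.0, size=2000)
        y = np.concatenate([rng.normal(3.0, 1.0, 1000),
                            rng.normal(5.0, 0.3, 400)])
        grid = np.linspace(0, 8, 100)
        full = area_density_ratio(x, y, grid=grid, bandwidth=0.3)
        idx = rng.choice(2000, size=1000, replace=False)
        idy = rng.choice(len(y), size=700, replace=False)
        sub = area_density_ratio(x[idx], y[idy], grid=grid, bandwidth=0.3)
        keep = ~(full.floored | sub.floored)
        assert np.corrcoef(full.ratio[keep], sub.ratio[keep])[0, 1] > 0.9
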