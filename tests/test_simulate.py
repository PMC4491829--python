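"""Stochastic adhesion simulator: conversion draws, stepping, termination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmacdyn.probmaps import OUT_OF_RANGE, constant_map
from cmacdyn.simulate import (MAX_ITERATIONS, ModelParams, SimState,
                              draw_conversion_factor, simulate_population,
                              simulate_trajectory, step)

AREA_GRID = ((0.0, 6.0, 61), (-0.6, 0.6, 25))
TENSION_GRID = ((-5.0, 5.0, 41), (-1.0, 1.0, 21))


def _maps(area_value, tension_value):
    return (constant_map(area_value, grid=AREA_GRID),
            constant_map(tension_value, grid=TENSION_GRID,
                         names=("v_tension", "d_tension")))


class TestModelParams:
    def test_sigma_is_mu_over_nu(self):
        p = ModelParams(mu1=0.005, mu2=0.1, nu=0.25, tau1=1, tau2=2, tau3=3)
        assert p.sigma1 == pytest.approx(0.02)
        assert p.sigma2 == pytest.approx(0.4)

    def test_tau_band_selection(self):
        p = ModelParams(mu1=1, mu2=1, nu=1, tau1=1, tau2=2, tau3=3)
        assert p.tau_for_area(1.9) == 1
        assert p.tau_for_area(2.0) == 2
        assert p.tau_for_area(3.49) == 2
        assert p.tau_for_area(3.5) == 3

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(mu1=0.0, mu2=1, nu=1, tau1=1, tau2=1, tau3=1)


class TestConversionFactor:
    def test_moments(self):
        rng = np.random.default_rng(12)
        draws = np.array([draw_conversion_factor(0.05, 0.25, rng)
                          for _ in range(100_000)])
        se_mean = 0.2 / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(0.05, abs=3 * se_mean)
        assert draws.std() == pytest.approx(0.2, rel=0.02)

    def test_infinite_noise_factor_degenerates_to_mean(self):
        rng = np.random.default_rng(0)
        assert draw_conversion_factor(0.05, np.inf, rng) == 0.05

    def test_fixed_seed_reproducible(self):
        a = draw_conversion_factor(0.1, 0.5, np.random.default_rng(7))
        b = draw_conversion_factor(0.1, 0.5, np.random.default_rng(7))
        assert a == b


class TestStep:
    def test_zero_maps_fixed_point(self):
        amap, tmap = _maps(0.0, 0.0)
        p = ModelParams(mu1=0.005, mu2=0.1, nu=0.25, tau1=1, tau2=1, tau3=1)
        s = SimState(A=1.0, dA=0.2, T=0.5, dT=0.1, iteration=3)
        nxt = step(s, amap, tmap, p, np.random.default_rng(0))
        assert (nxt.A, nxt.T) == (1.0, 0.5)
        assert (nxt.dA, nxt.dT) == (0.0, 0.0)
        assert nxt.iteration == 4

    def test_deterministic_limit_full_drive(self):
        amap, tmap = _maps(1.0, 1.0)
        p = ModelParams(mu1=0.005, mu2=0.1, nu=np.inf, tau1=1, tau2=1, tau3=1)
        s = SimState(A=1.0, dA=0.0, T=0.5, dT=0.0)
        nxt = step(s, amap, tmap, p, np.random.default_rng(0))
        assert nxt.dT == pytest.approx(0.005)   # p_A = +1 → ΔT = μ1 exactly
        assert nxt.dA == pytest.approx(0.1)
        assert nxt.A == pytest.approx(1.1)

    def test_hand_computed_step_with_seeded_noise(self):
        amap, tmap = _maps(0.5, -0.8)
        p = ModelParams(mu1=0.01, mu2=0.2, nu=2.0, tau1=1, tau2=1, tau3=1)
        rng = np.random.default_rng(99)
        phi1_expected = np.random.default_rng(99).normal(0.01, 0.005)
        s = SimState(A=2.0, dA=0.1, T=0.2, dT=0.0)
        nxt = step(s, amap, tmap, p, rng)
        assert nxt.dT == pytest.approx(0.5 * phi1_expected)
        assert nxt.T == pytest.approx(0.2 + 0.5 * phi1_expected)

    def test_out_of_range_propagates(self):
        amap, tmap = _maps(0.0, 0.0)
        p = ModelParams(mu1=0.005, mu2=0.1, nu=1.0, tau1=1, tau2=1, tau3=1)
        s = SimState(A=7.0, dA=0.0, T=0.5, dT=0.0)
        assert step(s, amap, tmap, p, np.random.default_rng(0)) is OUT_OF_RANGE


class TestTermination:
    @pytest.mark.parametrize("tau1", [1, 3, 10])
    def test_all_zero_maps_metastable_at_4_plus_tau1(self, tau1):
        amap, tmap = _maps(0.0, 0.0)
        p = ModelParams(mu1=0.005, mu2=0.1, nu=0.25, tau1=tau1, tau2=7, tau3=9)
        tr = simulate_trajectory(amap, tmap, p, seed=0)
        assert tr.termination == "IV"
        assert tr.lifetime == 4 + tau1      # area 0.2 μm² < 2 μm² → τ1 band

    def test_monotone_shrinkage_closed_form_type_i(self):
        # tension map ≡ -1, deterministic limit: ΔA = -μ2 per iteration from
        # A₀ = 1.0 down to the 0.2 μm² dissolution threshold
        mu2 = 0.17
        amap, tmap = _maps(0.0, -1.0)
        p = ModelParams(mu1=0.005, mu2=mu2, nu=np.inf, tau1=5, tau2=5, tau3=5)
        tr = simulate_trajectory(amap, tmap, p, seed=0, init=(1.0, -0.2, 0.5))
        assert tr.termination == "I"
        assert tr.lifetime == int(np.ceil((1.0 - 0.2) / mu2))

    def test_truncated_grid_with_positive_drift_exits(self):
        small_grid = ((0.0, 1.0, 11), (-0.6, 0.6, 25))
        amap = constant_map(0.0, grid=small_grid)
        tmap = constant_map(1.0, grid=TENSION_GRID,
                            names=("v_tension", "d_tension"))
        p = ModelParams(mu1=0.005, mu2=0.3, nu=np.inf, tau1=9, tau2=9, tau3=9)
        tr = simulate_trajectory(amap, tmap, p, seed=0)
        assert tr.termination == "II"

    def test_iteration_cap_reached_when_dynamic(self):
        # oscillation that never stabilizes nor dissolves: tension map +1,
        # large deterministic steps bouncing within the grid would exit, so
        # use tiny tension... instead alternate via noise-free zero area map
        amap, tmap = _maps(0.0, 1.0)
        p = ModelParams(mu1=0.005, mu2=0.11, nu=np.inf, tau1=9, tau2=9, tau3=9)
        tr = simulate_trajectory(amap, tmap, p, seed=0, max_iter=30)
        # grows by 0.11 per step (> stability delta) until the area grid
        # truncates it — with a cap below the exit time the cap wins
        assert tr.termination in ("II", "III")
        if tr.termination == "III":
            assert tr.lifetime == 30


class TestPopulation:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_termination_partition_fuzz(self, seed):
        """Every trajectory gets exactly one termination type and the
        population frequencies form a probability distribution, whatever
        the maps and parameters."""
        rng = np.random.default_rng(seed)
        amap = constant_map(float(rng.uniform(-1, 1)), grid=AREA_GRID)
        tmap = constant_map(float(rng.uniform(-1, 1)), grid=TENSION_GRID,
                            names=("v_tension", "d_tension"))
        p = ModelParams(mu1=float(rng.uniform(0.001, 0.01)),
                        mu2=float(rng.uniform(0.02, 0.8)),
                        nu=float(rng.uniform(0.06, 0.5)),
                        tau1=int(rng.integers(1, 11)),
                        tau2=int(rng.integers(1, 11)),
                        tau3=int(rng.integers(1, 11)))
        trajs, freqs = simulate_population(amap, tmap, p, n=40,
                                           seed=int(rng.integers(2 ** 31)),
                                           max_iter=200)
        assert sum(freqs.values()) == pytest.approx(1.0)
        assert all(tr.termination in ("I", "II", "III", "IV") for tr in trajs)
        for tr in trajs:
            if tr.termination == "III":
                assert tr.lifetime == 200

    def test_population_deterministic_given_master_seed(self):
        amap, tmap = _maps(0.3, 0.2)
        p = ModelParams(mu1=0.005, mu2=0.1, nu=0.25, tau1=3, tau2=3, tau3=3)
        _, f1 = simulate_population(amap, tmap, p, n=50, seed=21)
        _, f2 = simulate_population(amap, tmap, p, n=50, seed=21)
        assert f1 == f2

    def test_deterministic_limit_needs_no_seed(self):
        amap, tmap = _maps(0.4, 0.3)
        p = ModelParams(mu1=0.005, mu2=0.12, nu=np.inf, tau1=3, tau2=3, tau3=3)
        t1 = simulate_trajectory(amap, tmap, p, seed=1, max_iter=100)
        t2 = simulate_trajectory(amap, tmap, p, seed=999, max_iter=100)
        np.testing.assert_allclose(t1.areas, t2.areas)
        assert t1.termination == t2.termination

    def test_unit_consistency_under_tension_rescaling(self):
        """Scaling μ1 and the tension-map axis by a common factor leaves
        the area path unchanged in the deterministic limit."""
        rng = np.random.default_rng(3)
        net = rng.uniform(-1, 1, size=(41, 21))
        scale = 10.0
        tmap1 = constant_map(0.0, grid=TENSION_GRID,
                             names=("v_tension", "d_tension"))
        tmap1.net = net.copy()
        tmap2 = constant_map(0.0, grid=((-50.0, 50.0, 41), (-10.0, 10.0, 21)),
                             names=("v_tension", "d_tension"))
        tmap2.net = net.copy()
        amap = constant_map(0.6, grid=AREA_GRID)
        p1 = ModelParams(mu1=0.02, mu2=0.12, nu=np.inf, tau1=3, tau2=3, tau3=3)
        p2 = ModelParams(mu1=0.02 * scale, mu2=0.12, nu=np.inf,
                         tau1=3, tau2=3, tau3=3)
        t1 = simulate_trajectory(amap, tmap1, p1, seed=0, max_iter=60,
                                 init=(0.2, 0.1, 0.1))
        t2 = simulate_trajectory(amap, tmap2, p2, seed=0, max_iter=60,
                                 init=(0.2, 0.1, 1.0))
        np.testing.assert_allclose(t1.areas, t2.areas, atol=1e-10)
        assert t1.termination == t2.termination
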