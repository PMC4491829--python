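"""Model grid enumeration and χ² goodness-of-fit selection.

The simulator has six free parameters (μ1, μ2, ν, τ1, τ2, τ3).  The model
space is the full Cartesian product of per-parameter value lists — with the
canonical lists (4·5·4·5·5·5) that is 10,000 distinct models.  Each model
simulates a population of trajectories; five feature distributions (area,
tension, Δarea, Δtension, lifetime) are pooled from that population and
scored against the corresponding empirical distributions with a Pearson χ²
goodness-of-fit statistic on quantile bins of the empirical reference.
Objectives are single features or unweighted sums over feature subsets; the
argmin per objective is the optimally fitting model.
"""

from __future__ import annotations

import itertools
import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ModelParams, simulate_population

logger = logging.getLogger(__name__)

FEATURES = ("area", "v_tension", "d_area", "d_tension", "lifetime")

#: Canonical six value lists of the model space (μ1, μ2, ν, τ1, τ2, τ3).
CANONICAL_GRID_LISTS = {
    "mu1": (0.001, 0.025, 0.005, 0.0075),
    "mu2": (0.025, 0.05, 0.1, 0.5, 0.75),
    "nu": (0.0625, 0.125, 0.25, 0.5),
    "tau1": (1, 2, 3, 5, 10),
    "tau2": (1, 2, 3, 5, 10),
    "tau3": (1, 2, 3, 5, 10),
}

DEFAULT_OBJECTIVES = {
    "area": ("area",),
    "lifetime": ("lifetime",),
    "area+lifetime": ("area", "lifetime"),
    "all": FEATURES,
}

DEFAULT_N_BINS = 20


@dataclass
class FeatureDistributions:
    """Pooled per-feature sample sets from one population (empirical or
    simulated)."""

    area: np.ndarray
    v_tension: np.ndarray
    d_area: np.ndarray
    d_tension: np.ndarray
    lifetime: np.ndarray
    source: str = "empirical"

    def __post_init__(self) -> None:
        for name in FEATURES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size == 0:
                raise ValueError(f"feature sample set {name!r} is empty")
            setattr(self, name, arr)
        if np.any(self.lifetime <= 0):
            raise ValueError("lifetimes must be positive")


@dataclass
class GofResult:
    params: ModelParams
    chi2: dict             # feature -> χ² value
    scores: dict           # objective -> summed χ²
    ranks: dict = field(default_factory=dict)   # objective -> 0-based rank


def features_from_processed(tracks) -> FeatureDistributions:
    """Empirical feature distributions from filtered processed tracks
    (lifetimes in timepoints)."""
    tracks = list(tracks)
    return FeatureDistributions(
        area=np.concatenate([t.area_smooth for t in tracks]),
        v_tension=np.concatenate([t.v_tension for t in tracks]),
        d_area=np.concatenate([t.d_area for t in tracks]),
        d_tension=np.concatenate([t.d_tension for t in tracks]),
        lifetime=np.array([t.lifetime for t in tracks], dtype=float),
        source="empirical",
    )


def features_from_trajectories(trajectories, source: str = "model") -> FeatureDistributions:
    """Synthetic feature distributions pooled over a simulated population
    (lifetimes in iterations)."""
    trajectories = list(trajectories)
    return FeatureDistributions(
        area=np.concatenate([tr.areas for tr in trajectories]),
        v_tension=np.concatenate([tr.tensions for tr in trajectories]),
        d_area=np.concatenate([tr.d_areas for tr in trajectories]
                              or [np.array([0.0])]),
        d_tension=np.concatenate([tr.d_tensions for tr in trajectories]
                                 or [np.array([0.0])]),
        lifetime=np.array([max(tr.lifetime, 1) for tr in trajectories], dtype=float),
        source=source,
    )


def build_parameter_grid(mu1_list, mu2_list, nu_list, tau1_list, tau2_list,
                         tau3_list) -> list[ModelParams]:
    """Full Cartesian product in lexicographic order (μ1 outermost, τ3
    innermost)."""
    lists = [mu1_list, mu2_list, nu_list, tau1_list, tau2_list, tau3_list]
    if any(len(l) == 0 for l in lists):
        raise ValueError("every parameter value list must be non-empty")
    return [ModelParams(mu1=a, mu2=b, nu=c, tau1=d, tau2=e, tau3=f)
            for a, b, c, d, e, f in itertools.product(*lists)]


def canonical_grid() -> list[ModelParams]:
    """The canonical 10,000-model grid."""
    return build_parameter_grid(*CANONICAL_GRID_LISTS.values())


def chi2_gof(sample, reference, n_bins: int = DEFAULT_N_BINS) -> float:
    """Pearson χ² of ``sample`` against ``reference`` on quantile bins.

    Bin edges are ``n_bins``-quantiles of the reference (outermost bins
    open-ended, so every sample value is counted); expected counts are the
    reference bin proportions scaled to the sample size; the statistic sums
    (obs − exp)²/exp over bins with positive expectation.  Invariant under
    any common strictly monotone transform of both samples.
    """
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sample.size == 0 or reference.size == 0:
        raise ValueError("both sample and reference must be non-empty")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    qs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    # inverted-CDF quantiles are reference data values, making the statistic
    # exactly invariant under common strictly monotone transforms
    inner = np.unique(np.quantile(reference, qs, method="inverted_cdf"))
    # an inner edge equal to the reference maximum would leave an empty bin
    inner = inner[inner < reference.max()]
    if len(inner) + 1 < n_bins:
        warnings.warn(
            f"reference has too few distinct values for {n_bins} bins; "
            f"using {len(inner) + 1}", stacklevel=2)
    # right-closed bins (-inf, e1], (e1, e2], ..., (e_k, inf): edges are
    # reference data values, so ties at an edge stay in the lower bin
    n_eff = len(inner) + 1
    ref_counts = np.bincount(np.searchsorted(inner, reference, side="left"),
                             minlength=n_eff)
    obs_counts = np.bincount(np.searchsorted(inner, sample, side="left"),
                             minlength=n_eff)
    expected = ref_counts / reference.size * sample.size
    mask = expected > 0
    return float(np.sum((obs_counts[mask] - expected[mask]) ** 2 / expected[mask]))


def _model_seed(master_seed: int, params: ModelParams) -> np.random.SeedSequence:
    # Seed derived from the parameter values (not the grid position) so
    # scores are invariant to grid permutation.
    key = repr((params.mu1, params.mu2, params.nu,
                params.tau1, params.tau2, params.tau3)).encode()
    return np.random.SeedSequence([int(master_seed), zlib.crc32(key)])


def score_model(params: ModelParams, empirical: FeatureDistributions,
                area_map, tension_map, n_traj: int, seed: int,
                n_bins: int = DEFAULT_N_BINS, **sim_kwargs) -> GofResult:
    """Simulate one model population and score it feature-by-feature."""
    ss = _model_seed(seed, params)
    trajectories, _ = simulate_population(area_map, tension_map, params,
                                          n=n_traj,
                                          seed=ss.generate_state(1)[0],
                                          **sim_kwargs)
    synth = features_from_trajectories(trajectories)
    chi2 = {feat: chi2_gof(getattr(synth, feat), getattr(empirical, feat),
                           n_bins=n_bins)
            for feat in FEATURES}
    return GofResult(params=params, chi2=chi2, scores={})


def grid_search(grid, empirical: FeatureDistributions, area_map, tension_map,
                n_traj: int = 1000, seed: int = 0,
                objectives: dict | None = None,
                n_bins: int = DEFAULT_N_BINS,
                **sim_kwargs) -> list[GofResult]:
    """Score every model of the grid and rank per objective.

    Ranks are 0-based; ties are broken by the documented lexicographic grid
    order of the parameter tuples (stable under grid permutation).
    """
    objectives = objectives or DEFAULT_OBJECTIVES
    results = []
    for i, params in enumerate(grid):
        res = score_model(params, empirical, area_map, tension_map,
                          n_traj=n_traj, seed=seed, n_bins=n_bins, **sim_kwargs)
        res.scores = {name: float(sum(res.chi2[f] for f in feats))
                      for name, feats in objectives.items()}
        results.append(res)
        if (i + 1) % 50 == 0:
            logger.info("grid_search: scored %d/%d models", i + 1, len(grid))
    for name in objectives:
        order = sorted(
            range(len(results)),
            key=lambda k: (results[k].scores[name],
                           _param_tuple(results[k].params)))
        for rank, k in enumerate(order):
            results[k].ranks[name] = rank
    return results


def _param_tuple(p: ModelParams):
    return (p.mu1, p.mu2, p.nu, p.tau1, p.tau2, p.tau3)


def results_to_frame(results) -> pd.DataFrame:
    rows = []
    for res in results:
        row = dict(zip(("mu1", "mu2", "nu", "tau1", "tau2", "tau3"),
                       _param_tuple(res.params)))
        row |= {f"chi2_{f}": res.chi2[f] for f in FEATURES}
        row |= {f"score_{o}": s for o, s in res.scores.items()}
        row |= {f"rank_{o}": r for o, r in res.ranks.items()}
        rows.append(row)
    return pd.DataFrame(rows)


def best_models(results, objectives=None) -> dict:
    """Argmin model per objective."""
    if not results:
        raise ValueError("no results to select from")
    objectives = objectives or list(results[0].scores)
    return {name: min(results, key=lambda r: (r.scores[name],
                                              _param_tuple(r.params)))
            for name in objectives}
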