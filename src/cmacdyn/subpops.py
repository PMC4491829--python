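"""Metastable-adhesion detection, GMM decomposition and condition comparison.

Metastable ("steady-state") adhesions are those whose area stops varying.
Empirically they are detected as repeated area values at consecutive
timepoints (raw segmentation areas are pixel-quantized, so exact repeats
are meaningful); in simulated populations they are the termination-type-IV
trajectories.  The resulting area samples are decomposed into Gaussian
mixture subpopulations by EM, with the component count chosen by minimal
AIC over repeated bootstrap fits.  Treatment effects on the adhesion-size
distribution (e.g. microtubule disruption by nocodazole) are compared as a
kernel-density ratio between two conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

DEFAULT_VARIANCE_FLOOR = 1e-4   # μm⁴
DEFAULT_N_INIT = 10
DEFAULT_REPEATS = 100


@dataclass
class GmmFit:
    """One-dimensional Gaussian mixture decomposition.

    ``n_params = 3k - 1`` (k means, k s.d.s, k−1 free weights) and
    ``aic = 2·n_params − 2·loglik``.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    aic: float
    degenerate: bool = False

    @property
    def n_params(self) -> int:
        return 3 * self.k - 1


@dataclass
class DensityRatioCurve:
    grid: np.ndarray
    ratio: np.ndarray
    bandwidth: float
    n_a: int
    n_b: int
    floored: np.ndarray = field(default=None)   # where the denominator hit the floor
    peaks: np.ndarray = field(default=None)     # grid locations of ratio peaks


def stable_areas_empirical(tracks, tol: float = 0.0) -> np.ndarray:
    """Area values of empirical stability events.

    A stability event is an area value repeated (within ``tol``) at the next
    timepoint; each consecutive repeated pair emits the earlier value once.
    Uses raw (unsmoothed) areas, where exact repeats are meaningful.
    """
    out = []
    for t in tracks:
        a = np.asarray(t.area_raw, dtype=float)
        hits = np.abs(np.diff(a)) <= tol
        out.extend(a[:-1][hits])
    return np.asarray(out, dtype=float)


def stable_areas_synthetic(trajectories) -> np.ndarray:
    """Terminal area of every termination-type-IV trajectory."""
    areas = np.array([tr.states[-1].A for tr in trajectories
                      if tr.termination == "IV"], dtype=float)
    if areas.size == 0:
        logger.info("stable_areas_synthetic: no type-IV trajectories in population")
    return areas


def fit_gmm(values, k: int, n_init: int = DEFAULT_N_INIT, seed: int = 0,
            variance_floor: float = DEFAULT_VARIANCE_FLOOR,
            score_values=None) -> GmmFit:
    """Best-of-``n_init`` EM fit of a k-component 1-D Gaussian mixture.

    Variances are floored at ``variance_floor`` to avoid singular
    components; an all-identical sample yields a flagged degenerate fit.
    ``score_values`` evaluates the reported log-likelihood/AIC on a sample
    other than the one fit (used by bootstrap model selection, where
    scoring on the original sample keeps duplicated resample points from
    rewarding spurious spike components).
    """
    values = np.asarray(values, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if values.size < 3 * k:
        raise ValueError(f"need at least {3 * k} values to fit k={k} components")
    x = values.reshape(-1, 1)
    degenerate = np.ptp(values) == 0.0
    gm = GaussianMixture(n_components=k, covariance_type="full",
                         reg_covar=variance_floor, n_init=n_init,
                         random_state=seed, max_iter=300)
    import warnings
    with warnings.catch_warnings():
        # k-means seeding on resamples with duplicated points warns about
        # fewer distinct clusters than components; expected and harmless
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(x)
    score_on = values if score_values is None else np.asarray(score_values, float)
    loglik = float(gm.score(score_on.reshape(-1, 1)) * score_on.size)
    order = np.argsort(gm.means_.ravel())
    n_params = 3 * k - 1
    return GmmFit(k=k,
                  weights=gm.weights_[order],
                  means=gm.means_.ravel()[order],
                  sds=np.sqrt(gm.covariances_.ravel()[order]),
                  loglik=loglik,
                  aic=2.0 * n_params - 2.0 * loglik,
                  degenerate=degenerate)


def select_k_by_aic(values, k_max: int = 5, repeats: int = DEFAULT_REPEATS,
                    seed: int = 0, n_init: int = DEFAULT_N_INIT,
                    bootstrap: bool = True):
    """Repeated AIC-based selection of the mixture component count.

    Each repeat bootstrap-resamples the values (or merely re-seeds the EM
    when ``bootstrap=False``), fits k = 1..k_max and keeps the minimal-AIC
    fit.  Returns ``(modal_k, chosen_ks, fits)`` where ``chosen_ks`` is the
    per-repeat chosen k and ``fits`` the corresponding best fits, from which
    subpopulation means/weights across repeats can be pooled.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3 * k_max:
        raise ValueError(f"need at least {3 * k_max} values for k_max={k_max}")
    rng = np.random.default_rng(seed)
    chosen_ks = np.empty(repeats, dtype=int)
    fits: list[GmmFit] = []
    for rep in range(repeats):
        sample = rng.choice(values, size=values.size, replace=True) if bootstrap else values
        best = None
        for k in range(1, k_max + 1):
            fit = fit_gmm(sample, k, n_init=n_init,
                          seed=int(rng.integers(2 ** 31)),
                          score_values=values if bootstrap else None)
            if best is None or fit.aic < best.aic:
                best = fit
        chosen_ks[rep] = best.k
        fits.append(best)
    ks, counts = np.unique(chosen_ks, return_counts=True)
    modal_k = int(ks[np.argmax(counts)])
    return modal_k, chosen_ks, fits


def pooled_subpopulation_means(fits) -> np.ndarray:
    """All component means across repeats (one pooled sample for mode
    localization, mirroring per-repeat subpopulation summaries)."""
    return np.concatenate([f.means for f in fits])


def area_density_ratio(areas_a, areas_b, grid=None, bandwidth=None,
                       density_floor: float = 1e-4) -> DensityRatioCurve:
    """Ratio of kernel density estimates density_b / density_a on a shared
    grid (condition b relative to reference a), with the denominator
    floored; floored regions are flagged and the ratio peaks reported."""
    a = np.asarray(areas_a, dtype=float)
    b = np.asarray(areas_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if grid is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        pad = 0.05 * (hi - lo + 1e-12)
        grid = np.linspace(lo - pad, hi + pad, 256)
    grid = np.asarray(grid, dtype=float)
    if bandwidth is not None:
        factor_a = bandwidth / max(a.std(ddof=1), 1e-12)
        factor_b = bandwidth / max(b.std(ddof=1), 1e-12)
        kde_a = gaussian_kde(a, bw_method=factor_a)
        kde_b = gaussian_kde(b, bw_method=factor_b)
        bw = float(bandwidth)
    else:
        kde_a = gaussian_kde(a)
        kde_b = gaussian_kde(b)
        bw = float(kde_a.factor * a.std(ddof=1))
    dens_a = kde_a(grid)
    dens_b = kde_b(grid)
    floored = dens_a < density_floor
    if floored.any():
        logger.info("area_density_ratio: %d/%d grid points below density floor",
                    int(floored.sum()), len(grid))
    ratio = dens_b / np.maximum(dens_a, density_floor)
    peak_idx, _ = find_peaks(ratio)
    return DensityRatioCurve(grid=grid, ratio=ratio, bandwidth=bw,
                             n_a=a.size, n_b=b.size, floored=floored,
                             peaks=grid[peak_idx])
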