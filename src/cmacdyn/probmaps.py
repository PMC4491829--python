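"""Conditional net-probability maps of cross-correlation sign and lag order.

Each significant window observation carries a binary outcome — the sign of
its cross-correlation, or which signal led — together with a state context
(value, Δvalue).  Kernel regression of the binary label on that plane gives
the pointwise probability p⁺ of a positive outcome; with p⁻ = 1 − p⁺ the
*net probability* is

    net = p⁺ − p⁻ = 2·p⁺ − 1  ∈ [−1, 1]

estimated on a regular grid by Nadaraya–Watson regression with a product
Gaussian kernel.  A support mask marks grid nodes whose kernel-weighted
observation count reaches a density floor, so the downstream simulator is
never driven by extrapolated ±1 regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class OutOfRange:
    """Sentinel for map lookups outside the grid (termination type II)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "OUT_OF_RANGE"


OUT_OF_RANGE = OutOfRange()

#: Kernel-weighted equivalent-observation count required for support.
DEFAULT_DENSITY_FLOOR = 5.0

#: Default area-map grid: area 0–6 μm², Δarea ±0.6 μm².
DEFAULT_AREA_GRID = ((0.0, 6.0, 61), (-0.6, 0.6, 25))


@dataclass
class NetProbabilityMap:
    """Gridded net probability of a binary outcome on a (value, Δvalue) plane."""

    x_name: str
    dx_name: str
    grid_x: np.ndarray          # shape (nx,), regularly spaced
    grid_dx: np.ndarray         # shape (ndx,)
    net: np.ndarray             # shape (nx, ndx), in [-1, 1]
    support: np.ndarray         # bool, shape (nx, ndx)
    bandwidths: tuple[float, float]
    n_obs: int

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_dx = np.asarray(self.grid_dx, dtype=float)
        self.net = np.asarray(self.net, dtype=float)
        self.support = np.asarray(self.support, dtype=bool)
        if self.net.shape != (len(self.grid_x), len(self.grid_dx)):
            raise ValueError("net grid shape does not match axes")
        if self.support.shape != self.net.shape:
            raise ValueError("support grid shape does not match net")


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb, 0.9·min(σ, IQR/1.34)·n^(−1/5)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need >= 2 observations for a bandwidth")
    sd = v.std(ddof=1)
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale == 0:
        scale = max(abs(v).max(), 1.0) * 1e-3  # degenerate cloud
    return 0.9 * scale * n ** (-0.2)


def binarize_sign(observations) -> np.ndarray:
    """Label 1 for positive, 0 for negative cross-correlation."""
    r = np.array([o.r for o in observations], dtype=float)
    if np.any(r == 0):
        raise ValueError("r = 0 cannot be binarized (should not occur post-gate)")
    return (r > 0).astype(float)


def _kernel_regression(x, dx, labels, grid_x, grid_dx, bandwidths, density_floor):
    hx, hdx = bandwidths
    if hx <= 0 or hdx <= 0:
        raise ValueError("bandwidths must be positive")
    # unnormalized Gaussian weights: a coincident observation counts as 1
    wx = np.exp(-0.5 * ((grid_x[:, None] - x[None, :]) / hx) ** 2)      # (nx, n)
    wdx = np.exp(-0.5 * ((grid_dx[:, None] - dx[None, :]) / hdx) ** 2)  # (ndx, n)
    mass = np.einsum("in,jn->ij", wx, wdx)
    signed = np.einsum("in,jn->ij", wx, wdx * (2.0 * labels - 1.0)[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        net = np.where(mass > 0, signed / mass, 0.0)
    support = mass >= density_floor
    return net, support


def _build_map(observations, values, dvalues, labels, names, grid, bandwidths,
               density_floor) -> NetProbabilityMap:
    if len(observations) == 0:
        raise ValueError("cannot build a map from zero observations")
    x = np.asarray(values, dtype=float)
    dx = np.asarray(dvalues, dtype=float)
    if grid is None:
        raise ValueError("a grid specification is required")
    (x0, x1, nx), (d0, d1, ndx) = grid
    grid_x = np.linspace(x0, x1, nx)
    grid_dx = np.linspace(d0, d1, ndx)
    if bandwidths is None:
        bandwidths = (silverman_bandwidth(x), silverman_bandwidth(dx))
    net, support = _kernel_regression(x, dx, labels, grid_x, grid_dx,
                                      bandwidths, density_floor)
    return NetProbabilityMap(x_name=names[0], dx_name=names[1],
                             grid_x=grid_x, grid_dx=grid_dx, net=net,
                             support=support, bandwidths=tuple(bandwidths),
                             n_obs=len(x))


def percentile_grid(values, dvalues, n=(41, 21), lo=1.0, hi=99.0):
    """Data-driven grid spec spanning the [lo, hi] percentiles of each axis."""
    v = np.asarray(values, dtype=float)
    dv = np.asarray(dvalues, dtype=float)
    a, b = np.percentile(v, [lo, hi])
    c, d = np.percentile(dv, [lo, hi])
    return ((float(a), float(b), n[0]), (float(c), float(d), n[1]))


def sign_probability_map(observations, space: str = "area", grid=None,
                         bandwidths=None,
                         density_floor: float = DEFAULT_DENSITY_FLOOR) -> NetProbabilityMap:
    """Net probability of positive vs negative cross-correlation conditioned
    on (area, Δarea) (``space="area"``) or (tension, Δtension)
    (``space="tension"``).

    The area grid defaults to [0, 6] μm² × [−0.6, 0.6] μm²; the tension grid
    defaults to the observations' 1st–99th percentiles.  Bandwidths default
    to Silverman's rule per axis.
    """
    observations = list(observations)
    labels = binarize_sign(observations)
    if space == "area":
        values = [o.A0 for o in observations]
        dvalues = [o.dA for o in observations]
        names = ("area", "d_area")
        if grid is None:
            grid = DEFAULT_AREA_GRID
    elif space == "tension":
        values = [o.T0 for o in observations]
        dvalues = [o.dT for o in observations]
        names = ("v_tension", "d_tension")
        if grid is None:
            grid = percentile_grid(values, dvalues)
    else:
        raise ValueError(f"unknown space {space!r}")
    return _build_map(observations, values, dvalues, labels, names, grid,
                      bandwidths, density_floor)


def lag_ordering_map(observations, grid=None, bandwidths=None,
                     density_floor: float = DEFAULT_DENSITY_FLOOR) -> NetProbabilityMap:
    """Net probability that area leads (+1 pole) vs tension leads (−1 pole)
    in (area, Δarea) space.

    Positive observation lag means tension precedes area, so the label is
    1 for ``lag < 0`` (area leads) and 0 for ``lag > 0``.  Zero-lag
    observations carry no ordering information and are excluded (logged).
    """
    observations = list(observations)
    nonzero = [o for o in observations if o.lag != 0]
    if len(nonzero) < len(observations):
        logger.info("lag_ordering_map: excluded %d zero-lag observations",
                    len(observations) - len(nonzero))
    observations = nonzero
    if not observations:
        raise ValueError("no ordering information: all observations have lag 0")
    labels = np.array([1.0 if o.lag < 0 else 0.0 for o in observations])
    values = [o.A0 for o in observations]
    dvalues = [o.dA for o in observations]
    if grid is None:
        grid = DEFAULT_AREA_GRID
    return _build_map(observations, values, dvalues, labels,
                      ("area", "d_area"), grid, bandwidths, density_floor)


def map_lookup(pmap: NetProbabilityMap, x: float, dx: float):
    """Bilinear interpolation of the net grid; coordinates outside the grid
    return :data:`OUT_OF_RANGE` (a value, not an exception)."""
    gx, gdx = pmap.grid_x, pmap.grid_dx
    if not (gx[0] <= x <= gx[-1]) or not (gdx[0] <= dx <= gdx[-1]):
        return OUT_OF_RANGE
    i = min(int(np.searchsorted(gx, x, side="right")) - 1, len(gx) - 2)
    j = min(int(np.searchsorted(gdx, dx, side="right")) - 1, len(gdx) - 2)
    i = max(i, 0)
    j = max(j, 0)
    fx = (x - gx[i]) / (gx[i + 1] - gx[i])
    fy = (dx - gdx[j]) / (gdx[j + 1] - gdx[j])
    n = pmap.net
    return float((1 - fx) * (1 - fy) * n[i, j] + fx * (1 - fy) * n[i + 1, j]
                 + (1 - fx) * fy * n[i, j + 1] + fx * fy * n[i + 1, j + 1])


def write_map(pmap: NetProbabilityMap, path) -> None:
    """Serialize a map as a single CSV with '#'-prefixed metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"# x_name={pmap.x_name}\n")
        fh.write(f"# dx_name={pmap.dx_name}\n")
        fh.write(f"# bandwidth_x={float(pmap.bandwidths[0])!r}\n")
        fh.write(f"# bandwidth_dx={float(pmap.bandwidths[1])!r}\n")
        fh.write(f"# n_obs={pmap.n_obs}\n")
        fh.write("x,dx,net,support\n")
        for i, xv in enumerate(pmap.grid_x):
            for j, dv in enumerate(pmap.grid_dx):
                fh.write(f"{float(xv)!r},{float(dv)!r},{float(pmap.net[i, j])!r},"
                         f"{int(pmap.support[i, j])}\n")


def read_map(path) -> NetProbabilityMap:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    grid_x = np.unique(df["x"].to_numpy())
    grid_dx = np.unique(df["dx"].to_numpy())
    nx, ndx = len(grid_x), len(grid_dx)
    net = df["net"].to_numpy().reshape(nx, ndx)
    support = df["support"].to_numpy().astype(bool).reshape(nx, ndx)
    return NetProbabilityMap(x_name=meta["x_name"], dx_name=meta["dx_name"],
                             grid_x=grid_x, grid_dx=grid_dx, net=net,
                             support=support,
                             bandwidths=(float(meta["bandwidth_x"]),
                                         float(meta["bandwidth_dx"])),
                             n_obs=int(meta["n_obs"]))


def constant_map(value: float, grid=DEFAULT_AREA_GRID, names=("area", "d_area"),
                 bandwidths=(1.0, 1.0)) -> NetProbabilityMap:
    """Uniform map (testing/modelling aid), fully supported."""
    (x0, x1, nx), (d0, d1, ndx) = grid
    gx = np.linspace(x0, x1, nx)
    gdx = np.linspace(d0, d1, ndx)
    return NetProbabilityMap(x_name=names[0], dx_name=names[1], grid_x=gx,
                             grid_dx=gdx, net=np.full((nx, ndx), float(value)),
                             support=np.ones((nx, ndx), bool),
                             bandwidths=bandwidths, n_obs=0)
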