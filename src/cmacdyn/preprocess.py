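"""Channel-to-tension conversion, smoothing, deltas and track filters.

The FRET readout of the vinculin tension sensor is the per-adhesion ratio of
mean Venus (acceptor/FRET) to mean mTFP1 (donor) intensity.  High tension
stretches the sensor's elastic linker and lowers FRET, so the ratio is
log-transformed and inverted to yield a quantity that increases with
tension::

    T = -ln(venus_mean / mtfp1_mean)

T is in arbitrary (log-ratio) units; the log base only rescales it.  The
average of the two channels ("CY" signal) serves as a sensor-concentration
proxy.  Area, tension and CY series are smoothed with a cubic smoothing
spline before first differences are taken, and tracks are filtered on
lifetime and area-range criteria before any cross-correlation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .io import TrackTable

logger = logging.getLogger(__name__)

#: Default spline smoothing factor (near-interpolation).
DEFAULT_SMOOTHING_P = float(np.exp(-1e-6))

#: Strict lower bound on track lifetime (timepoints) for retention.
MIN_LIFETIME = 5
#: Strict lower bound on the absolute range of area variation (μm²).
MIN_AREA_RANGE = 0.5


@dataclass
class SmoothingConfig:
    """Cubic smoothing-spline parameterization.

    The spline minimizes ``p·Σ(y-f)² + (1-p)·∫f″²`` with ``0 < p ≤ 1``;
    ``p → 1`` is interpolation.  The default ``p = exp(-1e-6)`` is
    near-interpolating: it removes pixel-level jitter while preserving
    every real fluctuation at 30-s sampling.
    """

    p: float = DEFAULT_SMOOTHING_P

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"smoothing factor p must be in (0, 1], got {self.p}")


@dataclass
class ProcessedTrack:
    """One track after tension conversion, smoothing and differencing.

    All per-timepoint series have equal length ``n``; the delta series have
    length ``n - 1`` (forward differences of the smoothed series).
    """

    cell_id: object
    track_id: object
    timepoint: np.ndarray
    area_raw: np.ndarray
    area_smooth: np.ndarray
    v_tension: np.ndarray        # smoothed log-ratio tension signal
    v_tension_raw: np.ndarray
    cy: np.ndarray
    d_area: np.ndarray
    d_tension: np.ndarray

    @property
    def lifetime(self) -> int:
        return len(self.timepoint)

    @property
    def area_range(self) -> float:
        return float(self.area_raw.max() - self.area_raw.min())


def ratio_to_tension(venus_mean, mtfp1_mean):
    """Invert the linearized FRET ratio into a tension signal.

    ``T = -ln(venus/mtfp1)`` — strictly decreasing in the FRET ratio, so
    higher values mean higher per-molecule tension.  Accepts scalars or
    arrays; both intensities must be strictly positive.
    """
    venus = np.asarray(venus_mean, dtype=float)
    mtfp1 = np.asarray(mtfp1_mean, dtype=float)
    if np.any(venus <= 0) or np.any(mtfp1 <= 0):
        raise ValueError("channel intensities must be strictly positive to form a FRET ratio")
    out = -np.log(venus / mtfp1)
    return out if out.ndim else float(out)


def compute_cy(mtfp1_mean, venus_mean):
    """Sensor-concentration proxy: arithmetic mean of the two channel means."""
    mtfp1 = np.asarray(mtfp1_mean, dtype=float)
    venus = np.asarray(venus_mean, dtype=float)
    out = 0.5 * (mtfp1 + venus)
    return out if out.ndim else float(out)


def smooth_series(y, cfg: SmoothingConfig | None = None) -> np.ndarray:
    """Cubic smoothing spline evaluated at the input timepoints.

    Minimizes ``p·Σ(y-f)² + (1-p)·∫f″²`` (equivalently scipy's
    ``Σ(y-f)² + λ∫f″²`` with ``λ = (1-p)/p``).  Series shorter than five
    points are returned via natural-cubic interpolation, the ``p → 1``
    limit (indistinguishable at the near-interpolation default).
    """
    cfg = cfg or SmoothingConfig()
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("smooth_series requires a 1-D series of length >= 2")
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        raise ValueError(f"non-finite value in series at index {bad[0]}")
    x = np.arange(len(y), dtype=float)
    lam = (1.0 - cfg.p) / cfg.p
    if len(y) < 5:
        if len(y) < 3:
            return y.copy()
        return CubicSpline(x, y, bc_type="natural")(x)
    if lam == 0.0:
        return y.copy()
    return make_smoothing_spline(x, y, lam=lam)(x)


def compute_deltas(x) -> np.ndarray:
    """Forward first differences ``Δx_t = x_{t+1} - x_t`` (A₁−A₀ convention)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values to compute deltas")
    return np.diff(x)


def process_track(cell_id, track_id, sub: pd.DataFrame,
                  smoothing: SmoothingConfig | None = None) -> ProcessedTrack:
    """Convert one raw track into a :class:`ProcessedTrack`.

    Tension is computed from per-timepoint mean intensities (ratio of means,
    per adhesion), then area and tension are spline-smoothed and forward
    differences taken from the smoothed series.
    """
    area = sub["area"].to_numpy(dtype=float)
    mtfp1 = sub["mtfp1_mean"].to_numpy(dtype=float)
    venus = sub["venus_mean"].to_numpy(dtype=float)
    t_raw = ratio_to_tension(venus, mtfp1)
    area_s = smooth_series(area, smoothing)
    t_s = smooth_series(t_raw, smoothing)
    return ProcessedTrack(
        cell_id=cell_id,
        track_id=track_id,
        timepoint=sub["timepoint"].to_numpy(),
        area_raw=area,
        area_smooth=area_s,
        v_tension=t_s,
        v_tension_raw=np.asarray(t_raw, dtype=float),
        cy=compute_cy(mtfp1, venus),
        d_area=compute_deltas(area_s),
        d_tension=compute_deltas(t_s),
    )


def process_table(table: TrackTable,
                  smoothing: SmoothingConfig | None = None) -> list[ProcessedTrack]:
    """Process every track of a table (no filtering)."""
    return [process_track(cell, track, sub, smoothing)
            for (cell, track), sub in table.tracks()]


def filter_tracks(tracks, min_lifetime: int = MIN_LIFETIME,
                  min_area_range: float = MIN_AREA_RANGE) -> list[ProcessedTrack]:
    """Retain tracks with lifetime > ``min_lifetime`` timepoints AND raw-area
    range > ``min_area_range`` μm² (both strict).  Idempotent; an empty
    result is allowed and logged."""
    tracks = list(tracks)
    kept = [t for t in tracks
            if t.lifetime > min_lifetime and t.area_range > min_area_range]
    logger.info("filter_tracks: retained %d of %d tracks", len(kept), len(tracks))
    return kept


def processed_to_frame(tracks) -> pd.DataFrame:
    """Long-format DataFrame of processed tracks (deltas NaN-padded at the
    final timepoint of each track)."""
    rows = []
    for t in tracks:
        n = t.lifetime
        d_area = np.append(t.d_area, np.nan)
        d_tension = np.append(t.d_tension, np.nan)
        rows.append(pd.DataFrame({
            "cell_id": t.cell_id, "track_id": t.track_id,
            "timepoint": t.timepoint,
            "area_raw": t.area_raw, "area_smooth": t.area_smooth,
            "v_tension": t.v_tension, "cy": t.cy,
            "d_area": d_area, "d_tension": d_tension,
        }))
    if not rows:
        return pd.DataFrame(columns=["cell_id", "track_id", "timepoint", "area_raw",
                                     "area_smooth", "v_tension", "cy", "d_area", "d_tension"])
    return pd.concat(rows, ignore_index=True)
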