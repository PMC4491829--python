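"""Moving-window cross-correlation of adhesion area and tension.

Short windows (default 6 timepoints = 3 min at 30-s sampling) slide along
each processed track.  Within each window both series are standardized and
cross-correlated over all integer lags; windows whose peak |r| clears the
significance gate yield one :class:`WindowObservation` carrying the window's
state context — initial area A₀, its one-step change ΔA = A₁−A₀, initial
tension T₀ and ΔT — plus the peak correlation and its lag.

Lag sign convention: **positive lag means tension changes precede area
changes** by that many timepoints.  (The choice is arbitrary but fixed; all
downstream maps use only the sign of the lag.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ProcessedTrack

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LEN = 6   # timepoints; 3 min at 30-s sampling
DEFAULT_R_THRESHOLD = 0.8


@dataclass(frozen=True)
class WindowObservation:
    """One significant moving-window cross-correlation event."""

    cell_id: object
    track_id: object
    window_start: int
    A0: float
    dA: float
    T0: float
    dT: float
    r: float
    lag: int

    @property
    def sign(self) -> int:
        return 1 if self.r > 0 else -1


def standardize_window(values, scale: float | None = None):
    """Mean-centre a window and divide by a scale.

    ``scale=None`` uses the window's own sample s.d. (ddof=1); a supplied
    positive ``scale`` (e.g. a cohort-wide maximal s.d.) is used instead.
    A zero-variance window with no scale is degenerate: returns ``None``
    (the window is skipped, not an error).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("window length must be >= 3")
    centred = v - v.mean()
    if scale is None:
        sd = v.std(ddof=1)
        if sd == 0.0:
            return None
        return centred / sd
    if scale <= 0:
        raise ValueError("scale must be positive")
    return centred / scale


def crosscorrelogram(a, t, max_lag: int) -> np.ndarray:
    """Normalized sample cross-correlation of two equal-length series.

    Returns r(ℓ) for ℓ = −max_lag … +max_lag (length ``2·max_lag+1``) with

        r(ℓ) = Σ_k a_k · t_{k−ℓ}  /  sqrt(Σ a² · Σ t²)

    so r(0) = 1 for identical (already standardized) series and positive ℓ
    means the second series (tension) leads the first (area).
    """
    a = np.asarray(a, dtype=float)
    t = np.asarray(t, dtype=float)
    if a.shape != t.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    n = len(a)
    if n < 3:
        raise ValueError("series must have length >= 3")
    if not (0 <= max_lag <= n - 1):
        raise ValueError("max_lag must satisfy 0 <= max_lag <= n-1")
    denom = np.sqrt(np.dot(a, a) * np.dot(t, t))
    if denom == 0.0:
        raise ValueError("zero-energy series have no correlogram")
    # np.correlate(a, t, "full")[k] = Σ a_{k-(n-1)+j} t_j, i.e. lag ℓ = k-(n-1)
    full = np.correlate(a, t, mode="full") / denom
    centre = n - 1
    return full[centre - max_lag: centre + max_lag + 1]


def lags_axis(max_lag: int) -> np.ndarray:
    return np.arange(-max_lag, max_lag + 1)


def confidence_bound(n: int) -> float:
    """Large-sample 95% significance bound 2/√n for a cross-correlation at
    window length ``n`` (n=6 gives 0.8165, printed gate 0.8)."""
    if n < 3:
        raise ValueError("window length must be >= 3")
    return 2.0 / np.sqrt(n)


def _select_peak(r: np.ndarray, lags: np.ndarray, gate: float):
    """Peak |r| exceeding the gate; ties go to smaller |lag|, then negative
    lag.  Returns (r, lag) or None."""
    absr = np.abs(r)
    best = None
    for i in np.argsort(absr, kind="stable")[::-1]:
        if absr[i] <= gate:
            break
        if best is None:
            best = i
        elif np.isclose(absr[i], absr[best], rtol=0.0, atol=1e-12):
            li, lb = abs(int(lags[i])), abs(int(lags[best]))
            if li < lb or (li == lb and lags[i] < lags[best]):
                best = i
        else:
            break
    if best is None:
        return None
    return float(r[best]), int(lags[best])


def extract_observations(track: ProcessedTrack,
                         window_len: int = DEFAULT_WINDOW_LEN,
                         step: int = 1,
                         r_threshold: float = DEFAULT_R_THRESHOLD,
                         max_lag: int | None = None,
                         area_scale: float | None = None,
                         tension_scale: float | None = None) -> list[WindowObservation]:
    """Slide windows along one processed track and emit significant events.

    The significance gate is ``max(2/√window_len, r_threshold)``.  Context
    values (A₀, ΔA, T₀, ΔT) are read from the smoothed series at the window
    start.  Degenerate (zero-variance) windows and sub-threshold windows
    emit nothing.  ``area_scale``/``tension_scale`` switch standardization
    from the per-window s.d. to a supplied global s.d.
    """
    if window_len < 3:
        raise ValueError("window_len must be >= 3")
    if step < 1:
        raise ValueError("step must be >= 1")
    n = track.lifetime
    if n < window_len:
        logger.debug("track (%s, %s) shorter than window; no observations",
                     track.cell_id, track.track_id)
        return []
    if max_lag is None:
        # correlations at |lag| near n-1 rest on 1-2 products; cap the
        # search at half the window by default
        max_lag = window_len // 2
    gate = max(confidence_bound(window_len), r_threshold)
    lags = lags_axis(max_lag)
    area, tension = track.area_smooth, track.v_tension
    out: list[WindowObservation] = []
    for start in range(0, n - window_len + 1, step):
        end = start + window_len
        a = standardize_window(area[start:end], area_scale)
        t = standardize_window(tension[start:end], tension_scale)
        if a is None or t is None:
            continue
        r = crosscorrelogram(a, t, max_lag)
        peak = _select_peak(r, lags, gate)
        if peak is None:
            continue
        r_best, lag_best = peak
        out.append(WindowObservation(
            cell_id=track.cell_id, track_id=track.track_id, window_start=start,
            A0=float(area[start]), dA=float(area[start + 1] - area[start]),
            T0=float(tension[start]), dT=float(tension[start + 1] - tension[start]),
            r=r_best, lag=lag_best,
        ))
    return out


def extract_all(tracks, **kwargs) -> list[WindowObservation]:
    """Extract observations from a collection of processed tracks."""
    out: list[WindowObservation] = []
    for tr in tracks:
        out.extend(extract_observations(tr, **kwargs))
    return out


def observations_to_frame(observations) -> pd.DataFrame:
    cols = ["cell_id", "track_id", "window_start", "A0", "dA", "T0", "dT", "r", "lag"]
    rows = [{c: getattr(o, c) for c in cols} | {"sign": o.sign} for o in observations]
    return pd.DataFrame(rows, columns=cols + ["sign"])


def observations_from_frame(df: pd.DataFrame) -> list[WindowObservation]:
    return [WindowObservation(cell_id=row.cell_id, track_id=row.track_id,
                              window_start=int(row.window_start), A0=float(row.A0),
                              dA=float(row.dA), T0=float(row.T0), dT=float(row.dT),
                              r=float(row.r), lag=int(row.lag))
            for row in df.itertuples(index=False)]
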