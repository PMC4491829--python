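"""Synthetic track-table generator.

Emulates the statistical structure of per-adhesion FRET time series so the
whole analysis pipeline can run without microscope data: per-track
lifetimes of tens to hundreds of 30-s timepoints, areas in ~0.3–6 μm², an
area–tension coupling whose *sign* depends on the adhesion's area band, a
lead/lag rule switching on the one-step |Δarea|, multiplicative channel
noise, a tension-insensitive control mode, and a planted fraction of
size-stable (metastable) tracks holding exact area values.

The generative model, per track:

* a *home* area band is drawn (small < 1 μm², moderate 1–4.5 μm², large
  4.5–6 μm²) and a per-track step regime (small steps, |ΔA| < 0.2 μm², or
  large steps, |ΔA| ≥ 0.22 μm²) — so lead/lag regimes are temporally
  coherent within a track;
* the latent area path assembles toward a home level, fluctuates
  mean-revertingly inside the band (reflecting boundaries keep tracks
  regime-coherent), and disassembles at the end;
* latent tension increments mirror area increments through the planted
  coupling field: dT_t = cs·s(A_t)·g·dA_{t+shift} + (1−cs)·g·σ_step·η_t,
  where the shift is +1 when tension leads (large |ΔA|) and −1 when area
  leads (small |ΔA|);
* channels are synthesized as mtfp1 = I₀·(1+ε) and
  venus = I₀·exp(−T)·(1+ε′), so the preprocessing inversion
  −ln(venus/mtfp1) recovers T exactly at zero noise.

Noise ε is truncated at ±4 s.d.; intensities stay positive for
``channel_noise_sd < 0.25``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TrackTable

#: (lo, hi, sign) bands of the default plastic coupling field.
DEFAULT_COUPLING_BANDS = ((0.0, 1.0, -1), (1.0, 4.5, +1), (4.5, 6.0, -1))
#: |ΔA| at which temporal precedence switches from area-leads to
#: tension-leads (μm²).
DEFAULT_LAG_THRESHOLD = 0.2
#: Channel-noise bound below which synthesized intensities are positive.
NOISE_SD_BOUND = 0.25


@dataclass
class LagRule:
    """Lead/lag structure: tension leads by ``lag`` timepoints when the
    one-step |ΔA| is at/above ``da_threshold``; area leads by ``lag``
    otherwise.  ``lag=0`` plants synchronous coupling everywhere."""

    da_threshold: float = DEFAULT_LAG_THRESHOLD
    lag: int = 1

    def shift(self, d_area: float) -> int:
        """Signed source shift for the tension increment at this |ΔA|
        (+lag: tension mirrors the area's *future* change, i.e. leads)."""
        if self.lag == 0:
            return 0
        return self.lag if abs(d_area) >= self.da_threshold else -self.lag

    def tension_leads(self, d_area: float) -> bool:
        return abs(d_area) >= self.da_threshold


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort (the defaults are the standard
    study conditions; see :func:`default_plastic_config`)."""

    n_cells: int = 10
    tracks_per_cell: int = 25
    lifetime_range: tuple[int, int] = (40, 120)       # timepoints
    coupling_bands: tuple = DEFAULT_COUPLING_BANDS    # (lo, hi, sign)
    #: moderate-size band dominates, mirroring the observed share of
    #: moderate adhesions among significant windows
    band_weights: tuple = (0.12, 0.78, 0.10)
    coupling_strength: float = 0.9                    # in [0, 1]
    lag_rule: LagRule = field(default_factory=LagRule)
    small_step_sd: float = 0.07                       # μm², |ΔA| regime < threshold
    large_step_range: tuple[float, float] = (0.22, 0.32)
    p_small_steps: float = 0.55
    tension_gain: float = 0.3                         # a.u. per μm²
    tension_baseline: float = 0.3                     # a.u. (control mode)
    #: per-band latent tension baselines (a.u.), aligned with coupling_bands;
    #: the positive-coupling band sits at low tension so the canonical
    #: simulation start (T = 0.1 a.u.) lies in assembly-supporting territory
    band_tension_baselines: tuple = (0.8, 0.1, 1.8)
    tension_baseline_jitter: float = 0.05             # a.u., per-track
    intensity_baseline: float = 1000.0                # a.u.
    channel_noise_sd: float = 0.005                   # relative
    probe_mode: str = "tension"                       # "tension" | "control"
    stable_fraction: float = 0.2
    stable_modes: tuple = (1.0, 3.0, 6.0)             # μm²
    min_window: int = 6                               # shortest analysable track
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ValueError("coupling_strength must be in [0, 1]")
        if not (0.0 <= self.stable_fraction <= 1.0):
            raise ValueError("stable_fraction must be in [0, 1]")
        if self.lifetime_range[0] < self.min_window:
            raise ValueError("minimum lifetime must be >= the analysis window")
        if self.lifetime_range[1] < self.lifetime_range[0]:
            raise ValueError("lifetime_range must be (min, max) with min <= max")
        if not (0.0 <= self.channel_noise_sd < NOISE_SD_BOUND):
            raise ValueError(f"channel_noise_sd must be in [0, {NOISE_SD_BOUND})")
        if self.probe_mode not in ("tension", "control"):
            raise ValueError("probe_mode must be 'tension' or 'control'")
        a_max = max(hi for _, hi, _ in self.coupling_bands)
        for m in self.stable_modes:
            if not (0.0 < m <= a_max):
                raise ValueError(f"stable mode {m} outside the generated area range")

    def coupling_sign(self, area: float, d_area: float = 0.0) -> int:
        """Planted coupling sign s(A, ΔA) — the ground truth the sign map
        should recover.  The default field depends on the area band only."""
        for lo, hi, sign in self.coupling_bands:
            if lo <= area < hi:
                return sign
        return self.coupling_bands[-1][2] if area >= self.coupling_bands[-1][1] \
            else self.coupling_bands[0][2]


def default_plastic_config(**overrides) -> CohortConfig:
    """The standard plastic-coupling study conditions.

    Negative coupling below 1 μm², positive in 1–4.5 μm², negative in
    4.5–6 μm²; tension leads for |ΔA| ≥ 0.2 μm², area leads below; planted
    stable modes at 1, 3 and 6 μm².
    """
    return CohortConfig(**overrides)


def _truncnorm(rng, sd, size=None):
    return np.clip(rng.normal(0.0, 1.0, size=size), -4.0, 4.0) * sd


def _generate_area_path(rng, cfg: CohortConfig, L: int, band, step_small: bool,
                        stable_mode):
    """Latent area path: assembly → (banded plateau, optional exact hold) →
    disassembly.  Returns (areas, hold_slice)."""
    lo, hi, _ = band
    width = hi - lo
    # reflection bounds strictly inside the band keep the planted sign
    # unambiguous at band boundaries; the lower bound also respects the
    # segmentation size floor (~0.3 μm² minimum object size)
    blo, bhi = max(lo + 0.07, 0.3), hi - 0.07
    # large-step excursions need a wall-turn period much longer than the
    # analysis window, which only wide bands can geometrically host; in
    # narrow bands the tension-leads regime lives in the assembly and
    # disassembly ramps instead
    if (bhi - blo) < 8.0 * cfg.large_step_range[0]:
        step_small = True
    if stable_mode is not None:
        centre = float(np.clip(stable_mode, lo + 0.25 * width, hi - 0.25 * width))
    else:
        centre = rng.uniform(lo + 0.25 * width, hi - 0.25 * width)

    n_dis = min(6, L // 5)
    dis_start = (L - 1) - n_dis
    asm_deadline = min(10, L // 3)

    hold = None
    if stable_mode is not None:
        hold_len = int(rng.integers(6, 15))
        hold_start = asm_deadline + 2
        hold_len = min(hold_len, max(dis_start - hold_start - 2, 2))
        hold = (hold_start, hold_start + hold_len)

    A = np.empty(L)
    # tracks are band-coherent by construction: born just inside their home
    # band, assembling to a home level, disassembling back toward the band
    # floor — so every window context carries the band's planted sign
    A[0] = max(lo + 0.05 * width, 0.3)
    direction = 1
    for t in range(L - 1):
        a = A[t]
        floor = max(lo, 0.2) + (0.02 + rng.uniform(0.0, 0.01)) * width  # jittered so
        # clamping never produces exact repeats (those are reserved for the
        # planted stable segments)
        if t >= dis_start:                                    # disassembly
            da = -min(0.35 * (a - lo) + 0.02, 0.55) * (1 + 0.1 * _truncnorm(rng, 1.0))
            A[t + 1] = max(a + da, floor)
        elif hold is not None and hold[0] <= t + 1 < hold[1]:  # exact hold
            A[t + 1] = float(stable_mode)
        elif t < asm_deadline and not (blo <= a <= bhi):      # assembly
            da = np.clip(0.45 * (centre - a), -0.5, 0.5) + _truncnorm(rng, 0.02)
            A[t + 1] = float(np.clip(a + da, floor, hi))
        else:                                                  # banded plateau
            if step_small:
                da = 0.10 * (centre - a) + _truncnorm(rng, cfg.small_step_sd)
                da = np.clip(da, -0.18, 0.18)
            else:
                # random-sign excursions with a mild centering bias: kept
                # aperiodic (strong bias near walls would alternate with a
                # short period and alias the planted lead/lag structure,
                # which is why only wide bands host this regime)
                mag = rng.uniform(*cfg.large_step_range)
                p_up = float(np.clip(0.5 + 0.3 * (centre - a) / (0.5 * width),
                                     0.25, 0.75))
                da = (mag if rng.random() < p_up else -mag) + _truncnorm(rng, 0.03)
            nxt = a + da
            if nxt > bhi:
                nxt = max(2 * bhi - nxt, blo)
                direction = -1
            elif nxt < blo:
                nxt = min(2 * blo - nxt, bhi)
                direction = 1
            A[t + 1] = nxt
    return A, hold


def _generate_tension_path(rng, cfg: CohortConfig, A: np.ndarray,
                           baseline: float) -> np.ndarray:
    """Latent tension path coupled to the area path (see module docstring)."""
    L = len(A)
    dA = np.diff(A)
    T = np.empty(L)
    T[0] = baseline + _truncnorm(rng, cfg.tension_baseline_jitter)
    if cfg.probe_mode == "control":
        T[:] = cfg.tension_baseline
        return T
    cs = cfg.coupling_strength
    g = cfg.tension_gain
    for t in range(L - 1):
        src = t + cfg.lag_rule.shift(dA[t])
        drive = dA[src] if 0 <= src < L - 1 else 0.0
        sign = cfg.coupling_sign(A[t], dA[t])
        sigma = cfg.small_step_sd if abs(dA[t]) < cfg.lag_rule.da_threshold \
            else 0.5 * (cfg.large_step_range[0] + cfg.large_step_range[1])
        noise = 0.0 if cs == 1.0 else (1.0 - cs) * g * sigma * _truncnorm(rng, 1.0)
        T[t + 1] = T[t] + cs * sign * g * drive + noise
    return T


def _synthesize_channels(rng, cfg: CohortConfig, T: np.ndarray):
    """mtfp1 = I₀(1+ε), venus = I₀·exp(−T)(1+ε′); ε truncated N(0, sd)."""
    L = len(T)
    eps1 = _truncnorm(rng, cfg.channel_noise_sd, L)
    eps2 = _truncnorm(rng, cfg.channel_noise_sd, L)
    mtfp1 = cfg.intensity_baseline * (1.0 + eps1)
    venus = cfg.intensity_baseline * np.exp(-T) * (1.0 + eps2)
    return mtfp1, venus


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> TrackTable:
    """Generate one synthetic cohort as a validated :class:`TrackTable`.

    Deterministic given the config (and optional ``seed`` override of
    ``config.seed``).
    """
    cfg = config or default_plastic_config()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    bands = cfg.coupling_bands
    weights = np.asarray(cfg.band_weights, dtype=float)
    weights = weights / weights.sum()
    frames = []
    for ci in range(cfg.n_cells):
        cell_id = f"cell{ci:03d}"
        for tj in range(cfg.tracks_per_cell):
            L = int(rng.integers(cfg.lifetime_range[0], cfg.lifetime_range[1] + 1))
            is_stable = rng.random() < cfg.stable_fraction
            if is_stable:
                mode = float(rng.choice(np.asarray(cfg.stable_modes)))
                band_idx = next((k for k, b in enumerate(bands)
                                 if b[0] < mode <= b[1]), len(bands) - 1)
            else:
                mode = None
                band_idx = int(rng.choice(len(bands), p=weights))
            band = bands[band_idx]
            step_small = rng.random() < cfg.p_small_steps
            A, _ = _generate_area_path(rng, cfg, L, band, step_small, mode)
            T = _generate_tension_path(rng, cfg, A,
                                       cfg.band_tension_baselines[band_idx])
            mtfp1, venus = _synthesize_channels(rng, cfg, T)
            frames.append(pd.DataFrame({
                "cell_id": cell_id, "track_id": tj,
                "timepoint": np.arange(L, dtype=np.int64),
                "area": A, "mtfp1_mean": mtfp1, "venus_mean": venus,
            }))
    df = pd.concat(frames, ignore_index=True)
    return TrackTable(df)
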