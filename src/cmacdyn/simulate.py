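"""Map-driven stochastic simulation of adhesion trajectories.

A synthetic adhesion lives in the four-coordinate (A, ΔA, T, ΔT) space and
"ping-pongs" between the two net-probability maps.  One iteration:

1. look up the net probability p_A at (A, ΔA) in the area-conditioned map;
2. draw a conversion factor Φ1 ~ Normal(μ1, μ1/ν) and set ΔT′ = p_A·Φ1,
   T′ = T + ΔT′;
3. look up p_T at (T′, ΔT′) in the tension-conditioned map;
4. draw Φ2 ~ Normal(μ2, μ2/ν) and set ΔA′ = p_T·Φ2, A′ = A + ΔA′.

ν is the noise factor: large ν means nearly deterministic conversion.
Trajectories start as a small growing adhesion (A=0.2 μm², ΔA=0.1 μm²,
T=0.1 a.u.) and iterate up to 1,000 times.  Four termination archetypes:

I   complete assembly–disassembly cycle (area returns to the seed size
    after having grown past a growth mark);
II  a lookup leaves the sampled range of either map;
III the iteration cap is reached while still dynamic;
IV  metastability: |ΔA′| stays ≤ 0.1 μm² for 4 consecutive iterations,
    after which the trajectory runs τ more iterations and stops, with τ
    chosen by the current area band (τ1: A < 2 μm²; τ2: 2 ≤ A < 3.5;
    τ3: A ≥ 3.5 μm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probmaps import OUT_OF_RANGE, NetProbabilityMap, map_lookup

MAX_ITERATIONS = 1000
#: Default initial state: small growing adhesion at the empirical median
#: initial tension.
DEFAULT_INIT = (0.2, 0.1, 0.1)
#: Area at/below which a previously grown adhesion counts as dissolved (μm²).
DISSOLUTION_THRESHOLD = 0.2
#: Area the adhesion must exceed for a later dissolution to count as a
#: complete assembly–disassembly cycle (μm²).
GROWTH_MARK = 0.4
#: Metastability rule: |ΔA| ≤ STABILITY_DELTA for STABILITY_RUN consecutive
#: iterations.
STABILITY_DELTA = 0.1
STABILITY_RUN = 4
#: τ band edges on area (μm²): τ1 below 2, τ2 in [2, 3.5), τ3 at/above 3.5.
TAU_BAND_EDGES = (2.0, 3.5)

TERMINATION_TYPES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class ModelParams:
    """One point of the simulator model grid.

    mu1 converts net probability into a tension increment (a.u. per unit
    net probability); mu2 into an area increment (μm² per unit net
    probability); nu is the noise factor (σ_k = μ_k/ν); tau1–tau3 are the
    post-stabilization timers (iterations) for the three area bands.
    """

    mu1: float
    mu2: float
    nu: float
    tau1: int
    tau2: int
    tau3: int

    def __post_init__(self) -> None:
        for name in ("mu1", "mu2", "nu", "tau1", "tau2", "tau3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def sigma1(self) -> float:
        return self.mu1 / self.nu

    @property
    def sigma2(self) -> float:
        return self.mu2 / self.nu

    def tau_for_area(self, area: float) -> int:
        if area < TAU_BAND_EDGES[0]:
            return int(self.tau1)
        if area < TAU_BAND_EDGES[1]:
            return int(self.tau2)
        return int(self.tau3)


@dataclass
class SimState:
    A: float
    dA: float
    T: float
    dT: float
    iteration: int = 0


@dataclass
class SyntheticTrajectory:
    """One simulated adhesion lifetime."""

    states: list            # SimState per iteration, including the initial state
    termination: str        # "I" | "II" | "III" | "IV"
    lifetime: int           # iterations performed
    seed: int | None = None

    @property
    def areas(self) -> np.ndarray:
        return np.array([s.A for s in self.states])

    @property
    def tensions(self) -> np.ndarray:
        return np.array([s.T for s in self.states])

    @property
    def d_areas(self) -> np.ndarray:
        return np.array([s.dA for s in self.states[1:]])

    @property
    def d_tensions(self) -> np.ndarray:
        return np.array([s.dT for s in self.states[1:]])


def draw_conversion_factor(mu: float, nu: float, rng: np.random.Generator) -> float:
    """One draw of Φ ~ Normal(μ, μ/ν)."""
    if mu <= 0 or nu <= 0:
        raise ValueError("mu and nu must be strictly positive")
    return float(rng.normal(mu, mu / nu))


def step(state: SimState, area_map: NetProbabilityMap,
         tension_map: NetProbabilityMap, params: ModelParams,
         rng: np.random.Generator, increment_mode: bool = True):
    """One ping-pong iteration; returns the next SimState or OUT_OF_RANGE.

    ``increment_mode=True`` (default) treats p·Φ as the *change* in tension
    (then area); the alternative absolute reading, where p·Φ replaces the
    value outright, is available with ``increment_mode=False``.
    """
    p_a = map_lookup(area_map, state.A, state.dA)
    if p_a is OUT_OF_RANGE:
        return OUT_OF_RANGE
    phi1 = draw_conversion_factor(params.mu1, params.nu, rng)
    if increment_mode:
        dT_new = p_a * phi1
        T_new = state.T + dT_new
    else:
        T_new = p_a * phi1
        dT_new = T_new - state.T
    p_t = map_lookup(tension_map, T_new, dT_new)
    if p_t is OUT_OF_RANGE:
        return OUT_OF_RANGE
    phi2 = draw_conversion_factor(params.mu2, params.nu, rng)
    if increment_mode:
        dA_new = p_t * phi2
        A_new = state.A + dA_new
    else:
        A_new = p_t * phi2
        dA_new = A_new - state.A
    return SimState(A=A_new, dA=dA_new, T=T_new, dT=dT_new,
                    iteration=state.iteration + 1)


def simulate_trajectory(area_map: NetProbabilityMap,
                        tension_map: NetProbabilityMap,
                        params: ModelParams,
                        seed=None,
                        max_iter: int = MAX_ITERATIONS,
                        init: tuple[float, float, float] = DEFAULT_INIT,
                        dissolution_threshold: float = DISSOLUTION_THRESHOLD,
                        growth_mark: float = GROWTH_MARK,
                        increment_mode: bool = True) -> SyntheticTrajectory:
    """Iterate the two-map dynamics from the standard seed state and
    classify the termination archetype (see module docstring)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a0, da0, t0 = init
    state = SimState(A=a0, dA=da0, T=t0, dT=0.0, iteration=0)
    states = [state]
    grew = state.A > growth_mark
    stable_run = 0
    stability_fired = False
    grace_left = 0
    termination = None

    while state.iteration < max_iter:
        nxt = step(state, area_map, tension_map, params, rng,
                   increment_mode=increment_mode)
        if nxt is OUT_OF_RANGE:
            termination = "II"
            break
        state = nxt
        states.append(state)
        if state.A > growth_mark:
            grew = True
        if not stability_fired:
            stable_run = stable_run + 1 if abs(state.dA) <= STABILITY_DELTA else 0
            if stable_run >= STABILITY_RUN:
                stability_fired = True
                grace_left = params.tau_for_area(state.A)
        else:
            grace_left -= 1
        if stability_fired and grace_left <= 0:
            termination = "IV"
            break
        if grew and state.A <= dissolution_threshold:
            termination = "I"
            break
    if termination is None:
        termination = "III"
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return SyntheticTrajectory(states=states, termination=termination,
                               lifetime=state.iteration, seed=seed_out)


def simulate_population(area_map: NetProbabilityMap,
                        tension_map: NetProbabilityMap,
                        params: ModelParams,
                        n: int = 1000,
                        seed: int = 0,
                        max_iter: int = MAX_ITERATIONS,
                        **kwargs):
    """Simulate ``n`` independent trajectories (seeds spawned from the
    master seed by counter) and tabulate termination frequencies.

    Returns ``(trajectories, frequencies)`` where ``frequencies`` maps each
    termination type to its proportion (they sum to 1).
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    trajectories = [
        simulate_trajectory(area_map, tension_map, params,
                            seed=np.random.default_rng(child),
                            max_iter=max_iter, **kwargs)
        for child in children
    ]
    counts = {t: 0 for t in TERMINATION_TYPES}
    for tr in trajectories:
        counts[tr.termination] += 1
    freqs = {t: counts[t] / n for t in TERMINATION_TYPES}
    return trajectories, freqs


def trajectories_to_frame(trajectories) -> pd.DataFrame:
    """Long-format DataFrame: one row per iteration per trajectory."""
    rows = []
    for idx, tr in enumerate(trajectories):
        for s in tr.states:
            rows.append((idx, s.iteration, s.A, s.dA, s.T, s.dT,
                         tr.termination, tr.lifetime))
    return pd.DataFrame(rows, columns=["trajectory", "iteration", "area",
                                       "d_area", "v_tension", "d_tension",
                                       "termination", "lifetime"])
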