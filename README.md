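# cmacdyn

Analysis pipeline for the coupling between **vinculin-mediated tension** and
**cell–matrix adhesion complex (CMAC) area** in live-cell FRET
tension-sensor imaging.

Cell–matrix adhesions transmit force between the cytoskeleton and the
extracellular matrix, and reports on whether tension grows or shrinks
adhesions have long been contradictory. `cmacdyn` implements the analysis
that resolves this contradiction as *context dependence*: the sign of the
tension–area relationship, and which signal moves first, depend on the
adhesion's current size and growth rate. It is written for quantitative
cell biologists working with per-adhesion time series exported by
segmentation/tracking software, and for anyone who wants to reuse the
moving-window cross-correlation → probability-map → stochastic-simulation
methodology on other paired single-object signals.

## What the pipeline computes

Starting from a **track table** (one row per adhesion per 30-s timepoint:
`cell_id, track_id, timepoint, area, mtfp1_mean, venus_mean`):

1. **Tension signal** — per adhesion, T = −ln(Venus/mTFP1), the linearized,
   inverted FRET ratio (high tension ↔ low FRET). Series are smoothed with
   a cubic smoothing spline (p·Σ(y−f)² + (1−p)·∫f″², p = exp(−10⁻⁶)) and
   first-differenced; tracks with lifetime ≤ 5 timepoints or area range
   ≤ 0.5 μm² are dropped.
2. **Moving-window cross-correlation** — 6-timepoint (3-min) windows;
   standardized area and tension are cross-correlated over integer lags;
   windows with peak |r| above max(2/√6, 0.8) yield one observation
   (A₀, ΔA, T₀, ΔT, r, lag). Positive lag means tension precedes area.
3. **Net-probability maps** — Nadaraya–Watson kernel regression of the
   binarized correlation sign on the (A₀, ΔA) and (T₀, ΔT) planes gives
   net = p⁺ − p⁻ ∈ [−1, 1]; the same machinery on the lead/lag label gives
   the temporal-ordering map.
4. **Stochastic simulation** — synthetic adhesions iterate between the two
   maps: ΔT′ = net_A(A, ΔA)·Φ₁ and ΔA′ = net_T(T′, ΔT′)·Φ₂ with
   Φ_k ~ Normal(μ_k, μ_k/ν), up to 1,000 iterations, classified into four
   termination archetypes (complete disassembly / map-range exit /
   iteration cap / metastable).
5. **Model selection** — the 6-parameter grid (μ₁, μ₂, ν, τ₁–τ₃; the
   canonical value lists form 10,000 models) is scored against empirical
   area, tension, Δarea, Δtension and lifetime distributions with Pearson
   χ² on quantile bins.
6. **Metastable subpopulations** — adhesions repeating the same area at
   consecutive timepoints are decomposed by Gaussian-mixture/EM with
   bootstrap AIC selection of the component count; condition effects are
   compared as a kernel-density ratio of area distributions.

A **synthetic cohort generator** plants all of this structure (band-wise
coupling sign, |ΔA|-dependent lead/lag, channel noise, a tension-blind
control mode, exact-hold stable subpopulations) so the entire pipeline runs
and validates itself without any imaging data.

## Worked example

```python
import numpy as np
from cmacdyn import (default_plastic_config, generate_cohort, process_table,
                     filter_tracks, extract_all, sign_probability_map,
                     map_lookup)

cfg = default_plastic_config(seed=1)          # 250 tracks, 10 cells
tracks = filter_tracks(process_table(generate_cohort(cfg)))
obs = extract_all(tracks)                     # significant 3-min windows
amap = sign_probability_map(obs, "area")
for a in (0.5, 1.5, 5.0):
    print(f"net at A={a}, dA=+0.1: {map_lookup(amap, a, 0.1):+.2f}")
```

prints

```
net at A=0.5, dA=+0.1: -0.88
net at A=1.5, dA=+0.1: +1.00
net at A=5.0, dA=+0.1: -0.94
```

i.e. small (< 1 μm²) and large (> 4.5 μm²) adhesions anti-correlate area
and tension while moderately sized ones correlate positively — the planted
plastic relationship, read back from the data by the pipeline (97% of
supported map cells match the generator's ground truth). The
`examples/` directory holds one short script per capability
(generation, cross-correlation, maps, simulation, model selection,
subpopulations); each prints the numbers it computes and what they mean.

The same run from a shell:

```bash
cmacdyn run-all --seed 1 --out runs/demo
```

writes `observations.csv`, the three maps, `simulation_summary.json`,
`selection_report.json` and `subpopulations.json` into the run directory,
bit-identically for a fixed seed.

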