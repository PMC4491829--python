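# Methods

This note documents the models and procedures implemented in `cmacdyn`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic validation does and does not demonstrate.

## Signals and preprocessing

The vinculin tension sensor reports per-molecule load as a FRET ratio:
stretching the elastic linker separates donor (mTFP1) and acceptor (Venus)
and lowers FRET. Per adhesion and timepoint we form the ratio of mean
intensities and linearize/invert it,

    T = −ln(venus_mean / mtfp1_mean),

so T increases with tension. T is in arbitrary log-ratio units; the log
base is a pure rescaling and the natural log is used throughout. The ratio
of means (not the mean of pixel ratios) is deliberate: it matches how
upstream segmentation software summarizes objects. The mean of the two
channels (the "CY" signal) is kept as a sensor-concentration proxy.

Area and tension series are smoothed with a cubic smoothing spline
minimizing `p·Σ(y−f)² + (1−p)·∫f″²`. The default `p = exp(−10⁻⁶)` is
near-interpolating — it suppresses only sub-quantization jitter. The
implementation delegates to `scipy.interpolate.make_smoothing_spline` with
`λ = (1−p)/p`; scipy requires ≥ 5 points, so shorter series fall back to
the natural-cubic interpolant, which is the exact `p → 1` limit and
differs from the default by O(10⁻⁶). Forward differences Δx_t = x_{t+1} −
x_t are taken *after* smoothing. Tracks must have lifetime > 5 timepoints
and raw-area range > 0.5 μm² (both strict) to enter the analysis.

## Moving-window cross-correlation

Windows of 6 timepoints (3 min at 30-s sampling) slide along each track
with step 1. Within a window both series are standardized; the default
divides by the window's own sample s.d. (a cohort-wide scale can be
supplied instead — both conventions appear in the field and the choice
only rescales r jointly). The cross-correlogram is

    r(ℓ) = Σ_k a_k t_{k−ℓ} / √(Σa² · Σt²),  ℓ = −L … +L,

i.e. a biased estimator normalized by total energy, so r(0) = 1 for
identical standardized series. **Sign convention: positive lag means
tension changes precede area changes.** The default lag search range is
`window_len // 2` (±3): correlations at |ℓ| near n−1 rest on one or two
products and generate aliased false peaks.

A window emits an observation when its peak |r| exceeds
max(2/√n, 0.8) — the large-sample 95% bound, which for n = 6 is 0.8165
(rounding to the conventional 0.8 gate). Ties are broken toward smaller
|lag|, then toward negative lag, making extraction deterministic.
Zero-variance windows emit nothing. No multiple-testing correction is
applied beyond the gate. The observation records the window's *initial*
state (A₀, ΔA = A₁−A₀, T₀, ΔT) as its context.

## Net-probability maps

Observations are binarized (r > 0 vs r < 0) and the conditional
probability of a positive correlation is estimated on a regular grid by
Nadaraya–Watson regression with a product Gaussian kernel;
net = 2·p⁺ − 1 ∈ [−1, 1]. The same estimator applied to the
area-leads/tension-leads label (zero-lag observations carry no ordering
information and are excluded) yields the temporal-ordering map.

Defaults: the area grid spans [0, 6] μm² × [−0.6, 0.6] μm² (61 × 25
nodes); the tension grid is data-driven (1st–99th percentiles) because
tension units are arbitrary. Bandwidths default to Silverman's rule per
axis. A support mask marks nodes with kernel-weighted observation mass
≥ 5 equivalent observations; outside it the regression extrapolates and
should not be trusted (the mask is serialized with the map). Lookups use
bilinear interpolation; coordinates outside the grid return an
out-of-range *value* that the simulator consumes as a termination signal.

## Stochastic adhesion simulator

A synthetic adhesion is a state (A, ΔA, T, ΔT). One iteration:

1. p_A = net of the area-conditioned map at (A, ΔA);
2. ΔT′ = p_A·Φ₁ with Φ₁ ~ Normal(μ₁, μ₁/ν); T′ = T + ΔT′;
3. p_T = net of the tension-conditioned map at (T′, ΔT′);
4. ΔA′ = p_T·Φ₂ with Φ₂ ~ Normal(μ₂, μ₂/ν); A′ = A + ΔA′.

ν is a noise factor (σ = μ/ν; large ν → deterministic, and ν = ∞ is an
exact deterministic limit). The start state is a small growing adhesion:
A = 0.2 μm², ΔA = 0.1 μm², T = 0.1 a.u. The net probability × conversion
factor is interpreted as an *increment* of tension (then area); with
μ₁ ~ 10⁻³ an absolute-value reading would collapse the tension scale, but
the absolute variant is available behind `increment_mode=False`.

Termination archetypes:

* **I** — complete cycle: A falls to ≤ 0.2 μm² (the seed size) after
  having exceeded 0.4 μm² (2× seed; the initial state counts). Both
  constants are configurable; the verbal definition in the source
  literature fixes neither.
* **II** — any lookup leaves a map's sampled range.
* **III** — 1,000 iterations reached while still dynamic.
* **IV** — metastability: |ΔA′| ≤ 0.1 μm² for 4 consecutive iterations;
  the trajectory then runs τ more iterations and stops, τ chosen by the
  area band at firing (τ₁: A < 2; τ₂: 2 ≤ A < 3.5; τ₃: A ≥ 3.5 μm²).
  Whether τ is a count of extra live iterations, a resumable grace
  period, or a multiplier is underdetermined; we implement "extra
  iterations, then terminate". With all-zero maps this yields lifetime
  4 + τ₁ exactly, which the tests pin down.

Per-trajectory RNG streams are spawned from the master seed by counter, so
populations are reproducible and order-independent.

## Model selection

The model space is the Cartesian product of six value lists
(μ₁: 4, μ₂: 5, ν: 4, τ₁–τ₃: 5 each → 10,000 models), enumerated in
lexicographic order. Each model simulates a population; pooled area,
tension, Δarea, Δtension and per-trajectory lifetime samples are compared
with the empirical distributions by a Pearson χ² statistic on 20 quantile
bins of the empirical reference (right-closed, open-ended outer bins;
inverted-CDF quantiles make the statistic exactly invariant under common
monotone transforms; expected counts are reference proportions scaled to
the sample size). Objectives are single features or unweighted sums
("area", "lifetime", "area+lifetime", "all"); argmin wins, with ties
broken by the lexicographic parameter order so the selection is invariant
to grid permutation. Per-model simulation seeds are derived from the
parameter values, not the grid position, for the same reason. Synthetic
lifetimes (iterations) and empirical lifetimes (timepoints) are compared
on their own scales; no unit conversion is implied.

## Metastable subpopulations

Empirically, a stability event is an area value repeated at the next
timepoint within tolerance `tol` (default 0: raw segmentation areas are
pixel-quantized, so exact repeats are meaningful; for float-valued areas
set `tol` explicitly). In simulations, the metastable sample is the
terminal area of every type-IV trajectory.

The area sample is decomposed by 1-D Gaussian mixtures fit by EM
(k-means seeding, 10 restarts, variance floor 10⁻⁴ μm⁴), with the
component count chosen by minimal AIC, `AIC = 2(3k−1) − 2·loglik`.
"Repeated application" is 100 bootstrap resamples with re-seeded EM;
**AIC is evaluated on the original sample using parameters fit on the
replicate** — scoring on the replicate itself rewards spike components on
duplicated points and inflates k on null data (measured type-I rate ~45%
on a Gaussian null; with original-sample scoring it drops below 20%).
The report is the distribution of chosen k and the pooled component means
across repeats.

Condition comparisons use Gaussian KDE on a shared grid and the ratio
density_b/density_a with a small denominator floor; floored regions are
flagged and ratio peaks reported descriptively (no significance test).
Note that a near-discrete sample (such as exact-repeat stable areas from
the generator) produces spiky ratio curves; whole-population area samples
are the intended input.

## The synthetic cohort generator

The generator is the package's study-condition bench: it emulates exactly
the statistical structure the analysis is designed to detect, with ground
truth exposed for validation.

Defaults (the standard "plastic" conditions): 10 cells × 25 tracks;
lifetimes uniform on 40–120 timepoints (no lifetime distribution is
published for the original data; uniform is a flagged choice, not an
inference); coupling sign −/+/− on the area bands (0, 1), [1, 4.5),
[4.5, 6) μm²; band weights 0.12/0.78/0.10 so moderate adhesions dominate
as observed; coupling strength 0.9; lead/lag rule: tension leads by one
timepoint for |ΔA| ≥ 0.2 μm², area leads below; stable fraction 0.2 with
exact-hold modes at 1, 3 and 6 μm²; channels mtfp1 = I₀(1+ε),
venus = I₀·exp(−T)(1+ε′) with ε truncated Normal(0, 0.005) — chosen so
the log-ratio inversion recovers T exactly at zero noise and intensities
stay positive for any noise s.d. < 0.25. The control (tension-blind) mode
replaces T with a constant.

Structural choices that matter, and why:

* **Band-coherent tracks.** Each track lives inside one coupling band
  (born just inside it, reflecting at its walls, disassembling toward its
  floor, with a global ~0.3 μm² segmentation size floor). Early designs
  let tracks assemble across bands; windows straddling a sign boundary
  then carry mixed-sign correlations attributed to a single context, and
  observation-level sign fidelity dropped to ~86%. Real adhesions do
  cross regimes — this is precisely a blurring the analysis must live
  with on real data — but the validation generator's job is to make the
  planted field identifiable.
* **Aperiodic large steps, wide band only.** The tension-leads regime
  needs |ΔA| ≥ 0.2 μm² steps. In a band narrower than ~8 step-lengths a
  bouncing path becomes ~period-4, and for such a signal an
  anti-correlated lag-1 copy is *exactly* an in-phase lag-0 copy — the
  planted lead/lag aliases away. Large-step excursions are therefore
  random-sign (mildly centering-biased) and restricted to the wide
  moderate band; narrow bands express the tension-leads regime through
  their curved assembly/disassembly ramps instead.
* **Per-band tension baselines (0.8, 0.1, 1.8 a.u.).** These separate the
  bands in tension space so the tension-conditioned map carries real
  structure, and they place the positive-coupling regime at low tension,
  around the canonical simulation start (T = 0.1), so simulated
  adhesions can assemble out of the seed state.
* The latent coupling is `dT_t = cs·s(A_t)·g·dA_{t+shift} + (1−cs)·g·σ·η`
  with gain g = 0.3 a.u./μm²; at coupling strength 1 and zero noise every
  window correlates at exactly ±1 at the planted lag, which the tests
  exploit as a construction oracle.

What passing the validation shows — and does not. On the default cohort
the pipeline recovers the planted coupling sign on ≥ 95% (measured
97%) of supported map cells and the |ΔA| = 0.2 μm² lead/lag switch with
≥ 95% zone agreement, across seeds. This demonstrates the analysis
machinery is correct and well-calibrated for data with favorable
signal-to-noise and regime-coherent tracks. It does not demonstrate
performance under microscope realities the generator deliberately omits:
photobleaching, intensity-dependent noise, segmentation/tracking errors,
regime-crossing adhesions, spatial correlations between neighboring
adhesions, or sensor dynamic-range saturation.

## Numerical choices

* Window s.d. uses ddof = 1; windows shorter than 3 are rejected.
* Lag ties break toward smaller |lag|, then negative lag.
* Map node counts 61 × 25 on the area plane; density floor 5 equivalent
  observations.
* χ² bins: 20 quantile bins; bins collapse (with a warning) when the
  reference has too few distinct values — routine for lifetime
  distributions.
* GMM variance floor 10⁻⁴ μm⁴; an all-identical sample yields a flagged
  degenerate fit rather than an error.
* CSV artifacts are written at 17-significant-digit precision and read
  back with round-trip float parsing, so write∘read is the identity and
  full pipeline runs are bit-stable for a fixed seed.

## Known limitations

* **Termination composition.** On the default cohort's maps, the
  canonical parameter space yields at most ~20% complete
  assembly–disassembly (type I) cycles; map-range exits (II) and
  metastable endings (IV) dominate. The clean planted coupling saturates
  |net| ≈ 0.9 over most of the supported region, so area dynamics are
  either fast enough to escape the mapped ranges or slow enough to trip
  the 0.1 μm²/4-iteration stability rule. Empirical maps, with their
  noisier sign mixtures and milder |net|, occupy the intermediate regime
  in which complete cycles dominate; reproducing that composition would
  require matching the original data's noise structure, which the
  generator does not attempt. The simulator's mechanics (termination
  arithmetic, closed-form deterministic limits, partition and determinism
  properties) are what the tests certify.
* The grid search is enumeration only; no continuous optimization.
* Simulated adhesions are independent: no spatial or inter-adhesion
  coupling.
* The density-ratio comparison is descriptive; peaks are reported without
  a significance test.
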