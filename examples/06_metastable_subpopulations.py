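"""Detect metastable adhesion subpopulations and compare conditions.

Stable adhesions repeat the same area at consecutive timepoints; their
area distribution is decomposed by Gaussian mixtures with bootstrap
AIC-based choice of the component count.  A kernel-density ratio then
shows where a treatment enriches specific adhesion sizes.
"""

import numpy as np

from cmacdyn import (area_density_ratio, default_plastic_config,
                     generate_cohort, process_table, select_k_by_aic,
                     stable_areas_empirical)
from cmacdyn.subpops import pooled_subpopulation_means

cfg = default_plastic_config(seed=1)
tracks = process_table(generate_cohort(cfg))
stable = stable_areas_empirical(tracks, tol=0.0)
print(f"{stable.size} stable events (same area at consecutive timepoints); "
      f"planted modes at {cfg.stable_modes} um^2")

modal_k, chosen, fits = select_k_by_aic(stable, k_max=5, repeats=50, seed=3)
ks, counts = np.unique(chosen, return_counts=True)
print(f"AIC-chosen component count across 50 bootstrap repeats: "
      f"{dict(zip(ks.tolist(), counts.tolist()))} -> modal k = {modal_k}")
means = pooled_subpopulation_means(fits)
for m in cfg.stable_modes:
    nearest = means[np.argmin(np.abs(means - m))]
    print(f"  planted mode {m:.0f} um^2 -> recovered subpopulation mean "
          f"{nearest:.2f} um^2")

# condition comparison on whole-population area distributions: spike the
# 3 um^2 size class, as a microtubule poison would by blocking targeted
# disassembly of metastable adhesions of that size
rng = np.random.default_rng(9)
control = generate_cohort(cfg).df.area.to_numpy()
treated = np.concatenate([rng.choice(control, size=4000, replace=False),
                          rng.normal(3.0, 0.2, size=1200)])
curve = area_density_ratio(control, treated, bandwidth=0.25)
inner = (curve.grid > 0.5) & (curve.grid < 5.5)
peak = curve.grid[inner][np.argmax(curve.ratio[inner])]
print(f"density-ratio peak of treated vs control at {peak:.2f} um^2 "
      "(the enriched size class)")
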