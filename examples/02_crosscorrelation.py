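"""Moving-window cross-correlation of adhesion area and tension.

Converts channels to the tension signal T = -ln(Venus/mTFP1), smooths,
slides 6-timepoint (3-min) windows along every track and keeps windows
whose peak correlation clears the 95% gate 2/sqrt(6) = 0.82.
"""

import collections

import numpy as np

from cmacdyn import (confidence_bound, default_plastic_config, extract_all,
                     filter_tracks, generate_cohort, process_table)

table = generate_cohort(default_plastic_config(seed=1))
tracks = filter_tracks(process_table(table))
print(f"{len(tracks)} tracks pass the lifetime > 5 and area-range > 0.5 um^2 filters")

gate = confidence_bound(6)
print(f"significance gate at window length 6: |r| > {gate:.4f}")

obs = extract_all(tracks)
signs = collections.Counter(o.sign for o in obs)
lags = collections.Counter(np.sign(o.lag) for o in obs)
print(f"{len(obs)} significant windows: "
      f"{signs[1]} positively, {signs[-1]} negatively correlated")
print(f"temporal order: tension leads in {lags[1]}, area leads in {lags[-1]}, "
      f"synchronous in {lags[0]} windows")
# Each observation keeps its context (A0, dA, T0, dT) so the next stage can
# condition correlation sign and lag order on adhesion state.
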