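"""Decompose simulated 13-landmark body shapes into relative warps.

Simulates fish configurations with a 4:2:1 shape-variance spectrum plus
rotation/translation/scale nuisance, and recovers it.
"""

import numpy as np

from smoltqg.morphometrics import decompose_shapes
from smoltqg.synthetic import LandmarkConfig, simulate_landmarks

shapes = simulate_landmarks(LandmarkConfig(), n=400, seed=11)
dec = decompose_shapes(shapes)
print(f"{len(dec.warp_labels)} relative warps from 13 landmarks (2k-4 = 22)")
print("PVE of the leading axes:", np.round(dec.pve[:5], 1), "... sum =",
      round(dec.pve.sum(), 6))
print("centroid size range:", round(dec.centroid_size.min()),
      "-", round(dec.centroid_size.max()), "(nuisance scale, removed by GPA)")
print("\nThe leading three axes carry ~4:2:1 variance as configured; the")
print("remaining axes are sampling noise. Scores are x1000 by convention.")
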