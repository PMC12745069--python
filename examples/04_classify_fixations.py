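"""Split fixation distances into Close and Distant by k-quantiles clustering.

One-dimensional two-cluster quantile-based clustering (variable-wise
theta, scaled variables, best of 50 initializations) finds a data-driven
threshold on the distance to the ship.  On mixtures like the one below
the boundary lands between the components, in the 5-6 degree region where
the ship leaves the parafovea.
"""

import numpy as np

from dodgegaze.clustering import ClusterParams, kquantiles_fit

rng = np.random.default_rng(0)
close = rng.normal(3.0, 1.0, size=1300).clip(0.2)
distant = rng.normal(8.0, 1.2, size=700).clip(0.2)
distances = np.concatenate([close, distant])

split = kquantiles_fit(distances, ClusterParams(b=50, seed=1))
print(f"n = {len(distances)} fixation distances")
print(f"threshold: {split.threshold_deg:.2f} deg")
print(f"close: {split.n_close}  distant: {split.n_distant}")
print(f"cluster centers: {split.centers_deg[0]:.2f} / "
      f"{split.centers_deg[1]:.2f} deg, thetas "
      f"{split.thetas[0]:.2f} / {split.thetas[1]:.2f}")
print("Fixations below the threshold keep the ship within about the "
      "parafovea (monitoring); those above it sit in the periphery "
      "(exploration and planning).")
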