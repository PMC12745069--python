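"""Generate a binocular 2000-Hz gaze stream for one simulated trial.

Fixation onset points are drawn from a Close/Distant mixture of distances
to the on-screen ship; the printed means show the two components the
downstream clustering is meant to separate.
"""

import numpy as np

from dodgegaze import TrialSpec, generate_layout, run_trial, synth_trial_gaze
from dodgegaze.gaze import GazeParams
from dodgegaze.policies import GreedyGapPolicy

layout = generate_layout(9000, "medium", seed=3)
spec = TrialSpec(layout.id, 1, input_noise_sd=3)
log = run_trial(spec, layout, GreedyGapPolicy(), np.random.default_rng(1))
gaze = synth_trial_gaze(log, GazeParams(), participant_intercept=0.0,
                        rng=np.random.default_rng(2))

truth = gaze.truth
print(f"trial outcome: {log.outcome}, control frames: {log.n_control_frames}")
print(f"samples: {len(gaze.samples)} at 2000 Hz "
      f"({len(gaze.samples) / 2000:.1f} s)")
print(f"generated fixations: {len(truth)}")
for cls, grp in truth.groupby("cls"):
    print(f"  {cls:8s} n={len(grp):3d}  "
          f"mean distance {grp['distance_deg'].mean():.2f} deg")
print("Close fixations monitor the ship (a few degrees away); Distant "
      "fixations scout the approaching obstacle field.")
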