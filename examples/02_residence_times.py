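"""First-passage residence times of shell water.

Generates a toy trajectory in which waters enter and leave per-residue
hydration shells as a telegraph process with a known 50 ps mean dwell,
then recovers that dwell from the first-passage residence analysis
(first continuous stay only; re-entries excluded).
"""

import numpy as np

from lovhydra import synthdata as sd, watershell as ws

spec = sd.ShellDynamicsSpec(n_residues=50, n_frames=5000, dt=1.0,
                            mean_dwell=50.0, occupancy=2.0, seed=7)
traj = sd.gen_toy_trajectory(spec)
table = ws.residence_times(traj, cutoff=4.5)

mean = np.nanmean(table["mean_residence_ps"])
print(f"generated mean dwell : {spec.mean_dwell:.1f} ps")
print(f"recovered mean       : {mean:.1f} ps "
      f"over {int(table['n_visits'].sum())} first-passage visits")
print()
print("Each residue contributes the mean duration of its waters' first")
print("continuous shell visits; in the activated protein, bound water")
print("(planar geometry) shows the longest such residence times.")
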