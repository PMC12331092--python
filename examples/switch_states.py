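"""Classify engaged/disengaged switch states from a two-state trajectory.

Generates a synthetic ensemble in which the switch arginine (residue 394)
hops between an engaged geometry (Cζ 3.9 Å from the gate aspartate's Cγ,
an intact polar core) and a disengaged geometry (10 Å away, captured by the
peptide glutamate), then recovers the hidden states from the distance
series alone.
"""

import numpy as np

from argswitch import classify_states, polar_core_series
from argswitch.synth import SwitchSimParams, gen_switch_trajectory

params = SwitchSimParams(
    n_frames=5000, p_disengage=0.05, p_engage=0.05, seed=11
)
traj, truth_engaged = gen_switch_trajectory(params)

series = polar_core_series(traj)
states = classify_states(series, threshold=6.0)
accuracy = np.mean(states.engaged == truth_engaged)

print(f"frames: {traj.n_frames}, atoms: {traj.n_atoms}")
print(f"mean switch-gate distance: {series.values.mean():.2f} A")
print(f"engaged fraction (called): {states.engaged_fraction:.3f}")
print(f"engaged fraction (truth):  {truth_engaged.mean():.3f}")
print(f"state recovery accuracy:   {100 * accuracy:.2f} %")
print()
print("A 6 A threshold on the Czeta-Cgamma distance separates the intact")
print("polar core (inactive-like) from the disrupted, peptide-captured")
print("intermediate; with 0.2 A positional noise the two geometries are")
print(">6 sigma apart, so every frame is classified correctly.")
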