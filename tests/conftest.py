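import numpy as np
import pytest

from argswitch.synth import SwitchSimParams, gen_switch_trajectory
from argswitch.traj import AtomRecord, Topology, Trajectory


@pytest.fixture(scope="session")
def switch_sim():
    """A mixed engaged/disengaged switch trajectory with its ground truth."""
    params = SwitchSimParams(n_frames=800, p_disengage=0.05, p_engage=0.05, seed=7)
    traj, engaged = gen_switch_trajectory(params)
    return params, traj, engaged


def make_topology(spec):
    """Build a Topology from (atom_name, residue_name, residue_id, chain) tuples."""
    return Topology(
        atoms=tuple(
            AtomRecord(
                atom_index=i, atom_name=name, residue_name=resname,
                residue_id=resid, chain_id=chain,
            )
            for i, (name, resname, resid, chain) in enumerate(spec)
        )
    )


def make_traj(coords, topology=None, **kw):
    coords = np.asarray(coords, dtype=float)
    if topology is None:
        topology = make_topology(
            [("CA", "GLY", 100 + i, "A") for i in range(coords.shape[1])]
        )
    return Trajectory(topology=topology, coords=coords, **kw)
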