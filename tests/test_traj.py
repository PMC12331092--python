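"""Topology/trajectory I/O, the selection grammar, and rigid-body superposition."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from argswitch.errors import (
    DegenerateSelectionError,
    EmptyInputError,
    PDBParseError,
    SelectionSyntaxError,
    ShapeError,
)
from argswitch.synth import SwitchSimParams, gen_switch_trajectory
from argswitch.traj import (
    ReplicateSet,
    Trajectory,
    load_topology,
    load_trajectory,
    select_atoms,
    superpose,
    write_trajectory,
)

from conftest import make_topology, make_traj

TOY_PDB = """\
ATOM      1  CZ  ARG A 394      11.104  13.207   9.500  1.00  0.00           C
ATOM      2  NH1 ARG A 394      12.054  13.757  10.050  1.00  0.00           N
ATOM      3  NH2 ARG A 394      12.054  12.657   8.950  1.00  0.00           N
END
"""


class TestLoadTopology:
    def test_toy_pdb_echoes_records(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        top = load_topology(str(path))
        assert len(top) == 3
        assert [a.atom_name for a in top.atoms] == ["CZ", "NH1", "NH2"]
        assert all(a.residue_id == 394 and a.residue_name == "ARG" for a in top.atoms)
        assert [a.atom_index for a in top.atoms] == [0, 1, 2]

    def test_duplicate_serials_accepted_index_positional(self, tmp_path):
        # same serial (1) on both lines, distinct coordinates
        dup = TOY_PDB.replace("ATOM      2", "ATOM      1")
        path = tmp_path / "dup.pdb"
        path.write_text(dup)
        top = load_topology(str(path))
        assert [a.atom_index for a in top.atoms] == [0, 1, 2]

    def test_malformed_coordinate_names_line(self, tmp_path):
        bad = TOY_PDB.replace("13.207", "13.2.7")
        path = tmp_path / "bad.pdb"
        path.write_text(bad)
        with pytest.raises(PDBParseError, match=":1:"):
            load_topology(str(path))

    def test_insertion_code_rejected(self, tmp_path):
        bad = TOY_PDB.replace("A 394    ", "A 394A   ")
        path = tmp_path / "ins.pdb"
        path.write_text(bad)
        with pytest.raises(PDBParseError, match="insertion"):
            load_topology(str(path))

    def test_zero_atoms_is_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(EmptyInputError):
            load_topology(str(path))


class TestTrajectoryIO:
    def test_multimodel_frame_count(self, tmp_path):
        traj, _ = gen_switch_trajectory(SwitchSimParams(n_frames=2, seed=0))
        path = tmp_path / "two.pdb"
        write_trajectory(traj, str(path))
        top = load_topology(str(path))
        assert load_trajectory(str(path), top).n_frames == 2

    def test_single_frame(self, tmp_path):
        traj, _ = gen_switch_trajectory(SwitchSimParams(n_frames=1, seed=0))
        path = tmp_path / "one.pdb"
        write_trajectory(traj, str(path))
        assert load_trajectory(str(path), traj.topology).n_frames == 1

    def test_round_trip_within_pdb_precision(self, tmp_path):
        traj, _ = gen_switch_trajectory(SwitchSimParams(n_frames=100, seed=3))
        path = tmp_path / "rt.pdb"
        write_trajectory(traj, str(path))
        top = load_topology(str(path))
        assert top == traj.topology
        back = load_trajectory(str(path), top)
        assert np.abs(back.coords - traj.coords).max() <= 1e-3

    def test_atom_count_mismatch(self, tmp_path):
        traj, _ = gen_switch_trajectory(SwitchSimParams(n_frames=2, seed=0))
        path = tmp_path / "t.pdb"
        write_trajectory(traj, str(path))
        small = make_topology([("CA", "GLY", 1, "A")])
        with pytest.raises(ShapeError, match="1"):
            load_trajectory(str(path), small)

    def test_dcd_round_trip(self, tmp_path):
        import MDAnalysis as mda

        traj, _ = gen_switch_trajectory(SwitchSimParams(n_frames=5, seed=2))
        path = tmp_path / "t.dcd"
        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f]
                w.write(u.atoms)
        back = load_trajectory(str(path), traj.topology, format="dcd")
        assert back.n_frames == 5
        assert np.abs(back.coords - traj.coords).max() <= 1e-3


class TestSelectAtoms:
    def test_switch_cz_is_unique(self, switch_sim):
        _, traj, _ = switch_sim
        assert len(select_atoms(traj.topology, "resid 394 and name CZ")) == 1

    def test_phosphorus_of_both_phosphoresidues(self, switch_sim):
        _, traj, _ = switch_sim
        sel = select_atoms(traj.topology, "resid 350 352 and name P")
        assert len(sel) == 2

    def test_unknown_name_empty_with_warning(self, switch_sim):
        _, traj, _ = switch_sim
        with pytest.warns(UserWarning, match="matched no atoms"):
            sel = select_atoms(traj.topology, "name ZZ9")
        assert len(sel) == 0

    @pytest.mark.parametrize(
        "expr", ["", "and", "resid", "frobnicate 3", "resid 3.5", "resid 3 name"]
    )
    def test_grammar_violations(self, switch_sim, expr):
        _, traj, _ = switch_sim
        with pytest.raises(SelectionSyntaxError):
            select_atoms(traj.topology, expr)

    def test_clause_order_independent_and_idempotent(self, switch_sim):
        _, traj, _ = switch_sim
        clauses = ["resid 394 350", "name CZ P CA", "chain A P"]
        results = {
            select_atoms(traj.topology, " and ".join(p)).indices
            for p in itertools.permutations(clauses)
        }
        assert len(results) == 1
        # idempotence: re-resolving the same expression is identical
        expr = " and ".join(clauses)
        assert (
            select_atoms(traj.topology, expr).indices
            == select_atoms(traj.topology, expr).indices
        )


class TestSelectionTable:
    def test_table_mirrors_resolved_atoms(self, switch_sim):
        from argswitch.traj import selection_table

        _, traj, _ = switch_sim
        sel = select_atoms(traj.topology, "resid 350 352 and name P")
        df = selection_table(traj.topology, sel)
        assert list(df.residue_id) == [350, 352]
        assert set(df.atom_name) == {"P"}
        assert (df.expression == "resid 350 352 and name P").all()


class TestSuperpose:
    def _rigid_copies(self, n_frames, n_atoms, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(n_atoms, 3)) * 5.0
        frames = [base]
        for _ in range(n_frames - 1):
            rot = Rotation.random(rng=rng)
            frames.append(rot.apply(base) + rng.normal(size=3) * 10.0)
        return make_traj(np.array(frames))

    def test_rigid_copies_collapse_onto_reference(self):
        traj = self._rigid_copies(6, 12, seed=5)
        sel = select_atoms(traj.topology, "name CA")
        out = superpose(traj, 0, sel)
        rmsd = np.sqrt(((out.coords - out.coords[0]) ** 2).sum(-1).mean(-1))
        assert rmsd.max() <= 1e-6

    def test_identity_on_aligned_frames(self):
        traj = self._rigid_copies(1, 8, seed=1)
        coords = np.repeat(traj.coords, 3, axis=0)
        traj3 = make_traj(coords, topology=traj.topology)
        sel = select_atoms(traj3.topology, "name CA")
        out = superpose(traj3, 0, sel)
        assert np.abs(out.coords - traj3.coords).max() <= 1e-9

    def test_pure_translation_maps_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 3))
        traj = make_traj(np.array([base, base + np.array([5.0, 0, 0])]))
        sel = select_atoms(traj.topology, "name CA")
        out = superpose(traj, 0, sel)
        assert np.abs(out.coords[1] - out.coords[0]).max() <= 1e-9

    def test_intra_frame_distances_preserved(self):
        traj = self._rigid_copies(4, 10, seed=9)
        sel = select_atoms(traj.topology, "name CA")
        out = superpose(traj, 0, sel)
        for f in range(traj.n_frames):
            before = np.linalg.norm(
                traj.coords[f][:, None] - traj.coords[f][None], axis=-1
            )
            after = np.linalg.norm(
                out.coords[f][:, None] - out.coords[f][None], axis=-1
            )
            assert np.abs(before - after).max() <= 1e-6

    def test_collinear_selection_rejected(self):
        line = np.stack([np.linspace(0, 9, 10)] * 1).T.repeat(3, 1)
        line[:, 1:] = 0.0
        traj = make_traj(np.array([line, line]))
        sel = select_atoms(traj.topology, "name CA")
        with pytest.raises(DegenerateSelectionError):
            superpose(traj, 0, sel)


class TestReplicateSet:
    def test_last_frames_window(self, switch_sim):
        _, traj, _ = switch_sim
        rs = ReplicateSet(trajectories=[traj], analysis_window="last 100 frames")
        (w,) = rs.windowed()
        assert w.n_frames == 100
        assert np.array_equal(w.coords, traj.coords[-100:])

    def test_last_ns_window_uses_frame_times(self, switch_sim):
        _, traj, _ = switch_sim
        timed = Trajectory(
            topology=traj.topology,
            coords=traj.coords,
            frame_times=np.linspace(0.0, 300.0, traj.n_frames),
            condition=traj.condition,
        )
        rs = ReplicateSet(trajectories=[timed], analysis_window="last 50 ns")
        (w,) = rs.windowed()
        # 50/300 of uniformly spaced frames
        assert w.n_frames == pytest.approx(traj.n_frames / 6, abs=2)

    def test_ns_window_without_times_is_error(self, switch_sim):
        _, traj, _ = switch_sim
        rs = ReplicateSet(trajectories=[traj], analysis_window="last 50 ns")
        with pytest.raises(ValueError, match="frame_times"):
            rs.windowed()

    def test_mixed_conditions_rejected(self, switch_sim):
        _, traj, _ = switch_sim
        other = Trajectory(
            topology=traj.topology, coords=traj.coords, condition="other"
        )
        with pytest.raises(ShapeError, match="conditions"):
            ReplicateSet(trajectories=[traj, other])
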