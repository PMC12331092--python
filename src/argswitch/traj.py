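"""Structures, trajectories, atom selections and rigid-body superposition.

Coordinates are Å throughout.  Frames are bound to a :class:`Topology` whose
atom order matches the coordinate order; residue numbering is author
numbering taken verbatim from the source file (rat arrestin-2 conventions:
the switch arginine is residue 394, the gate-loop aspartate 299).

Multi-model PDB is the canonical trajectory format; DCD is supported behind
the same interface.  PDB records are read and written with biotite; a cheap
validation pass supplies line-numbered errors for malformed records.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateSelectionError,
    EmptyInputError,
    PDBParseError,
    SelectionSyntaxError,
    ShapeError,
)

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "AtomSelection",
    "ReplicateSet",
    "load_topology",
    "load_trajectory",
    "write_trajectory",
    "select_atoms",
    "superpose",
]

# Residue names under which a phosphorylated Ser/Thr may appear.  A plain
# SER/THR record carrying a "P" atom is treated as phosphorylated too.
PHOSPHO_RESNAMES = frozenset({"SEP", "TPO"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology, PDB naming conventions."""

    atom_index: int
    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str


@dataclass(frozen=True)
class Topology:
    """Ordered atom list; order matches the coordinate axis of bound trajectories."""

    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise EmptyInputError("topology must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Topology) and self.atoms == other.atoms

    def __hash__(self) -> int:
        return hash(self.atoms)


@dataclass
class Trajectory:
    """Frames of coordinates (frames × atoms × 3, Å) bound to a topology.

    ``replicate_id`` and ``condition`` tag the trajectory for pooling across
    replicate sets (e.g. condition ``"IM+C7pp2"`` vs ``"apo"``).
    """

    topology: Topology
    coords: np.ndarray
    frame_times: np.ndarray | None = None  # ns, informational only
    replicate_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ShapeError(
                f"coords must be frames × atoms × 3, got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise EmptyInputError("trajectory must contain at least one frame")
        if self.coords.shape[1] != len(self.topology):
            raise ShapeError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology size {len(self.topology)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ShapeError("coordinates must be finite")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ShapeError("frame_times length must equal the frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class AtomSelection:
    """A resolved selection: the expression plus sorted, unique 0-based indices."""

    expression: str
    indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def index_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


_WINDOW_RE = re.compile(r"^last\s+(\d+(?:\.\d+)?)\s*(ns|frames?)$")


@dataclass
class ReplicateSet:
    """Trajectories of one condition plus the analysis window applied to each.

    ``analysis_window`` is ``"all"``, ``"last <T> ns"`` (requires frame
    times) or ``"last <N> frames"``.  Members must share an identical
    topology so per-frame observables pool cleanly.
    """

    trajectories: list[Trajectory]
    analysis_window: str = "all"

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise EmptyInputError("replicate set must contain at least one trajectory")
        top = self.trajectories[0].topology
        for t in self.trajectories[1:]:
            if t.topology != top:
                raise ShapeError("all replicate-set members must share one topology")
        conditions = {t.condition for t in self.trajectories}
        if len(conditions) > 1:
            raise ShapeError(f"replicate set mixes conditions: {sorted(conditions)}")
        if self.analysis_window != "all" and _WINDOW_RE.match(self.analysis_window) is None:
            raise ValueError(
                f"analysis_window must be 'all', 'last T ns' or 'last N frames', "
                f"got {self.analysis_window!r}"
            )

    def window_frames(self, traj: Trajectory) -> np.ndarray:
        """Frame indices of ``traj`` inside the analysis window."""
        n = traj.n_frames
        if self.analysis_window == "all":
            return np.arange(n)
        m = _WINDOW_RE.match(self.analysis_window)
        assert m is not None
        amount, unit = float(m.group(1)), m.group(2)
        if unit == "ns":
            if traj.frame_times is None:
                raise ValueError(
                    "a 'last T ns' window requires trajectories with frame_times"
                )
            cutoff = traj.frame_times[-1] - amount
            return np.nonzero(traj.frame_times > cutoff)[0]
        k = min(int(amount), n)
        return np.arange(n - k, n)

    def windowed(self) -> list[Trajectory]:
        """Copies of the member trajectories restricted to the window."""
        out = []
        for t in self.trajectories:
            idx = self.window_frames(t)
            if idx.size == 0:
                raise EmptyInputError(
                    f"analysis window {self.analysis_window!r} selects no frames "
                    f"of replicate {t.replicate_id!r}"
                )
            out.append(
                replace(
                    t,
                    coords=t.coords[idx],
                    frame_times=None if t.frame_times is None else t.frame_times[idx],
                )
            )
        return out


# ---------------------------------------------------------------------------
# PDB / DCD input and output
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: str) -> None:
    """Line-numbered sanity check of ATOM/HETATM records before handing to biotite."""
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            n_records += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(
                    f"{path}:{lineno}: ATOM/HETATM record shorter than the "
                    "coordinate fields (needs 54 columns)"
                )
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{path}:{lineno}: unparseable {what} coordinate "
                        f"{line[lo:hi]!r}"
                    ) from None
            if line[26] != " ":
                raise PDBParseError(
                    f"{path}:{lineno}: insertion code {line[26]!r} not supported"
                )
    if n_records == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")


def _read_pdb_stack(path: str):
    import biotite.structure.io.pdb as pdb

    _validate_pdb_lines(path)
    try:
        pdb_file = pdb.PDBFile.read(path)
        stack = pdb_file.get_structure()  # AtomArrayStack, coordinates in Å
    except Exception as exc:  # biotite errors carry no line info
        raise PDBParseError(f"{path}: {exc}") from exc
    if stack.array_length() == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records found")
    return stack


def _topology_from_stack(stack) -> Topology:
    atoms = tuple(
        AtomRecord(
            atom_index=i,
            atom_name=str(stack.atom_name[i]),
            residue_name=str(stack.res_name[i]),
            residue_id=int(stack.res_id[i]),
            chain_id=(str(stack.chain_id[i]) or " ")[0],
        )
        for i in range(stack.array_length())
    )
    return Topology(atoms=atoms)


def load_topology(path: str, format: str = "pdb") -> Topology:
    """Read a topology from the first model of a PDB file.

    Atom indices are positional (0..n-1) regardless of the file's serial
    numbers; duplicate serials are therefore accepted.  Insertion codes are
    rejected.
    """
    if format != "pdb":
        raise ValueError(f"unsupported topology format {format!r}")
    return _topology_from_stack(_read_pdb_stack(path))


def load_trajectory(
    path: str,
    topology: Topology,
    format: str = "pdb-multimodel",
    replicate_id: str = "",
    condition: str = "",
) -> Trajectory:
    """Read frames from a multi-model PDB or a DCD file against ``topology``."""
    if format == "pdb-multimodel":
        stack = _read_pdb_stack(path)
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:  # single model
            coords = coords[None]
    elif format == "dcd":
        from MDAnalysis.coordinates.DCD import DCDReader

        with DCDReader(path) as reader:
            coords = np.asarray([ts.positions.copy() for ts in reader], dtype=float)
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")
    if coords.shape[1] != len(topology):
        raise ShapeError(
            f"{path}: expected {len(topology)} atoms per frame, found {coords.shape[1]}"
        )
    return Trajectory(
        topology=topology,
        coords=coords,
        replicate_id=replicate_id,
        condition=condition,
    )


_ELEMENT_GUESS = {"C": "C", "N": "N", "O": "O", "P": "P", "S": "S", "H": "H"}


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    return _ELEMENT_GUESS.get(stripped[:1].upper(), stripped[:1].upper() or "C")


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write all frames as a multi-model PDB (fixed-width, 3 decimals)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord[:] = traj.coords
    stack.atom_name = np.array([a.atom_name for a in traj.topology.atoms], dtype="U6")
    stack.res_name = np.array([a.residue_name for a in traj.topology.atoms], dtype="U5")
    stack.res_id = np.array([a.residue_id for a in traj.topology.atoms], dtype=int)
    stack.chain_id = np.array([a.chain_id for a in traj.topology.atoms], dtype="U4")
    stack.element = np.array(
        [_guess_element(a.atom_name) for a in traj.topology.atoms], dtype="U2"
    )
    stack.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------
#
#   expression := clause ("and" clause)*
#   clause     := ("resid" int+) | ("resname" name+) | ("name" name+)
#                 | ("chain" char+)
#
# Clauses are conjunctive; values within a clause are alternatives.

_CLAUSE_KEYWORDS = ("resid", "resname", "name", "chain")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens = []
    for m in re.finditer(r"\S+", expression):
        tokens.append((m.group(), m.start()))
    return tokens


def select_atoms(topology: Topology, expression: str) -> AtomSelection:
    """Resolve a selection expression against a topology.

    Deterministic: returns sorted unique indices.  An empty result is legal
    but emits a warning (a typo'd atom name is the usual cause).
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionSyntaxError("empty selection expression")

    clauses: list[tuple[str, list[str]]] = []
    i = 0
    while i < len(tokens):
        word, pos = tokens[i]
        if word == "and":
            if not clauses or i + 1 >= len(tokens):
                raise SelectionSyntaxError(
                    f"position {pos}: 'and' must join two clauses"
                )
            i += 1
            continue
        if word not in _CLAUSE_KEYWORDS:
            raise SelectionSyntaxError(
                f"position {pos}: expected one of {_CLAUSE_KEYWORDS}, got {word!r}"
            )
        values: list[str] = []
        i += 1
        while i < len(tokens) and tokens[i][0] != "and":
            v, vpos = tokens[i]
            if v in _CLAUSE_KEYWORDS:
                raise SelectionSyntaxError(
                    f"position {vpos}: keyword {v!r} must be joined with 'and'"
                )
            if word == "resid":
                try:
                    int(v)
                except ValueError:
                    raise SelectionSyntaxError(
                        f"position {vpos}: resid values must be integers, got {v!r}"
                    ) from None
            values.append(v)
            i += 1
        if not values:
            raise SelectionSyntaxError(
                f"position {pos}: clause {word!r} needs at least one value"
            )
        clauses.append((word, values))

    mask = np.ones(len(topology), dtype=bool)
    for keyword, values in clauses:
        if keyword == "resid":
            wanted_ids = {int(v) for v in values}
            clause_mask = np.array(
                [a.residue_id in wanted_ids for a in topology.atoms]
            )
        elif keyword == "resname":
            wanted = set(values)
            clause_mask = np.array([a.residue_name in wanted for a in topology.atoms])
        elif keyword == "name":
            wanted = set(values)
            clause_mask = np.array([a.atom_name in wanted for a in topology.atoms])
        else:  # chain
            wanted = set(values)
            clause_mask = np.array([a.chain_id in wanted for a in topology.atoms])
        mask &= clause_mask

    indices = tuple(int(i) for i in np.nonzero(mask)[0])
    if not indices:
        warnings.warn(
            f"selection {expression!r} matched no atoms", stacklevel=2
        )
    return AtomSelection(expression=expression, indices=indices)


def selection_table(topology: Topology, selection: AtomSelection):
    """Resolved selection as a tidy table (for TSV export)."""
    import pandas as pd

    atoms = [topology.atoms[i] for i in selection.indices]
    return pd.DataFrame(
        {
            "atom_index": [a.atom_index for a in atoms],
            "atom_name": [a.atom_name for a in atoms],
            "residue_name": [a.residue_name for a in atoms],
            "residue_id": [a.residue_id for a in atoms],
            "chain_id": [a.chain_id for a in atoms],
            "expression": selection.expression,
        }
    )


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------

def _check_not_degenerate(ref_sel_coords: np.ndarray) -> None:
    if ref_sel_coords.shape[0] < 3:
        raise DegenerateSelectionError(
            f"superposition needs ≥3 atoms, got {ref_sel_coords.shape[0]}"
        )
    centered = ref_sel_coords - ref_sel_coords.mean(axis=0)
    # Collinear points give a rank-1 covariance; the rotation is then
    # underdetermined about the line.
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateSelectionError(
            "superposition selection is collinear (rank < 2)"
        )


def superpose(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: AtomSelection | None = None,
    reference_coords: np.ndarray | None = None,
) -> Trajectory:
    """Least-squares rigid-body fit of every frame onto a reference.

    The optimal rotation is the Kabsch solution computed on the selection
    atoms; the transform is applied to all atoms, so intra-frame geometry is
    preserved exactly.  ``reference_coords`` (selection-sized, Å) overrides
    the ``reference_frame`` of the trajectory itself — used for fitting onto
    a time-averaged structure.
    """
    if selection is None or len(selection) == 0:
        raise DegenerateSelectionError("superposition requires a non-empty selection")
    sel = selection.index_array
    if reference_coords is None:
        ref = traj.coords[reference_frame, sel]
    else:
        ref = np.asarray(reference_coords, dtype=float)
        if ref.shape != (len(sel), 3):
            raise ShapeError(
                f"reference_coords must be {(len(sel), 3)}, got {ref.shape}"
            )
    _check_not_degenerate(ref)
    ref_center = ref.mean(axis=0)
    ref_centered = ref - ref_center

    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        mobile = traj.coords[f, sel]
        mob_center = mobile.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, mobile - mob_center)
        out[f] = rot.apply(traj.coords[f] - mob_center) + ref_center
    return replace(traj, coords=out)
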