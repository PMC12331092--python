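"""Geometric observables of the arrestin switch analysis.

The observables mirror how the activation intermediate is characterised:

* salt-bridge / contact *distance series* between phosphopeptide residues
  and arrestin arginines (specific atom pairs, or the minimum over charged
  side-chain groups),
* *contact stability* — the fraction of frames a contact is formed,
* the *polar-core integrity* metric, the distance between the switch
  arginine's guanidinium carbon (Cζ, residue 394) and the gate-loop
  aspartate's carboxylate carbon (Cγ, residue 299): small values mean an
  intact (inactive-like) polar core, large values a disrupted core,
* per-residue Cα RMSF of the bound phosphopeptide, and
* the engaged/disengaged two-state classification of the switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SelectionError
from .traj import AtomSelection, ReplicateSet, Trajectory, select_atoms, superpose

__all__ = [
    "ContactDefinition",
    "PolarCoreSpec",
    "DistanceSeries",
    "RMSFProfile",
    "SwitchStateSeries",
    "distance_series",
    "contact_fraction",
    "polar_core_series",
    "rmsf",
    "classify_states",
    "series_to_frame",
]

#: Default salt-bridge contact cutoff (Å): minimum acidic-oxygen to basic-
#: nitrogen distance at or below this counts the contact as formed.
SALT_BRIDGE_CUTOFF = 4.0

#: Default engaged/disengaged threshold (Å) on the Cζ–Cγ polar-core metric,
#: midway between the intact (~6 Å average) and disrupted (~10 Å average)
#: regimes.
SWITCH_STATE_THRESHOLD = 6.0


@dataclass(frozen=True)
class ContactDefinition:
    """A named residue–residue contact.

    ``mode="specific"`` measures one atom on each side (both selections must
    resolve to exactly one atom); ``mode="min-group"`` takes the per-frame
    minimum over all cross pairs — the standard salt-bridge criterion when
    the selections are the acidic oxygens and basic nitrogens.
    """

    name: str
    sel_a: AtomSelection
    sel_b: AtomSelection
    mode: str = "min-group"
    cutoff: float = SALT_BRIDGE_CUTOFF

    def __post_init__(self) -> None:
        if self.mode not in ("specific", "min-group"):
            raise ValueError(f"unknown contact mode {self.mode!r}")
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")
        if len(self.sel_a) == 0 or len(self.sel_b) == 0:
            raise SelectionError(
                f"contact {self.name!r}: empty selection "
                f"(a: {len(self.sel_a)} atoms, b: {len(self.sel_b)} atoms)"
            )
        if self.mode == "specific" and (len(self.sel_a) != 1 or len(self.sel_b) != 1):
            raise SelectionError(
                f"contact {self.name!r}: 'specific' mode needs exactly one atom "
                f"per side, got {len(self.sel_a)} and {len(self.sel_b)}"
            )


@dataclass(frozen=True)
class PolarCoreSpec:
    """Atom choices for the polar-core integrity metric.

    Defaults follow the charged-group carbon convention: Cζ of the switch
    arginine (residue 394) against Cγ of the gate-loop aspartate (residue
    299).  Anchor residues (27, 292, 170) are recorded for provenance but do
    not enter the metric.
    """

    switch_residue: int = 394
    switch_atom: str = "CZ"
    gate_residue: int = 299
    gate_atom: str = "CG"
    anchor_residues: tuple[int, ...] = (27, 292, 170)


@dataclass
class DistanceSeries:
    """Per-frame distance (Å) for one contact in one replicate."""

    name: str
    values: np.ndarray
    replicate_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise EmptyInputError(f"distance series {self.name!r} has no frames")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError(f"distance series {self.name!r} must be finite and ≥ 0")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation (Å)."""

    residue_ids: np.ndarray
    rmsf: np.ndarray

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.residue_ids.shape != self.rmsf.shape:
            raise ValueError("residue_ids and rmsf lengths differ")
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF values must be non-negative")


@dataclass
class SwitchStateSeries:
    """Per-frame engaged/disengaged labels plus summary statistics."""

    engaged: np.ndarray  # boolean per frame
    threshold: float
    replicate_id: str = ""
    condition: str = ""

    @property
    def states(self) -> np.ndarray:
        return np.where(self.engaged, "engaged", "disengaged")

    @property
    def engaged_fraction(self) -> float:
        return float(np.mean(self.engaged))


# ---------------------------------------------------------------------------
# Distances and contact stability
# ---------------------------------------------------------------------------

def distance_series(traj: Trajectory, contact: ContactDefinition) -> DistanceSeries:
    """Per-frame distance for a contact over a whole trajectory.

    Windowing is the caller's concern (apply :meth:`ReplicateSet.windowed`
    first).
    """
    ia = contact.sel_a.index_array
    ib = contact.sel_b.index_array
    if contact.mode == "specific":
        d = np.linalg.norm(
            traj.coords[:, ia[0]] - traj.coords[:, ib[0]], axis=1
        )
    else:
        # frames × |a| × |b| cross-pair distances, minimum per frame
        diff = traj.coords[:, ia, None, :] - traj.coords[:, None, ib, :]
        d = np.sqrt((diff ** 2).sum(axis=-1)).min(axis=(1, 2))
    return DistanceSeries(
        name=contact.name,
        values=d,
        replicate_id=traj.replicate_id,
        condition=traj.condition,
    )


def contact_fraction(
    series_set: list[DistanceSeries], cutoff: float
) -> tuple[float, dict[str, float]]:
    """Fraction of frames with distance ≤ cutoff, pooled over replicates.

    Returns ``(pooled_fraction, per_replicate_fractions)``.  The pooled value
    is frame-count weighted, so it equals the weighted mean of the
    per-replicate fractions by construction.
    """
    if not series_set:
        raise EmptyInputError("contact_fraction needs at least one distance series")
    names = {s.name for s in series_set}
    if len(names) > 1:
        raise ValueError(f"series mix contact definitions: {sorted(names)}")
    per_rep: dict[str, float] = {}
    hits = 0
    total = 0
    for s in series_set:
        n_hit = int(np.count_nonzero(s.values <= cutoff))
        per_rep[s.replicate_id] = n_hit / len(s)
        hits += n_hit
        total += len(s)
    return hits / total, per_rep


def polar_core_series(traj: Trajectory, spec: PolarCoreSpec | None = None) -> DistanceSeries:
    """Per-frame polar-core integrity distance (switch Cζ to gate Cγ)."""
    spec = spec or PolarCoreSpec()
    pairs = [
        (spec.switch_residue, spec.switch_atom),
        (spec.gate_residue, spec.gate_atom),
    ]
    sels = []
    for resid, atom in pairs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_atoms(traj.topology, f"resid {resid} and name {atom}")
        if len(sel) != 1:
            raise SelectionError(
                f"polar-core metric: residue {resid} atom {atom!r} resolved to "
                f"{len(sel)} atoms (need exactly 1)"
            )
        sels.append(sel)
    contact = ContactDefinition(
        name=f"polar_core_{spec.switch_residue}-{spec.gate_residue}",
        sel_a=sels[0],
        sel_b=sels[1],
        mode="specific",
    )
    return distance_series(traj, contact)


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def _rmsf_single(
    traj: Trajectory,
    peptide_sel: AtomSelection,
    align_sel: AtomSelection | None,
    n_passes: int = 2,
) -> np.ndarray:
    if traj.n_frames == 1:
        warnings.warn("single-frame trajectory: RMSF is identically zero", stacklevel=3)
        return np.zeros(len(peptide_sel))
    if np.all(traj.coords == traj.coords[0]):
        # static input: exactly zero, skip the (float-noisy) superposition
        return np.zeros(len(peptide_sel))
    work = traj
    if align_sel is not None:
        # Iterative fit onto the time-averaged structure: align to frame 0,
        # recompute the mean, realign onto it (2 passes by default).
        work = superpose(work, reference_frame=0, selection=align_sel)
        for _ in range(n_passes - 1):
            mean_ref = work.coords[:, align_sel.index_array].mean(axis=0)
            work = superpose(work, selection=align_sel, reference_coords=mean_ref)
    sub = work.coords[:, peptide_sel.index_array]
    mean_pos = sub.mean(axis=0)
    return np.sqrt(((sub - mean_pos) ** 2).sum(axis=-1).mean(axis=0))


def rmsf(
    replicates: ReplicateSet,
    peptide_selection: AtomSelection,
    align_selection: AtomSelection | None,
) -> RMSFProfile:
    """Per-residue Cα RMSF averaged over replicates.

    Each replicate is windowed, superposed onto its own time-averaged
    structure over ``align_selection`` (pass ``None`` to skip alignment, e.g.
    for pre-aligned or synthetic coordinates), and the per-atom fluctuation
    about the time-averaged position is computed; replicate profiles are then
    averaged.  ``peptide_selection`` is expected to be one atom (Cα) per
    residue.
    """
    if len(peptide_selection) == 0:
        raise SelectionError("rmsf: empty peptide selection")
    top = replicates.trajectories[0].topology
    residue_ids = np.array(
        [top.atoms[i].residue_id for i in peptide_selection.indices], dtype=int
    )
    profiles = [
        _rmsf_single(t, peptide_selection, align_selection)
        for t in replicates.windowed()
    ]
    return RMSFProfile(residue_ids=residue_ids, rmsf=np.mean(profiles, axis=0))


# ---------------------------------------------------------------------------
# State classification
# ---------------------------------------------------------------------------

def classify_states(
    series: DistanceSeries, threshold: float = SWITCH_STATE_THRESHOLD
) -> SwitchStateSeries:
    """Label each frame engaged (distance ≤ threshold) or disengaged."""
    if threshold <= 0:
        raise ValueError("state threshold must be positive")
    return SwitchStateSeries(
        engaged=series.values <= threshold,
        threshold=threshold,
        replicate_id=series.replicate_id,
        condition=series.condition,
    )


# ---------------------------------------------------------------------------
# Tidy export
# ---------------------------------------------------------------------------

def series_to_frame(series_set: list[DistanceSeries]) -> pd.DataFrame:
    """Tidy long-form table: condition, replicate, frame, contact_name, distance_A."""
    rows = []
    for s in series_set:
        rows.append(
            pd.DataFrame(
                {
                    "condition": s.condition,
                    "replicate": s.replicate_id,
                    "frame": np.arange(len(s)),
                    "contact_name": s.name,
                    "distance_A": s.values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
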