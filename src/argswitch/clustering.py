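"""Quality-threshold conformer clustering of the switch residue.

Frames are clustered on the heavy-atom RMSD of a selection (by default the
switch arginine) with the greedy quality-threshold algorithm: repeatedly
seed a cluster at the unassigned frame with the most unassigned neighbours
within the RMSD cutoff, assign seed plus neighbours, and remove them.  Ties
are broken toward the lowest frame index so results are deterministic.
Cluster ids are assigned in discovery order, which (by the greedy argument)
is also non-increasing size order: cluster 0 is the largest.

Because the source ensembles are simulated with the arrestin backbone
restrained, RMSD is computed after one *global* superposition on a body
selection (or on raw coordinates), never with per-pair fitting — the
quantity clustered is the conformation of the switch residue relative to
the fixed body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError
from .traj import AtomSelection, Trajectory, superpose

__all__ = [
    "ClusterParams",
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "qt_cluster",
    "representative_frame",
]

#: Unassigned-pool label in the assignment array.
UNASSIGNED = -1


@dataclass(frozen=True)
class ClusterParams:
    """QT clustering parameters.

    ``cutoff`` is in Å — 3.7 for the broad rebinding-ensemble analysis, 1.0
    for the tight relaxation-ensemble analysis.  ``max_clusters`` truncates
    the greedy loop; remaining frames go to the unassigned pool.
    """

    cutoff: float
    max_clusters: int | None = None
    presuperpose: AtomSelection | None = None

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cluster cutoff must be positive")
        if self.max_clusters is not None and self.max_clusters < 1:
            raise ValueError("max_clusters must be ≥ 1")


@dataclass
class ClusterResult:
    """Frame assignments, populations (%) and representative frames.

    ``assignment[f]`` is the cluster id of frame ``f`` (0 = largest) or
    ``UNASSIGNED``.  ``populations[i]`` is 100 × size/total for cluster
    ``i``; ``unassigned_pct`` completes the sum to 100.  ``centers[i]`` is
    the greedy seed frame of cluster ``i``.
    """

    assignment: np.ndarray
    populations: np.ndarray
    centers: np.ndarray
    unassigned_pct: float = 0.0

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def summary(self) -> list[dict]:
        return [
            {
                "id": i,
                "population_pct": float(self.populations[i]),
                "center_frame": int(self.centers[i]),
            }
            for i in range(self.n_clusters)
        ]


def pairwise_rmsd_matrix(
    frames: Trajectory,
    selection: AtomSelection,
    presuperpose: AtomSelection | None = None,
    chunk: int = 512,
) -> np.ndarray:
    """Symmetric frame × frame RMSD matrix over ``selection`` atoms.

    If ``presuperpose`` is given, all frames are first globally fitted onto
    frame 0 over that selection; RMSD is then computed without further
    per-pair fitting.
    """
    if frames.n_frames < 2:
        raise EmptyInputError("pairwise RMSD needs at least 2 frames")
    work = frames
    if presuperpose is not None:
        work = superpose(work, reference_frame=0, selection=presuperpose)
    sub = work.coords[:, selection.index_array]  # F × A × 3
    n = sub.shape[0]
    out = np.zeros((n, n))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        diff = sub[lo:hi, None, :, :] - sub[None, :, :, :]
        out[lo:hi] = np.sqrt((diff ** 2).sum(axis=-1).mean(axis=-1))
    # exact symmetry and zero diagonal despite fp rounding
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return out


def qt_cluster(matrix: np.ndarray, params: ClusterParams) -> ClusterResult:
    """Greedy quality-threshold clustering of a precomputed RMSD matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise EmptyInputError("empty RMSD matrix")
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"RMSD matrix must be square, got {matrix.shape}")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("RMSD matrix must be symmetric")

    n = matrix.shape[0]
    neighbors = matrix <= params.cutoff  # includes self (zero diagonal)
    assignment = np.full(n, UNASSIGNED, dtype=int)
    unassigned = np.ones(n, dtype=bool)
    centers: list[int] = []
    sizes: list[int] = []

    while unassigned.any():
        if params.max_clusters is not None and len(centers) >= params.max_clusters:
            break
        counts = neighbors[:, unassigned].sum(axis=1)
        counts[~unassigned] = -1
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = neighbors[seed] & unassigned
        cluster_id = len(centers)
        assignment[members] = cluster_id
        centers.append(seed)
        sizes.append(int(members.sum()))
        unassigned &= ~members

    populations = 100.0 * np.asarray(sizes, dtype=float) / n
    return ClusterResult(
        assignment=assignment,
        populations=populations,
        centers=np.asarray(centers, dtype=int),
        unassigned_pct=100.0 * float(unassigned.sum()) / n,
    )


def representative_frame(result: ClusterResult, cluster_id: int) -> int:
    """The representative (greedy-seed) frame of a cluster."""
    if not isinstance(cluster_id, (int, np.integer)) or not (
        0 <= cluster_id < result.n_clusters
    ):
        raise KeyError(f"unknown cluster id {cluster_id!r}")
    return int(result.centers[cluster_id])
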