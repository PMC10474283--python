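"""GROMOS conformational clustering.

The classic neighbour-counting algorithm on a pairwise best-fit RMSD
matrix: repeatedly take the unassigned frame with the most neighbours
(RMSD strictly below the cutoff, 4 Å by default), make it a cluster
center together with its neighbours, remove them, and continue until
every frame is assigned.  Clusters are reported largest-first with
their population percentages and representative central structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Ensemble
from .selections import Selection


@dataclass
class ClusteringResult:
    """Outcome of GROMOS clustering.

    ``assignments[f]`` is the cluster label of frame f, with label 0 the
    largest cluster; ``centers[k]`` is the frame index of cluster k's
    center; ``populations[k]`` its percentage of all frames.
    """

    assignments: np.ndarray
    centers: list[int]
    populations: np.ndarray
    cutoff: float
    selection: Selection | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == label)


def pairwise_rmsd_matrix(ensemble: Ensemble, selection: Selection) -> np.ndarray:
    """F×F symmetric matrix of best-fit RMSD over ``selection`` (Å).

    Fit and measurement both use the selection.  Vectorized: frame
    cross-covariances are reduced to batched 3×3 SVDs, so the F(F-1)/2
    optimal superpositions never materialize rotation matrices.
    """
    if ensemble.n_frames < 2:
        raise ValueError("pairwise RMSD needs at least 2 frames")
    idx = selection.indices
    if len(idx) < 3:
        raise ValueError("RMSD fit selection needs at least 3 atoms")
    x = ensemble.coords[:, idx, :].astype(np.float64)
    x = x - x.mean(axis=1, keepdims=True)
    sq = np.einsum("fij,fij->f", x, x)  # per-frame Σ‖r‖²
    f, m = x.shape[0], len(idx)
    # degenerate (collinear) fit sets break the superposition
    s0 = np.linalg.svd(x[0], compute_uv=False)
    if s0[1] < 1e-8 * max(s0[0], 1.0):
        raise ValueError("degenerate (collinear) fit selection")
    mat = np.zeros((f, f))
    for i in range(f - 1):
        h = np.einsum("ab,jac->jbc", x[i], x[i + 1:])  # (f-i-1, 3, 3)
        s = np.linalg.svd(h, compute_uv=False)
        sign = np.sign(np.linalg.det(h))
        sign[sign == 0] = 1.0
        trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
        msd = (sq[i] + sq[i + 1:] - 2.0 * trace) / m
        row = np.sqrt(np.maximum(msd, 0.0))
        # the trace identity cancels catastrophically near zero; recompute
        # tiny entries through the explicit optimal rotation
        for k in np.flatnonzero(msd < 1e-6):
            j = i + 1 + k
            u, _, vt = np.linalg.svd(h[k])
            d = np.sign(np.linalg.det(vt.T @ u.T))
            rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
            row[k] = np.sqrt(((x[i] @ rot.T - x[j]) ** 2).sum() / m)
        mat[i, i + 1:] = row
    mat = mat + mat.T
    return mat


def gromos_cluster(matrix: np.ndarray, cutoff: float = 4.0) -> ClusteringResult:
    """GROMOS neighbour-count clustering of a pairwise RMSD matrix.

    Neighbour criterion is strict (RMSD < cutoff).  Ties in neighbour
    count are broken by the lowest frame index.  Every frame ends up in
    exactly one cluster; isolated frames become singletons.  Clusters
    are relabelled by size descending, ties by center index ascending.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    if np.any(matrix < 0):
        raise ValueError("matrix must be non-negative")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    f = matrix.shape[0]
    neighbor = matrix < cutoff
    np.fill_diagonal(neighbor, False)
    unassigned = np.ones(f, dtype=bool)
    raw_clusters: list[tuple[int, np.ndarray]] = []
    while unassigned.any():
        counts = (neighbor & unassigned[None, :] & unassigned[:, None]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[center] & unassigned)
        members = np.union1d(members, [center])
        raw_clusters.append((center, members))
        unassigned[members] = False

    order = sorted(range(len(raw_clusters)),
                   key=lambda k: (-len(raw_clusters[k][1]), raw_clusters[k][0]))
    assignments = np.empty(f, dtype=np.int64)
    centers: list[int] = []
    sizes: list[int] = []
    for new_label, k in enumerate(order):
        center, members = raw_clusters[k]
        assignments[members] = new_label
        centers.append(center)
        sizes.append(len(members))
    populations = 100.0 * np.array(sizes, dtype=np.float64) / f
    return ClusteringResult(
        assignments=assignments, centers=centers,
        populations=populations, cutoff=float(cutoff),
    )


def central_structures(result: ClusteringResult, ensemble: Ensemble) -> Ensemble:
    """Cluster-center frames as a small ensemble, in cluster order."""
    if len(result.assignments) != ensemble.n_frames:
        raise ValueError(
            f"clustering of {len(result.assignments)} frames does not match "
            f"ensemble of {ensemble.n_frames}"
        )
    if any(c < 0 or c >= ensemble.n_frames for c in result.centers):
        raise ValueError("center frame index out of range")
    coords = ensemble.coords[result.centers]
    return Ensemble(topology=ensemble.topology, coords=coords)


def assignments_table(
    result: ClusteringResult, times: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-frame assignment table (frame, optional time, cluster label)."""
    data = {"frame": np.arange(len(result.assignments))}
    if times is not None:
        data["time_ps"] = np.asarray(times)
    data["cluster"] = result.assignments
    return pd.DataFrame(data)


def summary_table(result: ClusteringResult) -> pd.DataFrame:
    """Cluster summary: label, name (Cl-a, Cl-b, ...), size, percentage, center."""
    sizes = [int((result.assignments == k).sum()) for k in range(result.n_clusters)]
    names = [_cluster_name(k) for k in range(result.n_clusters)]
    return pd.DataFrame({
        "cluster": np.arange(result.n_clusters),
        "name": names,
        "size": sizes,
        "percentage": np.round(result.populations, 1),
        "center_frame": result.centers,
    })


def _cluster_name(k: int) -> str:
    """Cl-a, Cl-b, ..., Cl-z, Cl-aa, ... in size order."""
    letters = ""
    k += 1
    while k:
        k, r = divmod(k - 1, 26)
        letters = chr(ord("a") + r) + letters
    return f"Cl-{letters}"
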