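"""Contact prevalence, residue classification, hydrogen-bond proxy, and
occupancy grids.

A residue is "in contact" in a frame when any of its heavy atoms lies
within the cutoff (3.5 Å by default, inclusive) of any heavy atom of
the partner group; prevalence is the percentage of frames in contact,
reported to one decimal.  Distance queries use a k-d tree and agree
exactly with a brute-force all-pairs scan (the boundary comparison is
``<=`` on both paths, so ties are deterministic).

Occupancy grids voxelize the positions of a selection (e.g. water
oxygens) over all frames at 1 Å resolution: a voxel is occupied in a
frame when at least one selected atom center falls in it, so occupancy
times the frame count is always an integer.  Voxels at or above the
isovalue (0.44 by default) mark conserved sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import Ensemble
from .selections import Selection
from . import geometry

logger = logging.getLogger(__name__)

HYDROPHOBIC = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "GLY"}
POLAR = {"SER", "THR", "ASN", "GLN", "TYR", "CYS", "HIS"}
CHARGED = {"ASP", "GLU", "LYS", "ARG"}


def _heavy_subset(ensemble: Ensemble, sel: Selection) -> np.ndarray:
    elem = ensemble.topology.element
    keep = [i for i in sel.indices if str(elem[i]).upper() not in ("H", "D")]
    return np.asarray(keep, dtype=np.intp)


def _residue_groups(ensemble: Ensemble, atom_indices: np.ndarray):
    """Ordered (chain, resid, resname) keys and per-key atom index arrays."""
    top = ensemble.topology
    groups: dict[tuple[str, int, str], list[int]] = {}
    for i in atom_indices:
        key = (str(top.chain_id[i]), int(top.residue_id[i]), str(top.residue_name[i]))
        groups.setdefault(key, []).append(int(i))
    return list(groups), [np.asarray(v, dtype=np.intp) for v in groups.values()]


def contact_prevalence(
    ensemble: Ensemble,
    group_a: Selection,
    group_b: Selection,
    cutoff: float = 3.5,
    heavy_only: bool = True,
) -> pd.DataFrame:
    """Per-residue contact prevalence of group A against group B.

    Returns a DataFrame with one row per residue of A (chain, resid,
    resname), the percentage of frames in contact (one decimal), and
    the raw frame count.  Groups must be disjoint.
    """
    if np.intersect1d(group_a.indices, group_b.indices).size:
        raise ValueError("contact groups overlap")
    a_idx = _heavy_subset(ensemble, group_a) if heavy_only else group_a.indices
    b_idx = _heavy_subset(ensemble, group_b) if heavy_only else group_b.indices
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValueError("contact group empty after heavy-atom restriction")
    keys, res_atoms = _residue_groups(ensemble, a_idx)
    atom_to_res = {}
    for k, atoms in enumerate(res_atoms):
        for i in atoms:
            atom_to_res[int(i)] = k
    res_of_a = np.array([atom_to_res[int(i)] for i in a_idx])
    f = ensemble.n_frames
    counts = np.zeros(len(keys), dtype=np.int64)
    for fr in range(f):
        tree = cKDTree(ensemble.coords[fr, b_idx])
        hits = tree.query_ball_point(ensemble.coords[fr, a_idx], cutoff)
        touched = np.array([bool(h) for h in hits])
        for k in np.unique(res_of_a[touched]):
            counts[k] += 1
    return pd.DataFrame({
        "chain": [k[0] for k in keys],
        "resid": [k[1] for k in keys],
        "resname": [k[2] for k in keys],
        "percentage": np.round(100.0 * counts / f, 1),
        "contact_frames": counts,
        "n_frames": f,
        "cutoff": cutoff,
    })


def contact_matrix(
    ensemble: Ensemble,
    group_a: Selection,
    group_b: Selection,
    cutoff: float = 3.5,
    heavy_only: bool = True,
) -> pd.DataFrame:
    """Residue-pair contact-percentage matrix (rows: A residues, cols: B).

    Entry (i, j) is the percentage of frames in which residues i and j
    share any heavy-atom pair within the cutoff.
    """
    if np.intersect1d(group_a.indices, group_b.indices).size:
        raise ValueError("contact groups overlap")
    a_idx = _heavy_subset(ensemble, group_a) if heavy_only else group_a.indices
    b_idx = _heavy_subset(ensemble, group_b) if heavy_only else group_b.indices
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ValueError("contact group empty after heavy-atom restriction")
    keys_a, atoms_a = _residue_groups(ensemble, a_idx)
    keys_b, atoms_b = _residue_groups(ensemble, b_idx)

    def _position_map(idx, groups):
        a2r = {int(i): k for k, atoms in enumerate(groups) for i in atoms}
        return np.array([a2r[int(i)] for i in idx])

    res_of_a = _position_map(a_idx, atoms_a)
    res_of_b = _position_map(b_idx, atoms_b)
    counts = np.zeros((len(keys_a), len(keys_b)), dtype=np.int64)
    for fr in range(ensemble.n_frames):
        tree_b = cKDTree(ensemble.coords[fr, b_idx])
        pairs = cKDTree(ensemble.coords[fr, a_idx]).query_ball_tree(tree_b, cutoff)
        seen = np.zeros_like(counts, dtype=bool)
        for ai, blist in enumerate(pairs):
            for bj in blist:
                seen[res_of_a[ai], res_of_b[bj]] = True
        counts += seen
    pct = np.round(100.0 * counts / ensemble.n_frames, 1)
    labels_a = [f"{k[0]}:{k[2]}{k[1]}" for k in keys_a]
    labels_b = [f"{k[0]}:{k[2]}{k[1]}" for k in keys_b]
    return pd.DataFrame(pct, index=labels_a, columns=labels_b)


def hbond_proxy(
    ensemble: Ensemble,
    donors: Selection,
    acceptors: Selection,
    cutoff: float = 3.5,
    angle_min: float | None = None,
) -> pd.DataFrame:
    """Geometric hydrogen-bond proxy between N/O donors and acceptors.

    A donor-acceptor pair counts in a frame when the heavy-atom
    distance is <= cutoff and, when ``angle_min`` is given and the
    donor carries hydrogens, some donor-H-acceptor angle is >=
    ``angle_min`` degrees.  Selections must contain only N/O atoms.
    """
    top = ensemble.topology
    for sel, label in ((donors, "donors"), (acceptors, "acceptors")):
        bad = [i for i in sel.indices if str(top.element[i]).upper() not in ("N", "O")]
        if bad:
            raise ValueError(f"{label} selection contains non-N/O atoms: {bad[:5]}")
    h_idx = np.array(
        [i for i in range(top.n_atoms) if str(top.element[i]).upper() in ("H", "D")],
        dtype=np.intp,
    )
    f = ensemble.n_frames
    pair_counts: dict[tuple[int, int], int] = {}
    for fr in range(f):
        xyz = ensemble.coords[fr]
        tree = cKDTree(xyz[acceptors.indices])
        for d_pos, d in enumerate(donors.indices):
            near = tree.query_ball_point(xyz[d], cutoff)
            if not near:
                continue
            if angle_min is not None and len(h_idx):
                dh = np.linalg.norm(xyz[h_idx] - xyz[d], axis=1)
                hyd = h_idx[dh < 1.25]  # covalently bound hydrogens
            else:
                hyd = np.empty(0, dtype=np.intp)
            for a_pos in near:
                a = int(acceptors.indices[a_pos])
                if a == d:
                    continue
                ok = True
                if angle_min is not None and len(hyd):
                    angles = [_dha_angle(xyz[d], xyz[h], xyz[a]) for h in hyd]
                    ok = max(angles) >= angle_min
                if ok:
                    pair_counts[(int(d), a)] = pair_counts.get((int(d), a), 0) + 1
    rows = []
    for (d, a), c in sorted(pair_counts.items()):
        rows.append({
            "donor_resname": str(top.residue_name[d]),
            "donor_resid": int(top.residue_id[d]),
            "donor_atom": str(top.atom_name[d]),
            "acceptor_resname": str(top.residue_name[a]),
            "acceptor_resid": int(top.residue_id[a]),
            "acceptor_atom": str(top.atom_name[a]),
            "percentage": round(100.0 * c / f, 1),
            "contact_frames": c,
        })
    return pd.DataFrame(
        rows, columns=[
            "donor_resname", "donor_resid", "donor_atom",
            "acceptor_resname", "acceptor_resid", "acceptor_atom",
            "percentage", "contact_frames",
        ],
    )


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    u, v = d - h, a - h
    c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1, 1))))


def classify_residue_contacts(table: pd.DataFrame) -> pd.DataFrame:
    """Label a prevalence table by residue class and sort within class.

    Classes: hydrophobic (9 residues), polar (7), charged (4); unknown
    residue names are labelled "other" with a logged warning.  Rows are
    sorted class-wise by percentage descending.
    """
    def classify(resname: str) -> str:
        r = resname.upper()
        if r in HYDROPHOBIC:
            return "hydrophobic"
        if r in POLAR:
            return "polar"
        if r in CHARGED:
            return "charged"
        logger.warning("unknown residue name %r labelled 'other'", resname)
        return "other"

    out = table.copy()
    out["class"] = [classify(r) for r in out["resname"]]
    order = {"hydrophobic": 0, "polar": 1, "charged": 2, "other": 3}
    out["_rank"] = out["class"].map(order)
    out = out.sort_values(["_rank", "percentage"], ascending=[True, False])
    return out.drop(columns="_rank").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Occupancy grids
# ---------------------------------------------------------------------------

@dataclass
class OccupancyGrid:
    """Per-voxel fraction of frames containing a selected atom."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    occupancy: np.ndarray
    isovalue: float = 0.44

    def voxels_above(self, isovalue: float | None = None):
        """Voxel indices and centers with occupancy >= isovalue."""
        iso = self.isovalue if isovalue is None else isovalue
        idx = np.argwhere(self.occupancy >= iso)
        centers = self.origin + (idx + 0.5) * self.spacing
        vals = self.occupancy[tuple(idx.T)] if len(idx) else np.empty(0)
        return idx, centers, vals


def occupancy_grid(
    ensemble: Ensemble,
    selection: Selection,
    spacing: float = 1.0,
    isovalue: float = 0.44,
    reference_fit: Selection | None = None,
) -> OccupancyGrid:
    """Binary per-frame occupancy of a selection on a regular grid.

    The grid spans the selection's bounding box over all frames, padded
    by one voxel on every side.  When ``reference_fit`` is given,
    frames are first superposed to frame 0 on that selection so the
    grid is body-fixed.
    """
    if len(selection) == 0:
        raise ValueError("empty selection for occupancy grid")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords = ensemble.coords
    if reference_fit is not None:
        coords = geometry.superpose_ensemble(ensemble, coords[0], reference_fit)
    pts = coords[:, selection.indices, :]
    lo = pts.reshape(-1, 3).min(axis=0) - spacing
    hi = pts.reshape(-1, 3).max(axis=0) + spacing
    dims = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    counts = np.zeros(dims, dtype=np.int64)
    for fr in range(ensemble.n_frames):
        vox = np.floor((pts[fr] - lo) / spacing).astype(np.int64)
        vox = np.unique(vox, axis=0)
        counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    return OccupancyGrid(
        origin=lo, spacing=float(spacing), dims=dims,
        occupancy=counts / ensemble.n_frames, isovalue=isovalue,
    )


def grid_to_dx(grid: OccupancyGrid) -> str:
    """OpenDX scalar-field text for an occupancy grid (viewer-renderable)."""
    nx, ny, nz = grid.dims
    lines = [
        "# occupancy grid (fraction of frames per voxel)",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f}",
        f"delta {grid.spacing:.6f} 0 0",
        f"delta 0 {grid.spacing:.6f} 0",
        f"delta 0 0 {grid.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.occupancy.ravel(order="C")
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6f}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    return "\n".join(lines) + "\n"
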