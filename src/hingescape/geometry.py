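"""Geometric measurements on frames and ensembles.

Centers of mass, group distances and angles, radius of gyration,
Kabsch superposition, RMSD with separate fit/measurement selections,
and ensemble-average structures.  All functions accept either a single
frame ``(N, 3)`` or a stack of frames ``(F, N, 3)`` and vectorize over
the leading axis.

Conventions: coordinates in Å, angles in degrees, masses in Da.  RMSD
deviations are mass-unweighted by default (mass weighting optional),
matching common trajectory-tool behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Ensemble, Structure
from .selections import Selection


class GeometryError(ValueError):
    """Raised on degenerate geometric input (empty/collinear selections)."""


def _weights(topology: Structure, selection: Selection, weighting: str) -> np.ndarray:
    if len(selection) == 0:
        raise GeometryError(f"empty selection {selection.expression!r}")
    if weighting == "mass":
        w = topology.masses[selection.indices]
    elif weighting == "geometric":
        w = np.ones(len(selection))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return w / w.sum()


def center_of_mass(
    coords: np.ndarray,
    topology: Structure,
    selection: Selection,
    weighting: str = "mass",
) -> np.ndarray:
    """Weighted centroid of a selection; ``(3,)`` per frame."""
    w = _weights(topology, selection, weighting)
    sub = np.asarray(coords)[..., selection.indices, :]
    return np.einsum("...ij,i->...j", sub, w)


def group_distance(
    coords: np.ndarray,
    topology: Structure,
    sel_a: Selection,
    sel_b: Selection,
    weighting: str = "mass",
) -> np.ndarray | float:
    """Euclidean distance between the COMs of two groups (Å)."""
    ca = center_of_mass(coords, topology, sel_a, weighting)
    cb = center_of_mass(coords, topology, sel_b, weighting)
    return np.linalg.norm(ca - cb, axis=-1)


def group_angle(
    coords: np.ndarray,
    topology: Structure,
    sel_a: Selection,
    sel_b: Selection,
    sel_c: Selection,
    vertex: str = "b",
    weighting: str = "mass",
) -> np.ndarray | float:
    """Angle (degrees, in [0, 180]) at the vertex COM subtended by the others.

    ``vertex`` names which of the three groups ("a", "b" or "c") sits at
    the apex; the remaining two are the arms.
    """
    coms = {
        "a": center_of_mass(coords, topology, sel_a, weighting),
        "b": center_of_mass(coords, topology, sel_b, weighting),
        "c": center_of_mass(coords, topology, sel_c, weighting),
    }
    vertex = vertex.lower()
    if vertex not in coms:
        raise ValueError("vertex must be one of 'a', 'b', 'c'")
    arms = [coms[k] for k in "abc" if k != vertex]
    u = arms[0] - coms[vertex]
    v = arms[1] - coms[vertex]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-9) or np.any(nv < 1e-9):
        raise GeometryError("vertex COM coincides with an arm COM")
    cosang = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def min_distance(
    coords: np.ndarray,
    sel_a: Selection,
    sel_b: Selection,
) -> np.ndarray | float:
    """Minimum atom-atom distance between two disjoint groups (Å)."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise GeometryError("empty selection in min_distance")
    if np.intersect1d(sel_a.indices, sel_b.indices).size:
        raise GeometryError("selections overlap; minimum distance would be zero")
    a = np.asarray(coords)[..., sel_a.indices, :]
    b = np.asarray(coords)[..., sel_b.indices, :]
    d = np.linalg.norm(a[..., :, None, :] - b[..., None, :, :], axis=-1)
    return d.min(axis=(-2, -1))


def radius_of_gyration(
    coords: np.ndarray,
    topology: Structure,
    selection: Selection,
    weighting: str = "mass",
) -> np.ndarray | float:
    """Mass-weighted radius of gyration: sqrt(Σ mᵢ‖xᵢ−COM‖² / Σ mᵢ)."""
    w = _weights(topology, selection, weighting)
    sub = np.asarray(coords)[..., selection.indices, :]
    com = np.einsum("...ij,i->...j", sub, w)
    dev = sub - com[..., None, :]
    return np.sqrt(np.einsum("...ij,...ij,i->...", dev, dev, w))


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transform:
    """Proper rigid-body transform ``x -> R @ x + t`` (rotation then shift)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rotation=rt, translation=-rt @ self.translation)


def _check_not_collinear(points: np.ndarray, what: str) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if len(s) < 2 or s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError(f"{what}: fit selection is collinear or degenerate")


def kabsch_fit(
    mobile: np.ndarray,
    reference: np.ndarray,
    topology: Structure,
    fit_selection: Selection,
    weighting: str = "geometric",
) -> Transform:
    """Least-squares proper superposition of ``mobile`` onto ``reference``.

    Returns the transform minimizing the weighted RMSD over the fit
    selection; reflections are corrected so the rotation determinant is
    always +1.  Requires at least 3 non-collinear fit atoms.
    """
    if len(fit_selection) < 3:
        raise GeometryError("kabsch_fit needs at least 3 fit atoms")
    w = _weights(topology, fit_selection, weighting)
    p = np.asarray(mobile)[fit_selection.indices]
    q = np.asarray(reference)[fit_selection.indices]
    _check_not_collinear(q, "kabsch_fit")
    pc = (w[:, None] * p).sum(axis=0)
    qc = (w[:, None] * q).sum(axis=0)
    h = (w[:, None] * (p - pc)).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return Transform(rotation=rot, translation=qc - rot @ pc)


def rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    topology: Structure,
    fit_selection: Selection,
    calc_selection: Selection | None = None,
    weighting: str = "geometric",
    superpose: bool = True,
) -> float:
    """RMSD (Å) over ``calc_selection`` after superposing on ``fit_selection``.

    Separate fit and measurement selections support e.g. measuring a
    bound peptide's deviation while aligning on the receptor backbone.
    """
    calc = calc_selection if calc_selection is not None else fit_selection
    if len(calc) == 0:
        raise GeometryError("empty calc selection")
    if superpose:
        tf = kabsch_fit(mobile, reference, topology, fit_selection, weighting)
        moved = tf.apply(mobile)
    else:
        moved = np.asarray(mobile)
    dev = moved[calc.indices] - np.asarray(reference)[calc.indices]
    if weighting == "mass":
        w = topology.masses[calc.indices]
        w = w / w.sum()
        return float(np.sqrt(np.einsum("ij,ij,i->", dev, dev, w)))
    return float(np.sqrt((dev ** 2).sum() / len(calc)))


def rmsd_series(
    ensemble: Ensemble,
    reference: np.ndarray,
    fit_selection: Selection,
    calc_selection: Selection | None = None,
    weighting: str = "geometric",
) -> np.ndarray:
    """Per-frame RMSD of every frame against one reference frame."""
    return np.array([
        rmsd(ensemble.coords[f], reference, ensemble.topology,
             fit_selection, calc_selection, weighting)
        for f in range(ensemble.n_frames)
    ])


def superpose_ensemble(
    ensemble: Ensemble,
    reference: np.ndarray,
    fit_selection: Selection,
    weighting: str = "geometric",
) -> np.ndarray:
    """All frames superposed onto a reference; returns ``(F, N, 3)``."""
    out = np.empty_like(ensemble.coords)
    for f in range(ensemble.n_frames):
        tf = kabsch_fit(ensemble.coords[f], reference, ensemble.topology,
                        fit_selection, weighting)
        out[f] = tf.apply(ensemble.coords[f])
    return out


def average_structure(
    ensemble: Ensemble,
    fit_selection: Selection,
    weighting: str = "geometric",
) -> Structure:
    """Ensemble-average structure.

    Frames are superposed to the first frame on the fit selection, the
    coordinate mean is taken, and one refinement pass re-fits all
    frames to that mean before the final average.  The result is the
    natural reference for convergence RMSD series.
    """
    fitted = superpose_ensemble(ensemble, ensemble.coords[0], fit_selection, weighting)
    mean = fitted.mean(axis=0)
    refit = superpose_ensemble(
        Ensemble(topology=ensemble.topology, coords=fitted), mean,
        fit_selection, weighting,
    )
    return ensemble.topology.with_coords(refit.mean(axis=0))
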