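"""Elastic-network normal modes, RTB reduction, essential-dynamics PCA,
and mode overlap.

The elastic network model (ENM) places harmonic springs between every
atom pair within a cutoff; the mass-weighted Hessian's eigenvectors are
the normal modes.  Mode numbering follows the rigid-body-first
convention: modes 1-6 are the zero-frequency translations/rotations, so
the softest internal motion is "mode 7".

The rotation-translation-block (RTB) approximation treats each residue
as a rigid block with up to six degrees of freedom, reducing the
eigenproblem while preserving the low-frequency (domain-hinge) modes.
Essential-dynamics PCA diagonalizes the superposed-coordinate
covariance of an ensemble; the overlap between a PCA eigenvector and a
normal mode measures how much of the sampled collective motion the
elastic network anticipates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import Ensemble, Structure
from .selections import Selection
from . import geometry

ZERO_MODE_RTOL = 1e-8  # eigenvalue < rtol * max  =>  rigid-body mode


@dataclass
class NormalModeSet:
    """Eigenvalues (ascending) and all-atom displacement eigenvectors.

    Vectors are rows of shape (3N,), mass-unweighted Cartesian and
    normalized; they are mutually orthogonal in the mass-weighted
    metric.  ``mode(k)`` uses the 1-based physical numbering in which
    the six rigid-body modes are 1-6 and the first internal mode is 7.
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    n_zero: int
    block_definition: str = "none"

    def mode(self, number: int) -> np.ndarray:
        """1-based mode lookup (mode 7 = first internal mode for n_zero=6)."""
        if number < 1 or number > len(self.eigenvalues):
            raise IndexError(f"mode {number} out of range")
        return self.vectors[number - 1]

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def build_enm_hessian(
    structure: Structure,
    cutoff: float = 8.0,
    spring_constant=None,
) -> np.ndarray:
    """Anisotropic-network Hessian for an all-atom elastic network.

    Every atom pair within ``cutoff`` Å is connected by a spring of
    stiffness ``spring_constant(r)`` (uniform 1.0 when None; pass e.g.
    ``lambda r: r**-6`` for distance-weighted springs).  Off-diagonal
    3×3 super-elements are ``-k(r) Δx Δxᵀ / r²``; diagonal blocks make
    each 3-row band sum to zero (translational invariance).  Raises if
    any atom has no neighbour (disconnected network).
    """
    if structure.n_atoms < 2:
        raise ValueError("elastic network needs at least 2 atoms")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    k_of_r = (lambda r: 1.0) if spring_constant is None else spring_constant
    xyz = structure.coords
    n = structure.n_atoms
    pairs = cKDTree(xyz).query_pairs(cutoff, output_type="ndarray")
    touched = np.zeros(n, dtype=bool)
    hess = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        d = xyz[j] - xyz[i]
        r2 = float(d @ d)
        if r2 == 0.0:
            raise ValueError(f"atoms {i} and {j} coincide")
        k = float(k_of_r(np.sqrt(r2)))
        block = -(k / r2) * np.outer(d, d)
        hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        hess[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        hess[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
        touched[i] = touched[j] = True
    if not touched.all():
        lone = int(np.flatnonzero(~touched)[0])
        raise ValueError(
            f"atom {lone} has no neighbour within {cutoff} Å; network disconnected"
        )
    return hess


def _mass_weight(hessian: np.ndarray, masses: np.ndarray) -> np.ndarray:
    inv_sqrt = np.repeat(1.0 / np.sqrt(masses), 3)
    return hessian * np.outer(inv_sqrt, inv_sqrt)


def _finalize_modes(
    eigenvalues: np.ndarray,
    mw_vectors: np.ndarray,
    masses: np.ndarray,
    block_definition: str,
) -> NormalModeSet:
    """Convert mass-weighted eigenvectors to normalized Cartesian modes."""
    inv_sqrt = np.repeat(1.0 / np.sqrt(masses), 3)
    cart = mw_vectors * inv_sqrt[None, :]
    cart /= np.linalg.norm(cart, axis=1, keepdims=True)
    emax = max(float(eigenvalues[-1]), 1e-300)
    n_zero = int(np.sum(np.abs(eigenvalues) < ZERO_MODE_RTOL * emax))
    return NormalModeSet(
        eigenvalues=eigenvalues, vectors=cart,
        n_zero=n_zero, block_definition=block_definition,
    )


def enm_modes(
    structure: Structure,
    cutoff: float = 8.0,
    spring_constant=None,
    hessian: np.ndarray | None = None,
) -> NormalModeSet:
    """Full (unreduced) normal modes of the elastic network."""
    if hessian is None:
        hessian = build_enm_hessian(structure, cutoff, spring_constant)
    mw = _mass_weight(hessian, structure.masses)
    vals, vecs = np.linalg.eigh(mw)
    return _finalize_modes(vals, vecs.T, structure.masses, "none")


def residue_blocks(structure: Structure) -> list[np.ndarray]:
    """One block of atom indices per (chain, residue), in order of appearance."""
    order: dict[tuple[str, int], list[int]] = {}
    for i, (c, r) in enumerate(zip(structure.chain_id, structure.residue_id)):
        order.setdefault((str(c), int(r)), []).append(i)
    return [np.asarray(v, dtype=np.intp) for v in order.values()]


def rtb_modes(
    hessian: np.ndarray,
    structure: Structure,
    blocks: list[np.ndarray] | None = None,
) -> NormalModeSet:
    """Rotation-translation-block reduction of an elastic-network Hessian.

    Each block (one residue by default) contributes its rigid-body
    subspace: three translations plus up to three rotations about the
    block's center of mass — fewer for blocks with < 3 non-collinear
    atoms, whose degenerate rotation axes are dropped.  The
    mass-weighted Hessian is projected onto this subspace,
    diagonalized, and eigenvectors are back-projected to all-atom
    Cartesian space.  With single-atom blocks the reduction is exact.
    """
    if blocks is None:
        blocks = residue_blocks(structure)
    n = structure.n_atoms
    seen = np.zeros(n, dtype=bool)
    for b in blocks:
        if len(b) == 0:
            raise ValueError("empty block in RTB definition")
        if seen[b].any():
            raise ValueError("blocks overlap")
        seen[b] = True
    if not seen.all():
        raise ValueError("every atom must belong to exactly one block")

    masses = structure.masses
    sqrt_m = np.sqrt(masses)
    xyz = structure.coords
    columns: list[np.ndarray] = []
    for b in blocks:
        base = np.zeros((3 * n, 6))
        ncols = 0
        # translations
        for ax in range(3):
            col = np.zeros(3 * n)
            col[3 * b + ax] = sqrt_m[b]
            base[:, ncols] = col
            ncols += 1
        # rotations about the block COM
        com = (masses[b, None] * xyz[b]).sum(axis=0) / masses[b].sum()
        rel = xyz[b] - com
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = 1.0
            disp = np.cross(e, rel)  # (len(b), 3)
            col = np.zeros(3 * n)
            for c in range(3):
                col[3 * b + c] = sqrt_m[b] * disp[:, c]
            base[:, ncols] = col
            ncols += 1
        # orthonormalize within the block; drop rank-deficient directions
        q, r = np.linalg.qr(base[:, :ncols])
        keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1e-300)
        columns.append(q[:, keep])
    p = np.concatenate(columns, axis=1)  # (3N, m), orthonormal by block disjointness

    mw = _mass_weight(hessian, masses)
    reduced = p.T @ mw @ p
    reduced = 0.5 * (reduced + reduced.T)
    vals, vecs = np.linalg.eigh(reduced)
    back = (p @ vecs).T  # (m, 3N) mass-weighted all-atom vectors
    return _finalize_modes(vals, back, masses,
                           f"{len(blocks)} blocks (one residue per block)")


@dataclass
class PCAResult:
    """Essential-dynamics PCA of an ensemble.

    ``eigenvalues`` are variances (Å²) in descending order;
    ``vectors[k]`` is the corresponding orthonormal 3M displacement
    vector over the analysis selection.  ``mode(k)`` is 1-based: mode 1
    is the dominant collective displacement.
    """

    mean: Structure
    eigenvalues: np.ndarray
    vectors: np.ndarray
    fit_selection: Selection | None = None
    analysis_selection: Selection | None = None

    def mode(self, number: int) -> np.ndarray:
        if number < 1 or number > len(self.eigenvalues):
            raise IndexError(f"PCA mode {number} out of range")
        return self.vectors[number - 1]

    def project(self, coords_sub: np.ndarray, mode_number: int = 1) -> np.ndarray:
        """Projection of (frames of) analysis-selection coords onto a mode."""
        sel = self.analysis_selection
        mean_sub = self.mean.coords if sel is None else self.mean.coords[sel.indices]
        dev = np.asarray(coords_sub) - mean_sub
        return dev.reshape(*dev.shape[:-2], -1) @ self.mode(mode_number)


def pca(
    ensemble: Ensemble,
    fit_selection: Selection,
    analysis_selection: Selection | None = None,
    mass_weighted: bool = False,
) -> PCAResult:
    """Essential-dynamics PCA.

    Frames are superposed onto the ensemble-average structure over the
    fit selection, the covariance of the analysis-selection coordinates
    is diagonalized, and eigenpairs are returned variance-descending.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    analysis = analysis_selection if analysis_selection is not None else fit_selection
    if len(analysis) == 0:
        raise ValueError("empty analysis selection")
    avg = geometry.average_structure(ensemble, fit_selection)
    fitted = geometry.superpose_ensemble(ensemble, avg.coords, fit_selection)
    sub = fitted[:, analysis.indices, :]
    if mass_weighted:
        w = np.sqrt(ensemble.topology.masses[analysis.indices])
        sub = sub * w[None, :, None]
    flat = sub.reshape(ensemble.n_frames, -1)
    mean_flat = flat.mean(axis=0)
    dev = flat - mean_flat
    cov = dev.T @ dev / ensemble.n_frames
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order].T
    mean_struct = ensemble.topology.with_coords(fitted.mean(axis=0))
    return PCAResult(
        mean=mean_struct, eigenvalues=vals, vectors=vecs,
        fit_selection=fit_selection, analysis_selection=analysis,
    )


def mode_overlap(vector_a: np.ndarray, vector_b: np.ndarray,
                 centered: bool = False) -> float:
    """Signed normalized inner product of two displacement vectors.

    The default is the raw overlap a·b/(‖a‖‖b‖) conventional for 3N
    mode comparison; ``centered=True`` gives the Pearson variant
    (components mean-centered first).
    """
    a = np.asarray(vector_a, dtype=np.float64).ravel()
    b = np.asarray(vector_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if centered:
        a = a - a.mean()
        b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector in overlap")
    # identical / negated inputs must read exactly ±1
    if np.array_equal(a, b):
        return 1.0
    if np.array_equal(a, -b):
        return -1.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def animate_mode(
    structure: Structure,
    mode_vector: np.ndarray,
    amplitude: float,
    n_frames: int = 20,
) -> Ensemble:
    """Sinusoidal displacement of a structure along one mode.

    Frame k is ``x + amplitude * sin(2πk/n) * v`` for k = 0..n-1;
    useful for writing multi-model PDB animations of a hinge mode.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    v = np.asarray(mode_vector, dtype=np.float64).reshape(structure.n_atoms, 3)
    phases = np.sin(2.0 * np.pi * np.arange(n_frames) / n_frames)
    coords = structure.coords[None, :, :] + amplitude * phases[:, None, None] * v
    return Ensemble(topology=structure, coords=coords)
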