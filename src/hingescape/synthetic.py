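"""Deterministic ensemble generators with known ground truth.

The generators stand in for undeposited MD trajectories of a
two-domain hinge protein: a WFDC-like and a Kunitz-like domain joined
by a short hinge (mature-sequence numbering Pro22-Pro133, hinge
Asp71-Asp75).  Each produces an :class:`~hingescape.io.Ensemble`
together with a :class:`GroundTruth` record sufficient to predict every
downstream statistic — state populations, planted hinge angles,
contact schedules, hydration-site occupancies, membrane anchors —
exactly or within stated stochastic bounds.

All generators are pure functions of their parameters and seed: the
same call is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .io import Ensemble, Structure
from .selections import select
from . import geometry

# Mature-sequence landmarks used by the built-in collective variables.
FIRST_RESID = 22
LAST_RESID = 133
HINGE_START = 72  # first linker residue
DOMAIN_B_START = 76

_SPECIAL_RESNAMES = {
    22: "PRO", 60: "CYS", 61: "CYS", 62: "VAL", 63: "PHE", 67: "LYS",
    69: "CYS", 71: "ASP", 75: "ASP", 90: "PHE", 96: "ASP", 100: "ASN",
    107: "TYR", 113: "ASN", 114: "ASN", 115: "ASN", 116: "ASN",
    120: "LYS", 129: "ASN", 133: "PRO",
}


@dataclass
class HingeEnsembleSpec:
    """Parameters of the two-state hinge ensemble.

    Defaults emulate the study conditions: a 112-residue protein
    (resid 22-133), closed/open interdomain angles 85°/118° with
    weights 0.7/0.3, 3° angular spread per state, 0.3 Å isotropic
    thermal jitter, 2000 frames at 250 ps spacing (500 ns total).
    """

    n_residues_domain_a: int = 50
    n_residues_domain_b: int = 58
    linker_length: int = 4
    state_angles: tuple[float, ...] = (85.0, 118.0)
    state_weights: tuple[float, ...] = (0.7, 0.3)
    angle_sigma: float = 3.0
    thermal_noise_sigma: float = 0.3
    n_frames: int = 2000
    frame_dt: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.angle_sigma < 0 or self.thermal_noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if len(self.state_angles) != len(self.state_weights):
            raise ValueError("state_angles and state_weights lengths differ")
        w = np.asarray(self.state_weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("state_weights must be a simplex")
        if self.linker_length < 1:
            raise ValueError("need at least one linker residue")


@dataclass
class GroundTruth:
    """Planted facts emitted alongside every generated ensemble."""

    state_labels: np.ndarray | None = None
    angles: np.ndarray | None = None
    contact_schedule: np.ndarray | None = None
    designated_residue: tuple[str, int, str] | None = None
    occupancy_fraction: float | None = None
    site_point: np.ndarray | None = None
    anchor_residues: frozenset[int] | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Hinge topology
# ---------------------------------------------------------------------------

_HELIX_RISE = 2.1  # Å per residue; a slightly extended (3₁₀-like) helix
                   # whose longer lever arms keep the two planted states
                   # well beyond the 4 Å clustering cutoff


def _helix_segment(n: int, origin: np.ndarray, direction: np.ndarray,
                   radius: float = 2.3, rise: float = _HELIX_RISE,
                   twist_deg: float = 100.0) -> np.ndarray:
    """Cα positions of an ideal α-helix segment along ``direction``."""
    d = direction / np.linalg.norm(direction)
    # perpendicular frame
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p1 = np.cross(d, ref)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(d, p1)
    i = np.arange(n)
    phase = np.radians(twist_deg) * i
    return (origin[None, :] + np.outer(i * rise, d)
            + radius * (np.outer(np.cos(phase), p1) + np.outer(np.sin(phase), p2)))


def _bundle(n_res: int, offsets: tuple[tuple[int, int], ...],
            seg_len: int = 15, lateral: float = 7.0) -> np.ndarray:
    """A compact antiparallel helix bundle of ``n_res`` Cα atoms.

    Segments of ideal helix run alternately along ±x and are packed on
    a 2×2 lateral grid in (y, z) following ``offsets`` (in units of
    ``lateral``), giving a globular, internally stiff domain — the kind
    of rigid body a hinge connects.  The offset order controls where
    each residue range lands inside the domain and is chosen so the
    collective-variable groups subtend the physiological interdomain-
    angle range.
    """
    coords = []
    placed = 0
    seg = 0
    length_x = (seg_len - 1) * _HELIX_RISE
    while placed < n_res:
        n = min(seg_len, n_res - placed)
        oy, oz = offsets[seg % len(offsets)]
        oy *= lateral
        oz *= lateral
        if seg % 2 == 0:
            origin = np.array([0.0, oy, oz])
            direction = np.array([1.0, 0.0, 0.0])
        else:
            origin = np.array([length_x, oy, oz])
            direction = np.array([-1.0, 0.0, 0.0])
        coords.append(_helix_segment(n, origin, direction))
        placed += n
        seg += 1
    return np.concatenate(coords, axis=0)


# Layout constants of the hinge protein: segment packing per domain,
# domain-A direction from the pivot (degrees in the xy-plane), and the
# pivot-to-domain anchor distances (Å).
_OFFSETS_A = ((0, 0), (1, 0), (0, 1), (1, 1))
_OFFSETS_B = ((1, 0), (0, 1), (0, 0), (1, 1))
_ALPHA_A_DEG = 120.0
_ANCHOR_A = 26.0
_ANCHOR_B = 4.0
_LINKER_Z_SPAN = 4.5


def _resname(resid: int) -> str:
    return _SPECIAL_RESNAMES.get(resid, "ALA")


def hinge_topology(spec: HingeEnsembleSpec | None = None) -> Structure:
    """Base Cα structure of the two-domain hinge protein.

    Domain A ends and domain B begins near the hinge pivot at the
    origin; domain B extends along +x and domain A along a direction
    120° away in the xy-plane.  The linker residues are stacked along
    the hinge axis (≈ z), which makes rotation about that axis the
    softest internal elastic-network motion — the hinge-bending mode.
    """
    spec = spec or HingeEnsembleSpec()
    na, nb, nl = spec.n_residues_domain_a, spec.n_residues_domain_b, spec.linker_length

    bundle_a = _bundle(na, _OFFSETS_A)
    bundle_b = _bundle(nb, _OFFSETS_B)

    # Domain A: rotate the bundle's +x axis onto a_dir, then translate so
    # its final residue sits ANCHOR_A Å from the pivot along a_dir.
    alpha = np.radians(_ALPHA_A_DEG)
    a_dir = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    rot_a = _rotation_from_to(np.array([1.0, 0.0, 0.0]), a_dir)
    xa = bundle_a @ rot_a.T
    xa = xa + (_ANCHOR_A * a_dir - xa[-1])

    # Domain B: extend along +x, first residue ANCHOR_B Å past the pivot.
    xb = bundle_b + (np.array([_ANCHOR_B, 0.0, 0.0]) - bundle_b[0])

    # Linker: interpolate between the attachment points, stacked in z.
    t = np.linspace(0.0, 1.0, nl + 2)[1:-1]
    xl = xa[-1][None, :] * (1 - t[:, None]) + xb[0][None, :] * t[:, None]
    xl[:, 2] += np.linspace(-_LINKER_Z_SPAN, _LINKER_Z_SPAN, nl)

    coords = np.concatenate([xa, xl, xb], axis=0)
    n_res = na + nl + nb
    resids = np.arange(FIRST_RESID, FIRST_RESID + n_res)
    return Structure(
        serial=np.arange(1, n_res + 1),
        atom_name=["CA"] * n_res,
        element=["C"] * n_res,
        residue_name=[_resname(int(r)) for r in resids],
        residue_id=resids,
        chain_id=["A"] * n_res,
        coords=coords,
    )


def _rotation_from_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180° about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, np.pi)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def hinge_axis(top: Structure) -> np.ndarray:
    """Unit hinge axis: the normal of the interdomain plane.

    The plane is spanned by the directions from the hinge pivot (the
    origin) to the domain-A angle group and to the domain-B centroid;
    rotating domain B about this normal produces the in-plane
    opening/closing motion that the interdomain-angle CV tracks.
    """
    ca_a = select(top, "resid 60-62,67-69 and ca")
    com_a = top.coords[ca_a.indices].mean(axis=0)
    com_b = top.coords[top.residue_id >= DOMAIN_B_START].mean(axis=0)
    axis = np.cross(com_a, com_b)
    n = np.linalg.norm(axis)
    if n < 1e-9:
        raise ValueError("degenerate interdomain geometry: domains collinear")
    return axis / n


def _theta_of_rotation(top: Structure) -> tuple:
    """Closure measuring the built-in interdomain angle as a function of the
    hinge rotation δ.

    A hinge opening by δ rotates domain B by +δ about the hinge axis
    through the origin; the generated frames express the same relative
    motion in domain-B-fixed coordinates (domain A and the linker
    rotated by −δ), to which every collective variable is indifferent.
    """
    ca_a = select(top, "resid 60-62,67-69 and ca")
    ca_v = select(top, "resid 120-129 and ca")
    ca_c = select(top, "resid 90-96,100-107 and ca")
    com_a0 = top.coords[ca_a.indices].mean(axis=0)
    com_v = top.coords[ca_v.indices].mean(axis=0)
    com_c = top.coords[ca_c.indices].mean(axis=0)
    axis = hinge_axis(top)
    u2 = com_c - com_v

    def theta(delta: float) -> float:
        a = _axis_rotation(axis, -delta) @ com_a0
        u1 = a - com_v
        cosang = u1 @ u2 / (np.linalg.norm(u1) * np.linalg.norm(u2))
        return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

    return theta


def _invert_theta(theta_fn, target: float) -> float:
    """Hinge rotation δ (radians) at which the measured angle equals target."""
    grid = np.radians(np.arange(-170.0, 170.5, 1.0))
    vals = np.array([theta_fn(d) for d in grid])
    diffs = vals - target
    brackets = np.flatnonzero(np.sign(diffs[:-1]) * np.sign(diffs[1:]) <= 0)
    if len(brackets) == 0:
        raise ValueError(
            f"target interdomain angle {target:.1f}° unreachable by the hinge "
            f"(range {vals.min():.1f}-{vals.max():.1f}°)"
        )
    # prefer the bracket closest to the unrotated geometry
    k = brackets[np.argmin(np.abs(grid[brackets]))]
    return float(brentq(lambda d: theta_fn(d) - target, grid[k], grid[k + 1],
                        xtol=1e-12))


def make_hinge_ensemble(spec: HingeEnsembleSpec | None = None
                        ) -> tuple[Ensemble, GroundTruth]:
    """Two-domain hinge ensemble with planted state mixture.

    Per frame a state is drawn from ``state_weights``, the target
    interdomain angle from Normal(state_angle, angle_sigma), domain B
    is rotated about the hinge axis so the built-in ``interdomain_theta``
    collective variable equals that target exactly, and isotropic
    Gaussian thermal noise is added to every atom.  Ground truth
    carries the drawn labels and exact pre-noise angles.
    """
    spec = spec or HingeEnsembleSpec()
    rng = np.random.default_rng(spec.seed)
    top = hinge_topology(spec)
    theta_fn = _theta_of_rotation(top)

    labels = rng.choice(len(spec.state_angles), size=spec.n_frames,
                        p=np.asarray(spec.state_weights, dtype=float))
    targets = np.array([
        rng.normal(spec.state_angles[s], spec.angle_sigma) for s in labels
    ])
    targets = np.clip(targets, 5.0, 175.0)

    # domain-B-fixed frames: domain A and the linker carry the rotation
    moving = top.residue_id < DOMAIN_B_START
    axis = hinge_axis(top)
    coords = np.empty((spec.n_frames, top.n_atoms, 3))
    cache: dict[float, np.ndarray] = {}
    for f in range(spec.n_frames):
        tgt = round(float(targets[f]), 6)
        if tgt not in cache:
            delta = _invert_theta(theta_fn, tgt)
            r = _axis_rotation(axis, -delta)
            frame = top.coords.copy()
            frame[moving] = frame[moving] @ r.T
            cache[tgt] = frame
        coords[f] = cache[tgt]
    if spec.thermal_noise_sigma > 0:
        coords += rng.normal(0.0, spec.thermal_noise_sigma, size=coords.shape)
    times = np.arange(spec.n_frames, dtype=float) * spec.frame_dt
    ens = Ensemble(topology=top, coords=coords, times=times)
    truth = GroundTruth(state_labels=labels, angles=targets)
    return ens, truth


def hinge_displacement_field(structure: Structure) -> np.ndarray:
    """Unit 3N displacement field of an infinitesimal hinge rotation.

    Domain B atoms move as ``a × (x - pivot)`` where ``a`` is the
    generator's hinge axis through the origin; the whole-system
    rigid-body component is
    projected out in the mass-weighted metric, leaving the internal
    hinge-bending motion that a normal mode can be compared against.
    """
    n = structure.n_atoms
    field_vec = np.zeros((n, 3))
    b_mask = structure.residue_id >= DOMAIN_B_START
    axis = hinge_axis(structure)
    field_vec[b_mask] = np.cross(axis, structure.coords[b_mask])
    flat = field_vec.ravel()

    # mass-weighted rigid-body basis of the whole structure
    m = structure.masses
    sqrt_m = np.repeat(np.sqrt(m), 3)
    com = (m[:, None] * structure.coords).sum(axis=0) / m.sum()
    rel = structure.coords - com
    basis = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        basis.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(e, rel).ravel())
    b = np.array(basis).T * sqrt_m[:, None]
    q, _ = np.linalg.qr(b)
    mw = flat * sqrt_m
    mw = mw - q @ (q.T @ mw)
    internal = mw / sqrt_m
    norm = np.linalg.norm(internal)
    if norm == 0:
        raise ValueError("hinge field vanished after rigid-body projection")
    return internal / norm


# ---------------------------------------------------------------------------
# Ligand, hydration, membrane generators
# ---------------------------------------------------------------------------

def make_ligand_trajectory(
    receptor: Structure,
    bound_fraction: float,
    contact_distance: float = 3.0,
    unbound_distance: float = 8.0,
    n_frames: int = 100,
    seed: int = 0,
    residue_id: int | None = None,
) -> tuple[Ensemble, GroundTruth]:
    """Rigid ligand bound to one designated receptor residue on a schedule.

    In exactly ``round(bound_fraction * n_frames)`` frames (chosen by
    the seeded RNG) the ligand's nearest heavy atom sits at
    ``contact_distance`` from the designated residue; otherwise at
    ``unbound_distance``.  The placement is validated so that no other
    receptor residue ever comes within 3.5 Å.
    """
    if not (0.0 <= bound_fraction <= 1.0):
        raise ValueError("bound_fraction must be in [0, 1]")
    if not (contact_distance <= 3.5 < unbound_distance):
        raise ValueError("need contact_distance <= 3.5 < unbound_distance")
    rng = np.random.default_rng(seed)
    if residue_id is None:
        residue_id = 71 if 71 in receptor.residue_id else int(
            np.sort(np.unique(receptor.residue_id))[len(np.unique(receptor.residue_id)) // 2]
        )
    res_mask = receptor.residue_id == residue_id
    if not res_mask.any():
        raise ValueError(f"residue {residue_id} not in receptor")
    res_pos = receptor.coords[res_mask].mean(axis=0)
    com = receptor.coords.mean(axis=0)
    # candidate approach directions: away from the local crowd, away from
    # the global center, and the coordinate axes as fallbacks
    near = receptor.coords[
        np.linalg.norm(receptor.coords - res_pos, axis=1) < 12.0]
    candidates = []
    for raw in (res_pos - near.mean(axis=0), res_pos - com):
        n = np.linalg.norm(raw)
        if n > 1e-9:
            candidates.append(raw / n)
    candidates += [np.array(v, dtype=float) for v in
                   ((0, 0, 1), (0, 0, -1), (0, 1, 0), (0, -1, 0),
                    (1, 0, 0), (-1, 0, 0))]

    lig_local = np.array([
        [0.0, 0.0, 0.0],
        [1.4, 0.0, 0.0],
        [2.4, 1.0, 0.0],
        [2.8, 0.0, 0.0],
    ])
    other = receptor.coords[~res_mask]

    def try_direction(direction):
        proj = receptor.coords[res_mask] @ direction
        anchor = receptor.coords[res_mask][np.argmax(proj)]
        perp = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(direction, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        axes = np.stack([direction, perp, np.cross(direction, perp)], axis=1)

        def place(distance):
            return anchor + distance * direction + lig_local @ axes.T

        for dist, must_touch in ((contact_distance, True),
                                 (unbound_distance, False)):
            lig = place(dist)
            if np.linalg.norm(
                    lig[:, None, :] - other[None, :, :], axis=-1).min() <= 3.5:
                return None
            d_res = np.linalg.norm(
                lig[:, None, :] - receptor.coords[res_mask][None, :, :],
                axis=-1).min()
            if must_touch and d_res > 3.5:
                return None
            if not must_touch and d_res <= 3.5:
                return None
        return place

    place = None
    for direction in candidates:
        place = try_direction(direction)
        if place is not None:
            break
    if place is None:
        raise ValueError(
            f"ligand placement failed: no approach to residue {residue_id} "
            "keeps every other residue beyond 3.5 Å"
        )

    n_atoms_r = receptor.n_atoms
    topology = Structure(
        serial=np.concatenate([receptor.serial,
                               np.arange(1, len(lig_local) + 1) + receptor.serial.max()]),
        atom_name=list(receptor.atom_name) + [f"C{i+1}" for i in range(len(lig_local))],
        element=list(receptor.element) + ["C"] * len(lig_local),
        residue_name=list(receptor.residue_name) + ["LIG"] * len(lig_local),
        residue_id=np.concatenate([receptor.residue_id, [1] * len(lig_local)]),
        chain_id=list(receptor.chain_id) + ["B"] * len(lig_local),
        coords=np.concatenate([receptor.coords, place(unbound_distance)]),
    )
    k = int(round(bound_fraction * n_frames))
    bound = np.zeros(n_frames, dtype=bool)
    bound[rng.permutation(n_frames)[:k]] = True
    coords = np.empty((n_frames, topology.n_atoms, 3))
    coords[:, :n_atoms_r] = receptor.coords
    bound_pose = place(contact_distance)
    unbound_pose = place(unbound_distance)
    for f in range(n_frames):
        coords[f, n_atoms_r:] = bound_pose if bound[f] else unbound_pose
    times = np.arange(n_frames, dtype=float)
    ens = Ensemble(topology=topology, coords=coords, times=times)
    resname = str(receptor.residue_name[np.flatnonzero(res_mask)[0]])
    chain = str(receptor.chain_id[np.flatnonzero(res_mask)[0]])
    truth = GroundTruth(
        contact_schedule=bound,
        designated_residue=(chain, int(residue_id), resname),
    )
    return ens, truth


def make_hydrated_site(
    protein: Structure,
    site_occupancy: float,
    n_frames: int = 50,
    seed: int = 0,
) -> tuple[Ensemble, GroundTruth]:
    """One water oxygen occupying a fixed site in a planted fraction of frames.

    The water sits at a fixed point near the protein surface in exactly
    ``round(site_occupancy * n_frames)`` frames; in the remaining
    frames it is scattered 8-18 Å away (each frame a different spot, so
    no stray voxel accumulates appreciable occupancy).
    """
    if not (0.0 <= site_occupancy <= 1.0):
        raise ValueError("site_occupancy must be in [0, 1]")
    rng = np.random.default_rng(seed)
    site = protein.coords.max(axis=0) + np.array([5.0, 5.0, 5.0])
    k = int(round(site_occupancy * n_frames))
    present = np.zeros(n_frames, dtype=bool)
    present[rng.permutation(n_frames)[:k]] = True
    topology = Structure(
        serial=np.concatenate([protein.serial, [protein.serial.max() + 1]]),
        atom_name=list(protein.atom_name) + ["O"],
        element=list(protein.element) + ["O"],
        residue_name=list(protein.residue_name) + ["HOH"],
        residue_id=np.concatenate([protein.residue_id, [1]]),
        chain_id=list(protein.chain_id) + ["W"],
        coords=np.concatenate([protein.coords, site[None, :]]),
    )
    coords = np.empty((n_frames, topology.n_atoms, 3))
    coords[:, :-1] = protein.coords
    for f in range(n_frames):
        if present[f]:
            coords[f, -1] = site
        else:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            coords[f, -1] = site + u * rng.uniform(8.0, 18.0)
    ens = Ensemble(topology=topology, coords=coords,
                   times=np.arange(n_frames, dtype=float))
    truth = GroundTruth(occupancy_fraction=k / n_frames, site_point=site.copy())
    return ens, truth


def make_anchor_foot_protein(n_residues: int = 12) -> Structure:
    """A small Cα protein with a protruding two-residue membrane foot.

    Residues 1 (LEU, hydrophobic) and 2 (SER, polar) form the foot at
    the bottom; the rest of the chain rises steeply away from it, so
    the foot residues can anchor on a membrane slab while every other
    residue stays clear.  The standard test receptor for
    :func:`make_membrane_system`.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    coords = [(0.0, 0.0, 0.0), (3.8, 0.0, 0.0)]
    for k in range(2, n_residues):
        coords.append((1.9, 1.5 * (-1) ** k, 3.0 * (k - 1)))
    resnames = ["LEU", "SER"] + ["ALA"] * (n_residues - 2)
    return Structure(
        serial=np.arange(1, n_residues + 1),
        atom_name=["CA"] * n_residues,
        element=["C"] * n_residues,
        residue_name=resnames,
        residue_id=np.arange(1, n_residues + 1),
        chain_id=["A"] * n_residues,
        coords=np.asarray(coords),
    )


def make_membrane_system(
    protein: Structure,
    anchor_residues: set[int],
    n_frames: int = 20,
    seed: int = 0,
) -> tuple[Ensemble, GroundTruth]:
    """Protein anchored on a pseudo-lipid slab through designated residues.

    The slab has labelled polar head beads (name "P", element P) at
    z = 0 and apolar tail beads (names "C1"/"C2", element C) below; the
    protein is oriented and translated so every anchor residue keeps a
    heavy atom within 3.5 Å of a head bead in every frame while all
    other residues stay beyond 5 Å of any lipid bead.  Raises when the
    protein geometry makes that placement infeasible.
    """
    anchor_residues = set(int(r) for r in anchor_residues)
    present = set(int(r) for r in np.unique(protein.residue_id))
    missing = anchor_residues - present
    if missing:
        raise ValueError(f"anchor residues not in protein: {sorted(missing)}")
    rng = np.random.default_rng(seed)

    anchor_mask = np.isin(protein.residue_id, sorted(anchor_residues))
    com_all = protein.coords.mean(axis=0)
    com_anchor = protein.coords[anchor_mask].mean(axis=0)
    down = com_anchor - com_all
    if np.linalg.norm(down) < 1e-9:
        raise ValueError("anchor set is not directionally distinct from the protein")
    rot = _rotation_from_to(down / np.linalg.norm(down), np.array([0.0, 0.0, -1.0]))
    xyz = (protein.coords - com_all) @ rot.T

    # lift so the lowest anchor atom sits 3.0 Å above the head plane (z=0)
    anchor_low = xyz[anchor_mask][:, 2].min()
    xyz = xyz + np.array([0.0, 0.0, 3.0 - anchor_low])

    for resid in sorted(anchor_residues):
        zmin = xyz[protein.residue_id == resid][:, 2].min()
        if zmin > 3.4:
            raise ValueError(
                f"placement infeasible: anchor residue {resid} cannot reach the slab"
            )
    nonanchor_low = xyz[~anchor_mask][:, 2].min() if (~anchor_mask).any() else np.inf
    if nonanchor_low < 5.2:
        raise ValueError(
            "placement infeasible: a non-anchor residue approaches the slab"
        )

    # slab: grid of lipids under the protein footprint, plus one lipid
    # directly beneath every anchor atom to guarantee the contact
    margin = 6.0
    xy_min = xyz[:, :2].min(axis=0) - margin
    xy_max = xyz[:, :2].max(axis=0) + margin
    gx = np.arange(xy_min[0], xy_max[0] + 4.0, 4.0)
    gy = np.arange(xy_min[1], xy_max[1] + 4.0, 4.0)
    head_xy = [(x, y) for x in gx for y in gy]
    head_xy += [tuple(p) for p in xyz[anchor_mask][:, :2]]

    lip_names, lip_elems, lip_res, lip_coords = [], [], [], []
    for li, (x, y) in enumerate(head_xy):
        # upper leaflet: head at z=0, tail below; lower leaflet mirrored
        lip_names += ["P", "C1", "C2", "P"]
        lip_elems += ["P", "C", "C", "P"]
        lip_res += [li + 1] * 4
        lip_coords += [(x, y, 0.0), (x, y, -4.0), (x, y, -6.0), (x, y, -10.0)]
    lip_coords = np.asarray(lip_coords)

    n_p = protein.n_atoms
    topology = Structure(
        serial=np.arange(1, n_p + len(lip_coords) + 1),
        atom_name=list(protein.atom_name) + lip_names,
        element=list(protein.element) + lip_elems,
        residue_name=list(protein.residue_name) + ["POPC"] * len(lip_coords),
        residue_id=np.concatenate([protein.residue_id, lip_res]),
        chain_id=list(protein.chain_id) + ["M"] * len(lip_coords),
        coords=np.concatenate([xyz, lip_coords]),
    )
    coords = np.empty((n_frames, topology.n_atoms, 3))
    jitter = np.clip(rng.normal(0.0, 0.03, size=(n_frames, 3)), -0.09, 0.09)
    for f in range(n_frames):
        coords[f, :n_p] = xyz + jitter[f]
        coords[f, n_p:] = lip_coords
    ens = Ensemble(topology=topology, coords=coords,
                   times=np.arange(n_frames, dtype=float))
    truth = GroundTruth(anchor_residues=frozenset(anchor_residues))
    return ens, truth
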