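"""Elastic-network modes, RTB reduction, PCA, and overlaps."""

import numpy as np
import pytest

from hingescape import (
    Ensemble,
    Structure,
    animate_mode,
    build_enm_hessian,
    enm_modes,
    mode_overlap,
    pca,
    radius_of_gyration,
    rmsd,
    rtb_modes,
    select,
)
from hingescape.synthetic import hinge_displacement_field
from conftest import make_random_structure, make_random_ensemble


def diatomic(k_distance=2.0):
    return Structure(
        serial=[1, 2], atom_name=["CA", "CA"], element=["C", "C"],
        residue_name=["ALA", "ALA"], residue_id=[1, 2], chain_id=["A", "A"],
        coords=[[0.0, 0.0, 0.0], [k_distance, 0.0, 0.0]],
    )


def enm_energy(structure, coords, cutoff, k=1.0):
    """Pair-spring energy oracle: ½ Σ k (|r| − r₀)² over reference pairs."""
    ref = structure.coords
    n = structure.n_atoms
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            r0 = np.linalg.norm(ref[j] - ref[i])
            if r0 <= cutoff:
                r = np.linalg.norm(coords[j] - coords[i])
                e += 0.5 * k * (r - r0) ** 2
    return e


class TestHessian:
    def test_diatomic_closed_form(self):
        s = diatomic()
        hess = build_enm_hessian(s, cutoff=5.0)
        # mass-weighted nonzero eigenvalue of a k=1 spring: 2k/m
        mw = hess / 12.011
        vals = np.linalg.eigvalsh(mw)
        nonzero = vals[np.abs(vals) > 1e-10]
        assert len(nonzero) == 1
        assert nonzero[0] == pytest.approx(2.0 / 12.011, rel=1e-9)

    def test_translational_invariance_row_sums(self, rng):
        s = make_random_structure(rng, 20)
        hess = build_enm_hessian(s, cutoff=12.0)
        n = s.n_atoms
        for band in range(n):
            rows = hess[3 * band:3 * band + 3]
            sums = rows.reshape(3, n, 3).sum(axis=1)
            np.testing.assert_allclose(sums, 0.0, atol=1e-10)

    def test_matches_finite_difference_of_energy(self):
        rng = np.random.default_rng(17)
        s = make_random_structure(rng, 12)
        cutoff = 15.0
        hess = build_enm_hessian(s, cutoff=cutoff)
        n3 = 3 * s.n_atoms
        h = 1e-4
        x0 = s.coords.ravel()
        fd = np.zeros((n3, n3))
        for a in range(n3):
            for b in range(a, n3):
                def e(da, db):
                    x = x0.copy()
                    x[a] += da
                    x[b] += db
                    return enm_energy(s, x.reshape(-1, 3), cutoff)
                fd[a, b] = fd[b, a] = (
                    e(h, h) - e(h, -h) - e(-h, h) + e(-h, -h)) / (4 * h * h)
        scale = np.abs(hess).max()
        np.testing.assert_allclose(fd, hess, atol=1e-5 * scale)

    def test_disconnected_atom_raises(self, rng):
        s = make_random_structure(rng, 5)
        s.coords[4] = [500.0, 0.0, 0.0]
        with pytest.raises(ValueError, match="neighbour"):
            build_enm_hessian(s, cutoff=25.0)

    def test_distance_weighted_springs(self):
        s = diatomic(2.0)
        h_uniform = build_enm_hessian(s, cutoff=5.0)
        h_weighted = build_enm_hessian(s, cutoff=5.0,
                                       spring_constant=lambda r: r ** -6)
        np.testing.assert_allclose(h_weighted, h_uniform / 2.0 ** 6, atol=1e-12)


class TestRtb:
    def test_single_atom_blocks_match_full_enm(self, rng):
        s = make_random_structure(rng, 18, atoms_per_residue=1)
        hess = build_enm_hessian(s, cutoff=15.0)
        full = enm_modes(s, hessian=hess)
        red = rtb_modes(hess, s)  # every residue is one atom
        assert red.n_modes == full.n_modes
        np.testing.assert_allclose(
            red.eigenvalues, full.eigenvalues,
            atol=1e-6 * np.abs(full.eigenvalues).max())

    def test_exactly_six_zero_modes(self, hinge_top):
        local = np.random.default_rng(823)
        dense = make_random_structure(local, 21)
        dense.coords[:] = local.uniform(-6, 6, size=(21, 3))
        for s, cutoff in ((dense, 15.0), (hinge_top, 10.0)):
            hess = build_enm_hessian(s, cutoff=cutoff)
            nm = rtb_modes(hess, s)
            assert nm.n_zero == 6

    def test_multiatom_blocks_variational_upper_bound(self, rng):
        s = make_random_structure(rng, 24, atoms_per_residue=3)
        hess = build_enm_hessian(s, cutoff=14.0)
        full = enm_modes(s, hessian=hess)
        red = rtb_modes(hess, s)
        assert red.n_modes < full.n_modes
        # RTB eigenvalues bound the corresponding full ones from above
        for k in range(red.n_modes):
            assert red.eigenvalues[k] >= full.eigenvalues[k] - 1e-10

    def test_vectors_orthonormal_mass_weighted(self, hinge_top):
        hess = build_enm_hessian(hinge_top, cutoff=10.0)
        nm = rtb_modes(hess, hinge_top)
        v = nm.vectors[:12]
        m = np.repeat(hinge_top.masses, 3)
        gram = (v * m[None, :]) @ v.T
        gram /= gram[0, 0]
        np.testing.assert_allclose(gram, np.eye(12), atol=1e-8)

    def test_hinge_mode7_matches_planted_field(self, hinge_top):
        """The softest internal mode of the two-domain system is the
        planted hinge rotation."""
        hess = build_enm_hessian(hinge_top, cutoff=10.0)
        nm = rtb_modes(hess, hinge_top)
        field = hinge_displacement_field(hinge_top)
        assert abs(mode_overlap(nm.mode(7), field)) > 0.8

    def test_empty_block_raises(self, rng):
        s = make_random_structure(rng, 6)
        hess = build_enm_hessian(s, cutoff=15.0)
        with pytest.raises(ValueError):
            rtb_modes(hess, s, blocks=[np.arange(6), np.array([], dtype=int)])


class TestPca:
    def test_identical_frames_zero_variance(self, rng):
        base = make_random_ensemble(rng, 1, 12)
        ens = Ensemble(topology=base.topology,
                       coords=np.repeat(base.coords, 6, axis=0))
        res = pca(ens, select(ens.topology, "all"))
        assert np.abs(res.eigenvalues).max() < 1e-12

    def test_planted_one_dimensional_motion(self, rng):
        top = make_random_structure(rng, 15)
        u = rng.normal(size=45)
        # plant an internal motion: remove rigid-body components, which the
        # superposition step would otherwise strip from the variance
        rel = top.coords - top.coords.mean(axis=0)
        basis = []
        for ax in range(3):
            t = np.zeros((15, 3))
            t[:, ax] = 1.0
            basis.append(t.ravel())
            e = np.zeros(3)
            e[ax] = 1.0
            basis.append(np.cross(e, rel).ravel())
        q, _ = np.linalg.qr(np.array(basis).T)
        u = u - q @ (q.T @ u)
        u /= np.linalg.norm(u)
        amps = np.random.default_rng(5).normal(0, 1.0, 200)
        coords = top.coords[None] + (amps[:, None] * u[None, :]).reshape(-1, 15, 3)
        ens = Ensemble(topology=top, coords=coords)
        res = pca(ens, select(top, "all"))
        assert res.eigenvalues[0] == pytest.approx(amps.var(), rel=0.05)
        assert abs(mode_overlap(res.mode(1), u)) > 0.999
        # projections reproduce the planted per-frame displacements
        proj = res.project(coords, 1)
        sign = np.sign(mode_overlap(res.mode(1), u))
        np.testing.assert_allclose(proj * sign, amps - amps.mean(), atol=1e-6)

    def test_trace_equals_total_fluctuation(self, rng):
        ens = make_random_ensemble(rng, 30, 10)
        sel = select(ens.topology, "all")
        res = pca(ens, sel)
        from hingescape.geometry import superpose_ensemble, average_structure
        avg = average_structure(ens, sel)
        fitted = superpose_ensemble(ens, avg.coords, sel)
        flat = fitted.reshape(30, -1)
        dev = flat - flat.mean(axis=0)
        total = (dev ** 2).sum() / 30
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-8)

    def test_single_frame_raises(self, rng):
        ens = make_random_ensemble(rng, 1, 8)
        with pytest.raises(ValueError):
            pca(ens, select(ens.topology, "all"))


class TestOverlap:
    def test_trivial_values(self):
        v = np.array([1.0, 2.0, -3.0, 0.5])
        assert mode_overlap(v, v) == 1.0
        assert mode_overlap(v, -v) == -1.0
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 1.0, 0.0])
        assert mode_overlap(e1, e2) == 0.0

    def test_centered_variant_removes_mean(self):
        v = np.array([1.0, 1.0, 1.0, 2.0])
        w = np.array([5.0, 5.0, 5.0, 6.0])
        assert mode_overlap(v, w, centered=True) == pytest.approx(1.0)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            mode_overlap(np.zeros(3), np.ones(3))


class TestAnimateMode:
    def test_rmsd_follows_sine_envelope(self, rng):
        s = make_random_structure(rng, 10)
        v = rng.normal(size=30)
        v /= np.linalg.norm(v)
        amp, nf = 2.0, 8
        ens = animate_mode(s, v, amplitude=amp, n_frames=nf)
        sel = select(s, "all")
        for k in range(nf):
            expect = amp * abs(np.sin(2 * np.pi * k / nf)) * np.sqrt(1.0 / 10)
            got = rmsd(ens.coords[k], s.coords, s, sel, superpose=False)
            assert got == pytest.approx(expect, abs=1e-9)

    def test_small_amplitude_near_identity(self, rng):
        s = make_random_structure(rng, 10)
        v = np.zeros(30)
        v[0] = 1.0
        ens = animate_mode(s, v, amplitude=1e-9, n_frames=4)
        np.testing.assert_allclose(
            ens.coords, np.repeat(s.coords[None], 4, axis=0), atol=1e-8)

    def test_rigid_rotation_mode_preserves_rg_to_first_order(self, rng):
        s = make_random_structure(rng, 12)
        com = s.coords.mean(axis=0)
        field = np.cross([0, 0, 1.0], s.coords - com).ravel()
        field /= np.linalg.norm(field)
        amp = 1e-4
        ens = animate_mode(s, field, amplitude=amp, n_frames=5)
        sel = select(s, "all")
        rg0 = radius_of_gyration(s.coords, s, sel)
        for k in range(5):
            rg = radius_of_gyration(ens.coords[k], s, sel)
            assert abs(rg - rg0) < 1e-6
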