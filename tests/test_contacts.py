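"""Contact prevalence, classification, hydrogen-bond proxy, occupancy grids."""

import numpy as np
import pandas as pd
import pytest

from hingescape import (
    Ensemble,
    Selection,
    Structure,
    classify_residue_contacts,
    contact_matrix,
    contact_prevalence,
    grid_to_dx,
    hbond_proxy,
    occupancy_grid,
    select,
)
from conftest import make_random_ensemble


def two_group_system(n_frames, schedule_distance):
    """Three-residue chain + a single-atom ligand at per-frame distances.

    ``schedule_distance[f]`` is the ligand's distance from residue 2's
    only atom along +x; residues are 4 Å apart along y.
    """
    top = Structure(
        serial=[1, 2, 3, 4],
        atom_name=["CA", "CA", "CA", "C1"],
        element=["C", "C", "C", "C"],
        residue_name=["ALA", "LEU", "LYS", "LIG"],
        residue_id=[1, 2, 3, 9],
        chain_id=["A", "A", "A", "B"],
        coords=[[0, -4, 0], [0, 0, 0], [0, 4, 0], [5, 0, 0]],
    )
    coords = np.repeat(top.coords[None], n_frames, axis=0)
    for f, d in enumerate(schedule_distance):
        coords[f, 3] = [d, 0, 0]
    return Ensemble(topology=top, coords=coords)


def brute_force_prevalence(ens, a_idx, b_idx, cutoff):
    top = ens.topology
    keys = []
    for i in a_idx:
        key = (str(top.chain_id[i]), int(top.residue_id[i]))
        if key not in keys:
            keys.append(key)
    counts = {k: 0 for k in keys}
    for f in range(ens.n_frames):
        touched = set()
        for i in a_idx:
            for j in b_idx:
                if np.linalg.norm(ens.coords[f, i] - ens.coords[f, j]) <= cutoff:
                    touched.add((str(top.chain_id[i]), int(top.residue_id[i])))
        for k in touched:
            counts[k] += 1
    return [100.0 * counts[k] / ens.n_frames for k in keys]


class TestContactPrevalence:
    def test_fixed_contact_is_100_others_0(self):
        ens = two_group_system(5, [2.0] * 5)
        table = contact_prevalence(ens, select(ens.topology, "protein"),
                                   select(ens.topology, "resname LIG"))
        by_resid = table.set_index("resid")["percentage"]
        assert by_resid[2] == 100.0
        assert by_resid[1] == 0.0 and by_resid[3] == 0.0

    def test_planted_schedule_3_of_5(self):
        ens = two_group_system(5, [2.0, 9.0, 2.0, 9.0, 2.0])
        table = contact_prevalence(ens, select(ens.topology, "protein"),
                                   select(ens.topology, "resname LIG"))
        assert table.set_index("resid")["percentage"][2] == 60.0

    def test_boundary_distance_is_inclusive(self):
        ens = two_group_system(1, [3.5])
        table = contact_prevalence(ens, select(ens.topology, "protein"),
                                   select(ens.topology, "resname LIG"))
        assert table.set_index("resid")["percentage"][2] == 100.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ens = make_random_ensemble(rng, n_frames=15, n_atoms=24)
        a = select(ens.topology, "resid 1-4")
        b = select(ens.topology, "resid 6-8")
        table = contact_prevalence(ens, a, b, cutoff=6.0, heavy_only=False)
        expect = brute_force_prevalence(ens, a.indices, b.indices, 6.0)
        np.testing.assert_allclose(table["percentage"], np.round(expect, 1))

    def test_monotone_in_cutoff(self, rng):
        ens = make_random_ensemble(rng, n_frames=10, n_atoms=24)
        a = select(ens.topology, "resid 1-4")
        b = select(ens.topology, "resid 6-8")
        t1 = contact_prevalence(ens, a, b, cutoff=4.0, heavy_only=False)
        t2 = contact_prevalence(ens, a, b, cutoff=7.0, heavy_only=False)
        assert np.all(t2["percentage"].values >= t1["percentage"].values)

    def test_duplicated_frames_unchanged(self, rng):
        ens = make_random_ensemble(rng, n_frames=6, n_atoms=24)
        a = select(ens.topology, "resid 1-4")
        b = select(ens.topology, "resid 6-8")
        doubled = Ensemble(topology=ens.topology,
                           coords=np.concatenate([ens.coords, ens.coords]))
        t1 = contact_prevalence(ens, a, b, cutoff=6.0, heavy_only=False)
        t2 = contact_prevalence(doubled, a, b, cutoff=6.0, heavy_only=False)
        np.testing.assert_allclose(t1["percentage"], t2["percentage"])

    def test_percentage_times_frames_is_integral(self, rng):
        ens = make_random_ensemble(rng, n_frames=7, n_atoms=24)
        a = select(ens.topology, "resid 1-4")
        b = select(ens.topology, "resid 6-8")
        t = contact_prevalence(ens, a, b, cutoff=6.0, heavy_only=False)
        np.testing.assert_array_equal(
            t["contact_frames"], np.round(t["percentage"] * 7 / 100).astype(int))

    def test_overlapping_groups_rejected(self, rng):
        ens = make_random_ensemble(rng, n_frames=2, n_atoms=12)
        a = select(ens.topology, "resid 1-3")
        with pytest.raises(ValueError):
            contact_prevalence(ens, a, a)


class TestContactMatrix:
    def test_single_touching_pair(self):
        ens = two_group_system(4, [2.0] * 4)
        mat = contact_matrix(ens, select(ens.topology, "protein"),
                             select(ens.topology, "resname LIG"))
        assert mat.loc["A:LEU2", "B:LIG9"] == 100.0
        assert mat.loc["A:ALA1", "B:LIG9"] == 0.0

    def test_row_max_consistent_with_prevalence(self, rng):
        ens = make_random_ensemble(rng, n_frames=12, n_atoms=24)
        a = select(ens.topology, "resid 1-4")
        b = select(ens.topology, "resid 6-8")
        mat = contact_matrix(ens, a, b, cutoff=6.0, heavy_only=False)
        prev = contact_prevalence(ens, a, b, cutoff=6.0, heavy_only=False)
        # any-residue-of-B contact can only exceed the per-pair maximum
        assert np.all(prev["percentage"].values >= mat.values.max(axis=1) - 1e-9)


class TestHbondProxy:
    def _no_system(self, d):
        top = Structure(
            serial=[1, 2], atom_name=["O", "N"], element=["O", "N"],
            residue_name=["SER", "GLN"], residue_id=[1, 2], chain_id=["A", "A"],
            coords=[[0, 0, 0], [d, 0, 0]],
        )
        return Ensemble(topology=top, coords=top.coords[None])

    def test_close_pair_counts(self):
        ens = self._no_system(2.9)
        t = hbond_proxy(ens, Selection(np.array([0]), "d"),
                        Selection(np.array([1]), "a"))
        assert t["percentage"].iloc[0] == 100.0

    def test_far_pair_does_not(self):
        ens = self._no_system(4.0)
        t = hbond_proxy(ens, Selection(np.array([0]), "d"),
                        Selection(np.array([1]), "a"))
        assert len(t) == 0

    def test_half_schedule(self):
        top = self._no_system(2.9).topology
        coords = np.repeat(top.coords[None], 4, axis=0)
        coords[1, 1] = [5.0, 0, 0]
        coords[3, 1] = [5.0, 0, 0]
        ens = Ensemble(topology=top, coords=coords)
        t = hbond_proxy(ens, Selection(np.array([0]), "d"),
                        Selection(np.array([1]), "a"))
        assert t["percentage"].iloc[0] == 50.0

    def test_rejects_carbon_donor(self, rng):
        ens = make_random_ensemble(rng, 2, 6)
        carbons = select(ens.topology, "name CA")
        oxygens = select(ens.topology, "name O")
        with pytest.raises(ValueError, match="non-N/O"):
            hbond_proxy(ens, carbons, oxygens)


class TestClassification:
    def _table(self, resnames):
        return pd.DataFrame({
            "chain": ["A"] * len(resnames),
            "resid": range(1, len(resnames) + 1),
            "resname": resnames,
            "percentage": np.linspace(90, 10, len(resnames)),
        })

    def test_lookups(self):
        out = classify_residue_contacts(self._table(["LEU", "LYS", "SER"]))
        by = out.set_index("resname")["class"]
        assert by["LEU"] == "hydrophobic"
        assert by["LYS"] == "charged"
        assert by["SER"] == "polar"

    def test_full_partition_9_7_4(self):
        names = ["ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "GLY",
                 "SER", "THR", "ASN", "GLN", "TYR", "CYS", "HIS",
                 "ASP", "GLU", "LYS", "ARG"]
        out = classify_residue_contacts(self._table(names))
        counts = out["class"].value_counts()
        assert counts["hydrophobic"] == 9
        assert counts["polar"] == 7
        assert counts["charged"] == 4

    def test_unknown_is_other(self):
        out = classify_residue_contacts(self._table(["XYZ"]))
        assert out["class"].iloc[0] == "other"

    def test_sorted_by_percentage_within_class(self):
        out = classify_residue_contacts(
            self._table(["GLY", "ALA", "LEU", "SER"]))
        hydro = out[out["class"] == "hydrophobic"]["percentage"].values
        assert list(hydro) == sorted(hydro, reverse=True)


class TestOccupancyGrid:
    def _water_system(self, positions):
        positions = np.asarray(positions, dtype=float)
        top = Structure(
            serial=[1], atom_name=["O"], element=["O"],
            residue_name=["HOH"], residue_id=[1], chain_id=["W"],
            coords=positions[0][None, :],
        )
        return Ensemble(topology=top, coords=positions[:, None, :])

    def test_fixed_water_full_occupancy(self):
        ens = self._water_system([[5.2, 5.2, 5.2]] * 4)
        grid = occupancy_grid(ens, select(ens.topology, "water"))
        idx, centers, vals = grid.voxels_above(0.44)
        assert len(vals) == 1
        assert vals[0] == 1.0

    def test_half_occupancy_above_isovalue(self):
        pos = [[5.2, 5.2, 5.2], [20.0, 5.2, 5.2]] * 3
        ens = self._water_system(pos)
        grid = occupancy_grid(ens, select(ens.topology, "water"))
        _, _, vals = grid.voxels_above(0.44)
        assert list(vals) == [0.5, 0.5]  # both sites visited half the time

    def test_total_occupied_voxels_matches_brute_force(self, rng):
        ens = make_random_ensemble(rng, n_frames=8, n_atoms=12)
        sel = select(ens.topology, "all")
        grid = occupancy_grid(ens, sel, spacing=1.0)
        total = (grid.occupancy * ens.n_frames).sum()
        expect = 0
        for f in range(8):
            vox = np.floor((ens.coords[f] - grid.origin) / grid.spacing)
            expect += len(np.unique(vox.astype(int), axis=0))
        assert total == expect

    def test_occupancy_times_frames_integral(self, rng):
        ens = make_random_ensemble(rng, n_frames=6, n_atoms=10)
        grid = occupancy_grid(ens, select(ens.topology, "all"))
        scaled = grid.occupancy * 6
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-12)

    def test_dx_export_contains_grid_metadata(self):
        ens = self._water_system([[1.0, 2.0, 3.0]] * 2)
        grid = occupancy_grid(ens, select(ens.topology, "water"))
        text = grid_to_dx(grid)
        assert "gridpositions" in text and "origin" in text
        assert "1.000000" in text  # the occupied voxel value

    def test_empty_selection_raises(self, rng):
        ens = make_random_ensemble(rng, 2, 6)
        with pytest.raises(ValueError):
            occupancy_grid(ens, select(ens.topology, "resname XYZ"))
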