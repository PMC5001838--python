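import numpy as np
import pandas as pd
import pytest

from pcdhkit import (
    build_toy_assembly,
    conserved_interface_positions,
    contact_map,
    half_vs_half_rmsd,
    inter_repeat_angles,
    interface_bsa,
    kabsch_superpose,
    principal_axes,
    read_structure,
    sasa,
    write_structure,
)
from pcdhkit.geometry import DomainStructure, InterfaceTable
from pcdhkit.synthetic import ToyStructureSpec

import biotite.structure as struc


def atom_array(coords, chains, res_ids, elements="C", atom_names="CA", hetero=False):
    coords = np.asarray(coords, dtype=np.float32)
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords
    arr.chain_id = np.array([chains] * n if isinstance(chains, str) else chains)
    arr.res_id = np.asarray(res_ids)
    arr.res_name = np.full(n, "ALA")
    arr.atom_name = np.array([atom_names] * n if isinstance(atom_names, str) else atom_names)
    arr.element = np.array([elements] * n if isinstance(elements, str) else elements)
    arr.hetero = np.full(n, hetero)
    return arr


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


TOY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C
END
"""


class TestReadStructure:
    def test_toy_pdb(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        ds = read_structure(path)
        assert ds.residue_ids("A") == [1, 2]

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB)
        ds = read_structure(path)
        assert ds.atoms.array_length() == 1
        assert ds.atoms.coord[0, 0] == pytest.approx(1.0)

    def test_missing_repeat_range_lists_gaps(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        with pytest.raises(ValueError, match=r"\[3\]"):
            read_structure(path, repeat_ranges={"A": [("EC1", 1, 3)]})

    def test_round_trip_through_pdb_text(self, tmp_path):
        ds, _ = build_toy_assembly(ToyStructureSpec())
        path = tmp_path / "dimer.pdb"
        write_structure(ds, path)
        again = read_structure(path, repeat_ranges=ds.repeats, assembly=["A", "B"])
        assert again.atoms.array_length() == ds.atoms.array_length()
        np.testing.assert_allclose(again.atoms.coord, ds.atoms.coord, atol=1e-3)
        assert list(again.atoms.res_id) == list(ds.atoms.res_id)


class TestKabsch:
    def test_identical_sets_rmsd_zero(self, rng):
        X = rng.normal(size=(8, 3))
        _, _, rmsd = kabsch_superpose(X, X)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_recovered(self, rng):
        X = rng.normal(size=(12, 3))
        R = random_rotation(rng)
        Y = X @ R.T + np.array([5.0, -2.0, 1.0])
        Rhat, t, rmsd = kabsch_superpose(X, Y)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(Rhat, R, atol=1e-10)

    def test_proper_rotation_enforced(self, rng):
        X = rng.normal(size=(10, 3))
        Y = X.copy()
        Y[:, 0] = -Y[:, 0]  # mirror image
        R, _, _ = kabsch_superpose(X, Y)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_is_error(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_superposition_never_increases_rmsd(self, rng):
        for _ in range(10):
            X = rng.normal(size=(10, 3))
            Y = rng.normal(size=(10, 3))
            before = np.sqrt(((X - Y) ** 2).sum() / len(X))
            _, _, after = kabsch_superpose(X, Y)
            assert after <= before + 1e-12


class TestPrincipalAxes:
    def test_rod_along_z(self):
        coords = np.column_stack(
            [0.3 * np.cos(np.arange(10)), 0.1 * np.sin(np.arange(10)), 4.0 * np.arange(10)]
        )
        _, axes = principal_axes(coords)
        assert abs(axes[0, 2]) > 0.999
        assert axes[0, 2] > 0  # sign toward C-terminus

    def test_axes_orthonormal(self, rng):
        coords = rng.normal(size=(20, 3)) * np.array([5.0, 2.0, 1.0])
        _, axes = principal_axes(coords)
        np.testing.assert_allclose(axes @ axes.T, np.eye(3), atol=1e-10)

    def test_rotated_rod_gives_rotated_axes(self, rng):
        coords = np.column_stack(
            [0.5 * np.cos(0.7 * np.arange(15)), 0.3 * np.sin(0.7 * np.arange(15)),
             4.0 * np.arange(15)]
        )
        _, axes = principal_axes(coords)
        R = random_rotation(rng)
        _, axes_rot = principal_axes(coords @ R.T)
        np.testing.assert_allclose(axes_rot, axes @ R.T, atol=1e-8)

    def test_spherical_cloud_is_error(self, rng):
        n = 2000
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        with pytest.raises(ValueError, match="degenerate|spherical"):
            # perfect sphere surface: eigenvalues equal within tolerance
            principal_axes(np.vstack([np.eye(3), -np.eye(3)]) * 2.0)


class TestInterRepeatAngles:
    def _rod(self):
        k = np.arange(20)
        return np.column_stack([0.5 * np.cos(0.7 * k), 0.3 * np.sin(0.7 * k), 4.0 * k])

    def test_collinear_repeats_tilt_zero_azimuth_undefined(self):
        rod = self._rod()
        shifted = rod + np.array([0.0, 0.0, 80.0])
        tilt, az = inter_repeat_angles(rod, shifted)
        assert tilt == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(az)

    def test_rotation_about_second_axis_gives_tilt(self):
        rod = self._rod()
        _, axes = principal_axes(rod)
        v2 = axes[1]
        ang = np.radians(30.0)
        K = np.array(
            [[0, -v2[2], v2[1]], [v2[2], 0, -v2[0]], [-v2[1], v2[0], 0]]
        )
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        tilt, _ = inter_repeat_angles(rod, rod @ R.T)
        assert tilt == pytest.approx(30.0, abs=1e-6)

    def test_invariant_under_global_rigid_motion(self, rng):
        ds, truth = build_toy_assembly(ToyStructureSpec(tilt=25.0, azimuth=110.0))
        a, b = truth["repeat_ca"]
        tilt0, az0 = inter_repeat_angles(a, b)
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.normal(size=3) * 10
            tilt, az = inter_repeat_angles(a @ R.T + t, b @ R.T + t)
            assert tilt == pytest.approx(tilt0, abs=1e-8)
            assert az == pytest.approx(az0, abs=1e-8)


class TestContactMap:
    def test_contact_boundaries(self):
        near = DomainStructure(
            atoms=atom_array([[0, 0, 0], [7.9, 0, 0]], "A", [1, 2])
        )
        far = DomainStructure(
            atoms=atom_array([[0, 0, 0], [8.1, 0, 0]], "A", [1, 2])
        )
        assert contact_map(near).has_contact(("A", 1), ("A", 2))
        assert len(contact_map(far).pairs) == 0

    def test_matches_brute_force(self, rng):
        n_res = 50
        coords = rng.uniform(0, 30, size=(n_res * 2, 3))
        res_ids = np.repeat(np.arange(1, n_res + 1), 2)
        ds = DomainStructure(atoms=atom_array(coords, "A", res_ids))
        cm = contact_map(ds, cutoff=8.0)
        expected = set()
        for i in range(n_res):
            for j in range(i + 1, n_res):
                d = np.linalg.norm(
                    coords[2 * i : 2 * i + 2, None, :] - coords[None, 2 * j : 2 * j + 2, :],
                    axis=2,
                ).min()
                if d < 8.0:
                    expected.add((("A", i + 1), ("A", j + 1)))
        assert cm.pairs == expected

    def test_scope_filters(self):
        ds = DomainStructure(
            atoms=atom_array([[0, 0, 0], [3, 0, 0], [6, 0, 0]], ["A", "A", "B"], [1, 2, 1])
        )
        assert len(contact_map(ds, scope="intrachain").pairs) == 1
        inter = contact_map(ds, scope="interchain").pairs
        assert all(a[0] != b[0] for a, b in inter)


class TestSasa:
    def test_isolated_sphere_analytic(self):
        ds = DomainStructure(atoms=atom_array([[0, 0, 0]], "A", [1]))
        area = sasa(ds, n_points=960, radii=1.7)[("A", 1)]
        assert area == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-5)

    def test_complex_sasa_bounded_by_sum_of_parts(self, rng):
        ds, _ = build_toy_assembly(ToyStructureSpec())
        total = sasa(ds, radii=1.7).sum()
        parts = sum(
            sasa(DomainStructure(atoms=ds.chain_atoms(c)), radii=1.7).sum()
            for c in ("A", "B")
        )
        assert total <= parts + 1e-6

    def test_quadrature_convergence(self):
        ds, _ = build_toy_assembly(ToyStructureSpec())
        s1 = sasa(ds, n_points=2000, radii=1.7)
        s2 = sasa(ds, n_points=4000, radii=1.7)
        rel = np.abs(s1.values - s2.values) / np.maximum(s2.values, 1.0)
        assert rel.max() < 0.01

    def test_unknown_element_is_error(self):
        arr = atom_array([[0, 0, 0]], "A", [1], elements="Xx")
        with pytest.raises(ValueError, match="Xx"):
            sasa(DomainStructure(atoms=arr))


class TestInterfaceBsa:
    def test_distant_protomers_bury_nothing(self):
        arr = atom_array([[0, 0, 0], [100, 0, 0]], ["A", "B"], [1, 1])
        ds = DomainStructure(atoms=arr, assembly=["A", "B"])
        table = interface_bsa(ds, radii=1.7)
        assert (table.residues["bsa"] == 0).all()
        assert table.footprint().empty

    def test_planted_patch_recovered(self):
        ds, truth = build_toy_assembly(ToyStructureSpec())
        table = interface_bsa(ds, radii=truth["atom_radius"])
        for protomer in (0, 1):
            assert sorted(table.footprint(protomer)["res_id"]) == truth["patch"]

    def test_totals_equal_member_sums(self):
        ds, _ = build_toy_assembly(ToyStructureSpec())
        table = interface_bsa(ds, radii=1.7)
        totals = table.totals()
        fp = table.footprint()
        for _, row in totals.iterrows():
            members = fp[
                (fp["protomer"] == row["protomer"])
                & (fp["pair_label"] == row["pair_label"])
            ]
            assert row["bsa"] == pytest.approx(members["bsa"].sum())

    def test_unassigned_chain_is_error(self):
        arr = atom_array([[0, 0, 0], [5, 0, 0], [9, 0, 0]], ["A", "B", "C"], [1, 1, 1])
        ds = DomainStructure(atoms=arr, assembly=["A", "B", "C"])
        with pytest.raises(ValueError, match="unassigned"):
            interface_bsa(ds, protomers=(["A"], ["B"]), radii=1.7)


def make_iface_table(buried, structure_id="s", region="EC2/EC3"):
    rows = [
        {
            "protomer": 0,
            "chain": "A",
            "res_id": r,
            "repeat": region.split("/")[0],
            "bsa": 25.0 if b else 2.0,
            "pair_label": region if b else "",
        }
        for r, b in buried.items()
    ]
    return InterfaceTable(structure_id=structure_id, residues=pd.DataFrame(rows), bsa_min=10.0)


class TestConservedInterface:
    def test_position_buried_everywhere_selected(self):
        tables = [make_iface_table({10: True}) for _ in range(6)]
        maps = [{("A", 10): 100}] * 6
        out = conserved_interface_positions(tables, maps)
        assert out[out["position"] == 100]["selected"].all()

    def test_four_of_six_not_selected_for_ec23(self):
        tables = [make_iface_table({10: i < 4}) for i in range(6)]
        maps = [{("A", 10): 100}] * 6
        out = conserved_interface_positions(tables, maps)
        row = out[(out["position"] == 100) & (out["region"] == "EC2/EC3")]
        assert row["count"].iloc[0] == 4
        assert not row["selected"].any()

    def test_four_of_five_selected_for_ec14(self):
        tables = [
            make_iface_table({7: i < 4}, region="EC1/EC4") for i in range(5)
        ]
        maps = [{("A", 7): 55}] * 5
        out = conserved_interface_positions(tables, maps)
        assert out[(out["position"] == 55)]["selected"].all()

    def test_matches_counting_oracle(self, rng):
        n_tables, n_res = 6, 15
        buried = rng.random((n_tables, n_res)) < 0.5
        tables = [
            make_iface_table({r + 1: bool(buried[t, r]) for r in range(n_res)})
            for t in range(n_tables)
        ]
        maps = [{("A", r + 1): r + 1 for r in range(n_res)}] * n_tables
        out = conserved_interface_positions(tables, maps)
        for r in range(n_res):
            count = int(buried[:, r].sum())
            rows = out[out["position"] == r + 1]
            if count == 0:
                assert rows.empty
            else:
                assert rows["count"].iloc[0] == count
                assert rows["selected"].iloc[0] == (count >= 5)


class TestHalfVsHalf:
    def test_identical_halves_superpose_exactly(self):
        ds, _ = build_toy_assembly(ToyStructureSpec())
        rmsd, n_pairs, pairing = half_vs_half_rmsd(ds, "A")
        assert n_pairs == 20
        assert rmsd == pytest.approx(0.0, abs=1e-4)
        assert len(pairing) == n_pairs
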