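import math

import numpy as np
import pytest
from helixcurate.errors import (
    FormatError,
    GeometryError,
    RadiusError,
    SelectionError,
)
from helixcurate.struct_metrics import (
    Atom,
    Structure,
    bfactor_group_percent_diff,
    buried_area,
    clash_scan,
    group_sasa,
    kabsch_superpose,
    min_group_distance,
    parse_selection,
    read_structure,
    rmsd_selection,
    sasa,
    sidechain_rotation,
    sphere_lattice,
)


def atom(name="CA", element="C", pos=(0.0, 0.0, 0.0), resnum=1,
         chain="A", resname="ALA", b=20.0):
    return Atom(element=element, atom_name=name, residue_name=resname,
                residue_number=resnum, chain_id=chain,
                position=np.array(pos, dtype=float), b_factor=b)


def rot_z(deg):
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a), 0.0],
                     [math.sin(a), math.cos(a), 0.0],
                     [0.0, 0.0, 1.0]])


class TestReadStructure:
    def test_tiny_pdb(self, tiny_pdb):
        s = read_structure(tiny_pdb)
        assert len(s) == 3
        assert s.atoms[0].element == "N"
        assert s.atoms[1].atom_name == "CA"
        np.testing.assert_allclose(
            s.atoms[0].position, [11.104, 6.134, -6.504], atol=1e-3
        )
        assert s.atoms[2].b_factor == pytest.approx(14.0)

    def test_pdb_cif_equivalence(self, tiny_pdb, tmp_path):
        import biotite.structure.io.pdb as pdb
        import biotite.structure.io.pdbx as pdbx

        arr = pdb.get_structure(pdb.PDBFile.read(str(tiny_pdb)), model=1,
                                extra_fields=["b_factor", "occupancy"])
        cif = pdbx.CIFFile()
        pdbx.set_structure(cif, arr)
        cif_path = tmp_path / "tiny.cif"
        cif.write(str(cif_path))

        a = read_structure(tiny_pdb)
        b = read_structure(cif_path)
        assert len(a) == len(b)
        for x, y in zip(a.atoms, b.atoms):
            assert x.atom_name == y.atom_name
            np.testing.assert_allclose(x.position, y.position, atol=1e-3)

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000"
            "  0.60 10.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000"
            "  0.40 10.00           C\n"
            "END\n"
        )
        path = tmp_path / "altloc.pdb"
        path.write_text(text)
        s = read_structure(path)
        assert len(s) == 1
        np.testing.assert_allclose(s.atoms[0].position, [0.0, 0.0, 0.0],
                                   atol=1e-3)

    def test_unparseable_file(self, tmp_path):
        path = tmp_path / "bad.cif"
        path.write_text("data_x\nloop_\n_nonsense\ngarbage garbage\n")
        with pytest.raises(FormatError):
            read_structure(path)


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        sup = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(sup.translation, 0.0, atol=1e-9)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_recovered(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        sup = kabsch_superpose(pts, pts + [5.0, 0.0, 0.0])
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.translation, [5.0, 0.0, 0.0],
                                   atol=1e-9)

    def test_90_degree_rotation_recovered(self):
        pts = np.random.default_rng(2).normal(size=(4, 3))
        sup = kabsch_superpose(pts, pts @ rot_z(90.0).T)
        angle = math.degrees(
            math.acos(np.clip((np.trace(sup.rotation) - 1.0) / 2.0, -1, 1))
        )
        assert angle == pytest.approx(90.0, abs=1e-6)
        assert sup.rmsd < 1e-9

    def test_count_mismatch(self):
        with pytest.raises(SelectionError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_rmsd_matches_rotation_grid_brute_force(self):
        rng = np.random.default_rng(3)
        mobile = rng.normal(size=(5, 3))
        reference = rng.normal(size=(5, 3))
        best = kabsch_superpose(mobile, reference).rmsd

        # brute force: scan z-y-z Euler rotations on a 2-degree grid
        from scipy.spatial.transform import Rotation

        m0 = mobile - mobile.mean(axis=0)
        r0 = reference - reference.mean(axis=0)
        grid = np.arange(0.0, 360.0, 2.0)
        beta_grid = np.arange(0.0, 180.0 + 1e-9, 2.0)
        bg, gg = np.meshgrid(beta_grid, grid, indexing="ij")
        brute = np.inf
        for alpha in grid:
            angles = np.column_stack([
                np.full(bg.size, alpha), bg.ravel(), gg.ravel()
            ])
            mats = Rotation.from_euler("zyz", angles,
                                       degrees=True).as_matrix()
            moved = np.einsum("rij,nj->rni", mats, m0)
            vals = np.sqrt(
                np.mean(np.sum((moved - r0) ** 2, axis=2), axis=1)
            )
            brute = min(brute, float(vals.min()))
        assert best <= brute + 1e-9
        assert brute - best < 0.05  # grid tolerance


class TestRmsdSelection:
    def test_identical(self):
        s = Structure([atom(resnum=i) for i in range(1, 5)])
        assert rmsd_selection(s, s, parse_selection("name CA")) == \
            pytest.approx(0.0, abs=1e-9)

    def test_one_displaced_atom_no_superposition(self):
        a = Structure([atom(resnum=i, pos=(i * 10.0, 0, 0))
                       for i in range(1, 5)])
        moved = [at for at in a.atoms]
        b_atoms = [
            Atom(at.element, at.atom_name, at.residue_name,
                 at.residue_number, at.chain_id, at.position.copy(),
                 at.b_factor)
            for at in moved
        ]
        b_atoms[0].position = b_atoms[0].position + [0.0, 1.0, 0.0]
        b = Structure(b_atoms)
        value = rmsd_selection(a, b, parse_selection("name CA"),
                               superpose=False)
        assert value == pytest.approx(0.5)

    def test_no_matches_is_error(self):
        a = Structure([atom(chain="A")])
        b = Structure([atom(chain="B")])
        with pytest.raises(SelectionError):
            rmsd_selection(a, b, parse_selection("chain A"))


class TestSasa:
    def test_single_carbon_closed_form(self):
        s = Structure([atom()])
        area = sasa(s)[0]
        exact = 4.0 * math.pi * (1.7 + 1.4) ** 2
        assert abs(area - exact) / exact < 0.005

    def test_distant_atoms_isolated(self):
        s = Structure([atom(), atom(pos=(100.0, 0, 0), resnum=2)])
        areas = sasa(s)
        exact = 4.0 * math.pi * 3.1 ** 2
        np.testing.assert_allclose(areas, exact, rtol=0.005)

    def test_caged_atom_nearly_buried(self):
        center = atom()
        cage = [
            atom(pos=(2.0 * dx, 2.0 * dy, 2.0 * dz), resnum=2 + k)
            for k, (dx, dy, dz) in enumerate(
                (dx, dy, dz)
                for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                for dz in (-1, 0, 1)
                if (dx, dy, dz) != (0, 0, 0)
            )
        ]
        areas = sasa(Structure([center] + cage))
        isolated = 4.0 * math.pi * 3.1 ** 2
        assert areas[0] < 0.01 * isolated

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(scale=3.0, size=(8, 3))
        s1 = Structure([atom(pos=p, resnum=i + 1)
                        for i, p in enumerate(pts)])
        moved = pts @ rot_z(37.0).T + [5.0, -3.0, 11.0]
        s2 = Structure([atom(pos=p, resnum=i + 1)
                        for i, p in enumerate(moved)])
        a1, a2 = sasa(s1), sasa(s2)
        total1, total2 = a1.sum(), a2.sum()
        assert abs(total1 - total2) / total1 < 0.005

    def test_adding_atom_never_increases_per_atom_sasa(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(scale=2.5, size=(6, 3))
        base = [atom(pos=p, resnum=i + 1) for i, p in enumerate(pts)]
        before = sasa(Structure(base))
        extra = atom(pos=(0.5, 0.5, 0.5), resnum=99)
        after = sasa(Structure(base + [extra]))[:-1]
        assert np.all(after <= before + 1e-9)

    def test_unknown_element(self):
        s = Structure([atom(element="Zz")])
        with pytest.raises(RadiusError):
            sasa(s)
        # override table accepted
        areas = sasa(s, radii_overrides={"Zz": 1.7})
        assert areas[0] > 0

    def test_lattice_is_deterministic_and_unit(self):
        lat = sphere_lattice(960)
        np.testing.assert_allclose(np.linalg.norm(lat, axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_array_equal(lat, sphere_lattice(960))


class TestGroupSasa:
    def test_whole_structure_equals_total(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(scale=3.0, size=(5, 3))
        s = Structure([atom(pos=p, resnum=i + 1)
                       for i, p in enumerate(pts)])
        total = sasa(s).sum()
        assert group_sasa(s, parse_selection("resi 1-5")) == \
            pytest.approx(total)

    def test_empty_selection(self):
        s = Structure([atom()])
        with pytest.raises(SelectionError):
            group_sasa(s, parse_selection("chain Z"))

    def test_free_cysteine_sidechain_order_of_magnitude(self):
        # rough CYS geometry: SASA of the side chain alone is ~1e2 Å^2
        atoms = [
            atom("N", "N", (-0.5, 1.4, 0.0)),
            atom("CA", "C", (0.0, 0.0, 0.0)),
            atom("C", "C", (1.5, 0.0, 0.2)),
            atom("O", "O", (2.2, 1.0, 0.3)),
            atom("CB", "C", (-0.7, -0.8, -1.1), resname="CYS"),
            atom("SG", "S", (-0.4, -2.6, -1.0), resname="CYS"),
        ]
        for a in atoms:
            a.residue_name = "CYS"
        s = Structure(atoms)
        value = group_sasa(s, parse_selection("sidechain"))
        assert 50.0 < value < 250.0


class TestBuriedArea:
    def test_isolated_group_zero(self):
        s = Structure([atom(), atom(pos=(100.0, 0, 0), resnum=2)])
        value = buried_area(s, parse_selection("resi 1"))
        assert value == pytest.approx(0.0, abs=0.5)

    def test_contact_pair_matches_spherical_cap(self):
        # two identical carbons at 1.7 Å: buried area of one equals the
        # spherical cap hidden inside the neighbor's expanded sphere
        s = Structure([atom(), atom(pos=(1.7, 0, 0), resnum=2)])
        value = buried_area(s, parse_selection("resi 1"))
        r = 1.7 + 1.4
        cap_height = r - 1.7 / 2.0
        analytic = 2.0 * math.pi * r * cap_height
        assert value == pytest.approx(analytic, rel=0.01)

    def test_polymer_pocket_burial_positive(self):
        from helixcurate.synthetic_data import generate_toy_polymer

        poly = generate_toy_polymer(3, 5.0, 120.0)
        value = buried_area(poly, parse_selection("resi 2"))
        assert value > 0.0


class TestDistances:
    def test_two_atoms(self):
        s = Structure([atom(resnum=1), atom(resnum=2, pos=(5.0, 0, 0))])
        d, (a, b) = min_group_distance(
            s, parse_selection("resi 1"), parse_selection("resi 2")
        )
        assert d == pytest.approx(5.0)
        assert (a.residue_number, b.residue_number) == (1, 2)

    def test_argmin_pair(self):
        s = Structure([
            atom(resnum=1, pos=(7.0, 0, 0)),
            atom(resnum=1, name="CB", pos=(3.0, 0, 0)),
            atom(resnum=2, pos=(0.0, 0, 0)),
        ])
        d, (a, _) = min_group_distance(
            s, parse_selection("resi 1"), parse_selection("resi 2")
        )
        assert d == pytest.approx(3.0)
        assert a.atom_name == "CB"

    def test_empty_selection(self):
        s = Structure([atom()])
        with pytest.raises(SelectionError):
            min_group_distance(s, parse_selection("resi 1"),
                               parse_selection("resi 99"))


class TestBfactor:
    def test_identical_zero(self):
        s = Structure([atom(b=37.0), atom(resnum=2, b=11.0)])
        assert bfactor_group_percent_diff(
            s, s, parse_selection("resi 1-2")
        ) == 0.0

    def test_constructed_seven_point_three(self):
        a = Structure([atom(b=53.65)])
        b = Structure([atom(b=50.0)])
        value = bfactor_group_percent_diff(a, b, parse_selection("resi 1"))
        assert value == pytest.approx(7.3)

    def test_empty_selection(self):
        s = Structure([atom()])
        with pytest.raises(SelectionError):
            bfactor_group_percent_diff(s, s, parse_selection("resi 9"))


class TestClashScan:
    def test_touching_spheres_no_clash(self):
        a = Structure([atom()])
        b = Structure([atom(pos=(3.4, 0, 0))])
        assert len(clash_scan(a, b)) == 0

    def test_overlap_arithmetic(self):
        a = Structure([atom()])
        b = Structure([atom(pos=(2.9, 0, 0))])
        report = clash_scan(a, b)
        assert len(report) == 1
        assert report.clashes[0].overlap == pytest.approx(0.5)
        assert report.clashes[0].distance == pytest.approx(2.9)

    def test_hydrogens_excluded(self):
        a = Structure([atom(name="H1", element="H")])
        b = Structure([atom(pos=(0.5, 0, 0))])
        assert len(clash_scan(a, b)) == 0

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = Structure([atom(pos=p, resnum=i + 1) for i, p in
                       enumerate(rng.normal(scale=2.0, size=(5, 3)))])
        b = Structure([atom(pos=p, resnum=i + 1, chain="B") for i, p in
                       enumerate(rng.normal(scale=2.0, size=(5, 3)))])
        ab = clash_scan(a, b)
        ba = clash_scan(b, a)
        pairs_ab = {(la, lb) for la, lb in ab.pair_labels()}
        pairs_ba = {(lb, la) for la, lb in ba.pair_labels()}
        assert pairs_ab == pairs_ba


def _tyrosine_ring(resnum=1):
    # regular hexagon in the xy plane plus stem atoms
    ring_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    atoms = [
        atom(name, "C",
             (1.4 * math.cos(math.radians(60 * i)),
              1.4 * math.sin(math.radians(60 * i)), 0.0),
             resnum=resnum, resname="TYR")
        for i, name in enumerate(ring_names)
    ]
    atoms.append(atom("CB", "C", (2.9, 0.0, 0.0), resnum=resnum,
                      resname="TYR"))
    return atoms


class TestSidechainRotation:
    def test_identical_residues(self):
        ring = _tyrosine_ring()
        assert sidechain_rotation(ring, ring) == pytest.approx(0.0,
                                                               abs=1e-6)

    @pytest.mark.parametrize("angle", [90.0, 44.1, 72.3])
    def test_in_plane_axis_rotation_recovered(self, angle):
        ring = _tyrosine_ring()
        a = math.radians(angle)
        rx = np.array([[1, 0, 0],
                       [0, math.cos(a), -math.sin(a)],
                       [0, math.sin(a), math.cos(a)]])
        rotated = [
            Atom(at.element, at.atom_name, at.residue_name,
                 at.residue_number, at.chain_id, rx @ at.position,
                 at.b_factor)
            for at in ring
        ]
        assert sidechain_rotation(ring, rotated) == pytest.approx(
            angle, abs=1e-6
        )

    def test_noncyclic_vector_angle(self):
        lys_a = [
            atom("CB", "C", (0.0, 0.0, 0.0), resname="LYS"),
            atom("NZ", "N", (0.0, 0.0, 4.0), resname="LYS"),
        ]
        lys_b = [
            atom("CB", "C", (0.0, 0.0, 0.0), resname="LYS"),
            atom("NZ", "N", (0.0, 4.0, 0.0), resname="LYS"),
        ]
        assert sidechain_rotation(lys_a, lys_b) == pytest.approx(
            90.0, abs=1e-6
        )

    def test_too_few_ring_atoms(self):
        partial = _tyrosine_ring()[:2]
        # falls back to the vector rule, which needs CB
        with pytest.raises(GeometryError):
            sidechain_rotation(partial, partial)
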