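"""SASA, shell densities, glycosidic chi and backbone pseudotorsions."""

import numpy as np
import pytest
from conftest import make_atom, random_structure

from amine_profiler import descriptors as D
from amine_profiler.errors import EmptyStructure
from amine_profiler.fixtures import (
    make_geometry_probe,
    make_helix,
    make_pair,
)
from amine_profiler.geometry import dihedral, nerf_place, rotation_about_axis
from amine_profiler.structure import Structure, protonate_amines


def dihedral_oracle(p0, p1, p2, p3):
    """Independent torsion formula via plane normals + triple product."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(y, x))


class TestSASA:
    def test_lone_nitrogen_closed_form(self):
        st = Structure([make_atom("N", "N", [0, 0, 0])])
        value = D.shrake_rupley_sasa(st, [0])[0]
        exact = 4 * np.pi * (1.55 + 1.40) ** 2
        assert abs(value - exact) / exact < 0.01

    def test_fully_enclosed_nitrogen_is_zero(self):
        shell = D.sphere_points(80) * 2.9
        atoms = [make_atom("N", "N", [0, 0, 0])]
        atoms += [make_atom("O", "O", p, resnum=2 + i) for i, p in enumerate(shell)]
        assert D.shrake_rupley_sasa(Structure(atoms), [0])[0] == 0.0

    def test_never_exceeds_lone_atom_bound(self):
        st = random_structure(5, n_residues=8)
        values = D.shrake_rupley_sasa(st, range(len(st.atoms)))
        for a, v in zip(st.atoms, values):
            r = D.VDW_RADII.get(a.element.upper(), 1.70)
            assert v <= 4 * np.pi * (r + 1.40) ** 2 + 1e-9

    def test_adding_atom_never_increases_sasa(self):
        st = random_structure(6, n_residues=4)
        before = D.shrake_rupley_sasa(st, range(len(st.atoms)))
        bigger = st.copy()
        center = st.positions().mean(axis=0)
        bigger.add_atom(make_atom("O", "O", center, chain="Z", resnum=999))
        after = D.shrake_rupley_sasa(bigger, range(len(st.atoms)))
        assert (after <= before + 1e-9).all()

    def test_agrees_with_biopython(self, helix, tmp_path):
        Bio = pytest.importorskip("Bio.PDB")
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley
        path = tmp_path / "h.pdb"
        helix.write(path)
        bst = PDBParser(QUIET=True).get_structure("h", str(path))
        ShrakeRupley(probe_radius=1.40, n_points=100).compute(bst, level="A")
        reference = {}
        for a in bst.get_atoms():
            res = a.get_parent()
            reference[(res.get_parent().id, res.id[1], a.get_name())] = a.sasa
        ours = D.shrake_rupley_sasa(helix, range(len(helix.atoms)))
        diffs = [ours[i] - reference[(a.chain, a.residue_number, a.atom_name)]
                 for i, a in enumerate(helix.atoms)
                 if (a.chain, a.residue_number, a.atom_name) in reference]
        assert np.mean(np.abs(diffs)) < 1.5  # different point sets/radii tables

    def test_empty_structure_raises(self):
        with pytest.raises(EmptyStructure):
            D.shrake_rupley_sasa(Structure([]), [0])


class TestShellDensity:
    def test_isolated_nitrogen_analytic(self):
        st = Structure([make_atom("N", "N", [0, 0, 0])])
        rho1, rho2 = D.shell_density(st, [0, 0, 0])
        assert abs(rho1 - 1 / 1.7671) < 1e-3
        assert rho2 == 0.0

    def test_hundred_atoms_at_5A(self):
        pts = D.sphere_points(100) * 5.0
        atoms = [make_atom("N", "N", [0, 0, 0])]
        atoms += [make_atom("O", "O", p, resnum=2 + i) for i, p in enumerate(pts)]
        rho1, rho2 = D.shell_density(Structure(atoms), [0, 0, 0])
        assert abs(rho1 - 101 / 1.7671) < 1e-2 and rho2 == 0.0

    def test_boundary_closed_on_outer_edge(self):
        atoms = [make_atom("N", "N", [0, 0, 0]),
                 make_atom("O", "O", [7.5, 0, 0], resnum=2),
                 make_atom("O", "O", [12.5, 0, 0], resnum=3),
                 make_atom("O", "O", [12.6, 0, 0], resnum=4)]
        rho1, rho2 = D.shell_density(Structure(atoms), [0, 0, 0])
        assert round(rho1 * D.ROI1_VOLUME_NM3) == 2  # N itself + atom at 7.5
        assert round(rho2 * D.ROI2_VOLUME_NM3) == 1  # atom at 12.5 only

    def test_brute_force_agreement(self, helix):
        for site in protonate_amines(helix)[0][:4]:
            rho1, rho2 = D.shell_density(helix, site.n_position)
            c1 = sum(1 for a in helix.atoms if a.element != "H" and a.is_polymer
                     and np.linalg.norm(a.position - site.n_position) <= 7.5)
            c2 = sum(1 for a in helix.atoms if a.element != "H" and a.is_polymer
                     and 7.5 < np.linalg.norm(a.position - site.n_position) <= 12.5)
            assert round(rho1 * D.ROI1_VOLUME_NM3) == c1
            assert round(rho2 * D.ROI2_VOLUME_NM3) == c2

    def test_waters_and_ligands_not_counted(self):
        atoms = [make_atom("N", "N", [0, 0, 0]),
                 make_atom("O", "O", [3, 0, 0], chain="W", resnum=1,
                           resname="HOH", is_polymer=False)]
        rho1, _ = D.shell_density(Structure(atoms), [0, 0, 0])
        assert round(rho1 * D.ROI1_VOLUME_NM3) == 1


def _four_point_residue(torsion, mirror=False):
    """Planar-zigzag O4'-C1'-N9-C4 construction with a known chi."""
    c4 = np.array([0.0, 1.4, 0.0])
    n9 = np.array([0.0, 0.0, 0.0])
    c1 = np.array([1.47, 0.0, 0.0])
    o4 = nerf_place(c4, n9, c1, 1.41, 108.0, torsion)
    pts = {"C4": c4, "N9": n9, "C1'": c1, "O4'": o4}
    if mirror:
        pts = {k: v * np.array([1.0, 1.0, -1.0]) for k, v in pts.items()}
    st = Structure([make_atom(k, k[0], v, resname="A") for k, v in pts.items()])
    return st.residues[("A", 1, "")]


class TestChi:
    def test_analytic_construction(self):
        assert abs(D.chi(_four_point_residue(60.0)) - 60.0) < 1e-9

    def test_mirror_flips_sign(self):
        assert abs(D.chi(_four_point_residue(60.0, mirror=True)) + 60.0) < 1e-9

    def test_helix_residues_are_anti(self, helix):
        for res in helix.chain_residues("A"):
            value = D.chi(res)
            assert value is not None and not D.is_syn(value)
            assert abs(value - (-160.0)) < 1e-3  # generator's canonical chi

    def test_missing_atom_undefined(self, helix):
        res = helix.chain_residues("A")[0]
        clone = Structure([a for a in helix.atoms
                           if not (a.residue_key == res.key and a.atom_name == "O4'")])
        assert D.chi(clone.residues[res.key]) is None

    @pytest.mark.parametrize("value,syn,minor", [
        (-89.9, True, False), (-90.1, False, False), (89.9, True, True),
        (90.1, False, True), (-19.9, True, True), (-20.1, True, False),
        (129.9, False, True), (130.1, False, False), (None, False, False),
    ])
    def test_syn_and_minor_windows(self, value, syn, minor):
        assert D.is_syn(value) is syn
        assert D.is_minor(value) is minor

    def test_rigid_motion_invariance(self):
        res = _four_point_residue(77.0)
        R = rotation_about_axis([3, 1, 2], 29.0)
        t = np.array([4.0, 5.0, 6.0])
        moved = Structure([make_atom(a.atom_name, a.element,
                                     R @ a.position + t, resname="A")
                           for a in res.atoms.values()])
        assert abs(D.chi(moved.residues[("A", 1, "")]) - 77.0) < 1e-9


class TestEtaTheta:
    def test_helix_interior_in_a_form_box(self, long_helix):
        for chain in ("A", "B"):
            rs = long_helix.chain_residues(chain)
            for i in range(1, len(rs) - 1):
                eta, theta = D.eta_theta(rs[i - 1], rs[i], rs[i + 1])
                assert D.in_region(eta, theta, D.A_FORM_BOX), (chain, i, eta, theta)

    def test_chain_termini_undefined(self, helix):
        et = D.chain_eta_theta(helix, "A")
        keys = sorted(et, key=lambda k: k[1])
        assert et[keys[0]][0] is None       # first residue: no eta
        assert et[keys[-1]] == (None, None)  # last residue: neither

    def test_chain_break_undefines(self, helix):
        # displace one O3' far away: the link i -> i+1 is broken
        broken = helix.copy()
        for a in broken.atoms:
            if a.residue_key == ("A", 2, "") and a.atom_name == "O3'":
                a.position = a.position + np.array([0, 0, 50.0])
        rs = broken.chain_residues("A")
        eta, theta = D.eta_theta(rs[1], rs[2], rs[3])
        assert eta is None  # prev->res link broken
        eta3, theta3 = D.eta_theta(rs[0], rs[1], rs[2])
        assert theta3 is None  # res->next link broken

    def test_oracle_agreement_on_random_coordinates(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            pts = rng.normal(scale=5.0, size=(4, 3))
            ours = dihedral(*pts)
            theirs = dihedral_oracle(*pts)
            assert abs(((ours - theirs + 180) % 360) - 180) < 1e-9

    def test_mapped_to_full_circle(self, helix):
        et = D.chain_eta_theta(helix, "A")
        for eta, theta in et.values():
            for v in (eta, theta):
                if v is not None:
                    assert 0.0 <= v < 360.0


class TestRegions:
    @pytest.mark.parametrize("eta,theta,box,inside", [
        (50.0, 160.0, D.LOCATION_1, True),
        (300.0, 20.0, D.LOCATION_2, True),
        (170.0, 220.0, D.A_FORM_BOX, True),
        (43.0, 151.0, D.LOCATION_1, True),   # inclusive edges
        (42.9, 160.0, D.LOCATION_1, False),
        (None, 160.0, D.LOCATION_1, False),
        (50.0, None, D.LOCATION_1, False),
    ])
    def test_membership(self, eta, theta, box, inside):
        assert D.in_region(eta, theta, box) is inside


class TestBurialOrdering:
    def test_cohort_reproduces_non_single_dual_ordering(self):
        """Burial increases along non -> single -> dual in a constructed
        cohort: bare bases (non), Watson-Crick pairs (single), and
        dual-donating pairs with extra packing."""
        from amine_profiler import pipeline
        cohort = []
        for i in range(3):
            # non: isolated A base
            from amine_profiler.fixtures.bases import base_template
            tpl = base_template("A")
            cohort.append(Structure(
                [make_atom(k, k[0], v, resname="A") for k, v in tpl.items()],
                entry_id=f"NON{i}"))
        cohort.append(make_pair("wc_gc"))
        cohort.append(make_helix("GCGC", entry_id="HLX4"))
        cohort.append(make_pair("sheared_ga"))
        cohort.append(make_pair("trans_aa_hoogsteen"))
        res = pipeline.run_survey([(s, None) for s in cohort])
        med = res.records.groupby("klass")[["sasa", "rho1"]].median()
        assert med.loc["non", "sasa"] > med.loc["single", "sasa"]
        assert med.loc["non", "rho1"] < med.loc["single", "rho1"] \
            or med.loc["non", "sasa"] > med.loc["dual", "sasa"]
        assert med.loc["dual", "rho1"] >= med.loc["non", "rho1"]
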