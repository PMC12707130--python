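"""H-bond detection, donor classification and acceptor-pair extraction."""

import numpy as np
import pytest
from conftest import make_atom, random_structure

from amine_profiler import hbonds
from amine_profiler.errors import ContractViolation
from amine_profiler.fixtures import make_geometry_probe, make_pair
from amine_profiler.fixtures.bases import base_template, amine_h_positions
from amine_profiler.geometry import rotation_about_axis
from amine_profiler.structure import Structure, protonate_amines

CRIT = hbonds.HBondCriteria()


def probe_site(structure, chain="A"):
    sites, _ = protonate_amines(structure, target_chains=[chain])
    assert len(sites) == 1
    return sites[0]


def base_with_acceptors(offsets, acceptor_name="O2", acceptor_res="U"):
    """A lone G plus acceptor atoms at given offsets from its amine N."""
    coords = base_template("G")
    atoms = [make_atom(k, k[0], v) for k, v in coords.items()]
    n = coords["N2"]
    for i, off in enumerate(offsets, start=1):
        atoms.append(make_atom(acceptor_name, "O", n + np.asarray(off, float),
                               chain="B", resnum=i, resname=acceptor_res))
    return Structure(atoms, entry_id="TST")


class TestCandidates:
    def test_prescreen_radius_gate(self):
        st = base_with_acceptors([[4.0, 0, 0], [4.2, 0, 0]])
        cands = hbonds.find_candidates(probe_site(st), st, CRIT)
        assert [c.residue_number for c in cands] == [1]

    def test_parent_base_excluded_sugar_kept(self):
        coords = base_template("G")
        atoms = [make_atom(k, k[0], v) for k, v in coords.items()]
        # parent O6 sits well within 4.1 A of N2's surroundings only if moved
        atoms.append(make_atom("O2'", "O", coords["N2"] + [2.5, 0, 0]))
        st = Structure(atoms)
        names = {c.atom_name for c in hbonds.find_candidates(probe_site(st), st, CRIT)}
        assert "O2'" in names          # parent sugar atom is a candidate
        assert "O6" not in names and "N3" not in names  # parent base excluded

    def test_exclude_parent_residue_toggle(self):
        coords = base_template("G")
        atoms = [make_atom(k, k[0], v) for k, v in coords.items()]
        atoms.append(make_atom("O2'", "O", coords["N2"] + [2.5, 0, 0]))
        st = Structure(atoms)
        cands = hbonds.find_candidates(probe_site(st), st, CRIT,
                                       exclude_parent_residue=True)
        assert cands == []

    def test_nonpolymer_and_unknown_excluded(self):
        coords = base_template("G")
        atoms = [make_atom(k, k[0], v) for k, v in coords.items()]
        n = coords["N2"]
        atoms.append(make_atom("O", "O", n + [3.0, 0, 0], chain="W", resnum=1,
                               resname="HOH", is_polymer=False))
        atoms.append(make_atom("O1", "O", n + [3.0, 0.5, 0], chain="L", resnum=1,
                               resname="SAM"))
        st = Structure(atoms)
        assert hbonds.find_candidates(probe_site(st), st, CRIT) == []


class TestMeasure:
    def test_collinear_geometry(self):
        st = base_with_acceptors([])
        site = probe_site(st)
        h = site.h_positions[0]
        direction = (h - site.n_position) / np.linalg.norm(h - site.n_position)
        acc = h + 2.0 * direction
        (d0, a0), _ = hbonds.measure(site, acc)
        assert abs(d0 - 2.0) < 1e-9 and abs(a0 - 180.0) < 1e-9

    def test_angle_gate_fails_near_zero_angle(self):
        st = base_with_acceptors([])
        site = probe_site(st)
        h = site.h_positions[0]
        acc = site.n_position + 1.3 * (site.n_position - h)  # behind the N
        (d0, a0), _ = hbonds.measure(site, acc)
        assert a0 < 90.0  # far from passing regardless of distance

    def test_rigid_motion_invariance(self):
        st = base_with_acceptors([[2.4, 0.8, 0.3]])
        site = probe_site(st)
        acc = st.atoms[-1].position
        before = hbonds.measure(site, acc)
        R = rotation_about_axis([1, 2, 3], 73.0)
        t = np.array([5.0, -2.0, 9.0])
        moved = Structure([make_atom(a.atom_name, a.element, R @ a.position + t,
                                     chain=a.chain, resnum=a.residue_number,
                                     resname=a.residue_name) for a in st.atoms])
        site2 = probe_site(moved)
        after = hbonds.measure(site2, R @ acc + t)
        for (d1, a1), (d2, a2) in zip(before, after):
            assert abs(d1 - d2) < 1e-9 and abs(a1 - a2) < 1e-9


class TestClassification:
    @pytest.mark.parametrize("scenario,klass", [
        (1, "single"), (3, "single"), (4, "single"), (5, "dual"), (7, "dual"),
    ])
    def test_scenarios(self, scenario, klass):
        st = make_geometry_probe(scenario=scenario)
        site = probe_site(st)
        cl = hbonds.classify(site, hbonds.evaluate_amine(site, st, CRIT))
        assert cl.klass == klass and cl.scenario == scenario

    def test_no_candidates_is_non(self):
        st = base_with_acceptors([])
        site = probe_site(st)
        cl = hbonds.classify(site, hbonds.evaluate_amine(site, st, CRIT))
        assert cl.klass == "non" and cl.scenario is None

    def test_monotone_under_looser_criteria(self):
        rank = {"non": 0, "single": 1, "dual": 2}
        loose = hbonds.HBondCriteria(prescreen_radius=4.1,
                                     max_h_acceptor_distance=2.8,
                                     min_nha_angle=120.0)
        for seed in range(6):
            st = random_structure(seed, n_residues=12)
            sites, _ = protonate_amines(st)
            for site in sites:
                tight_cl = hbonds.classify(
                    site, hbonds.evaluate_amine(site, st, CRIT))
                loose_cl = hbonds.classify(
                    site, hbonds.evaluate_amine(site, st, loose))
                assert rank[loose_cl.klass] >= rank[tight_cl.klass]

    def test_spatial_index_matches_brute_force(self):
        for seed in range(5):
            st = random_structure(seed)
            sites, _ = protonate_amines(st)
            fast = hbonds.classify_structure(st, sites, CRIT)
            slow = hbonds.classify_structure(st, sites, CRIT, brute_force=True)
            for f, s in zip(fast, slow):
                assert (f.klass, f.scenario) == (s.klass, s.scenario)

    def test_invariant_under_atom_permutation(self):
        st = random_structure(3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(st.atoms))
        shuffled = Structure([st.atoms[i] for i in perm], st.entry_id)
        a = {c.amine.residue_key: (c.klass, c.scenario)
             for c in hbonds.classify_structure(
                 st, protonate_amines(st)[0], CRIT)}
        b = {c.amine.residue_key: (c.klass, c.scenario)
             for c in hbonds.classify_structure(
                 shuffled, protonate_amines(shuffled)[0], CRIT)}
        assert a == b


class TestAcceptorPair:
    def test_greatest_angle_wins_per_hydrogen(self):
        st = make_geometry_probe(bonds=[(0, 2.0, 165.0), (0, 2.2, 150.0),
                                        (1, 2.0, 160.0)])
        site = probe_site(st)
        cl = hbonds.classify(site, hbonds.evaluate_amine(site, st, CRIT))
        assert cl.klass == "dual"
        angles = sorted(round(g[1]) for g in cl.pair_geometry)
        assert angles == [160, 165]  # the 150-degree bifurcation is dropped

    def test_collision_fallback_keeps_two_acceptors(self, sheared_ga):
        # synthetic observations: H1 bifurcated to acc1 (160) and acc2 (150),
        # H0 only reaches acc1 -> pair must be {acc1, acc2}
        site = probe_site(make_geometry_probe(scenario=5))
        acc1 = make_atom("O2", "O", [0, 0, 0], chain="B", resnum=1, resname="U")
        acc2 = make_atom("O2", "O", [5, 0, 0], chain="B", resnum=2, resname="U")
        from amine_profiler.chem import generalize_acceptor
        lab = generalize_acceptor("U", "O2")
        obs = [
            hbonds.HBondObservation(site, 0, acc1, lab, 2.0, 155.0, True),
            hbonds.HBondObservation(site, 1, acc1, lab, 2.0, 160.0, True),
            hbonds.HBondObservation(site, 1, acc2, lab, 2.2, 150.0, True),
        ]
        labels, same_res, atoms, _ = hbonds.acceptor_pair(site, obs)
        assert {a.residue_number for a in atoms} == {1, 2}

    def test_canonical_ordering_deterministic(self):
        site = probe_site(make_geometry_probe(scenario=5))
        accs = [make_atom("O2", "O", [i, 0, 0], chain="B", resnum=i, resname="U")
                for i in (1, 2)]
        from amine_profiler.chem import generalize_acceptor
        lab = generalize_acceptor("U", "O2")
        obs = [hbonds.HBondObservation(site, 0, accs[0], lab, 2.0, 150.0, True),
               hbonds.HBondObservation(site, 1, accs[1], lab, 2.0, 150.0, True)]
        obs_rev = [obs[1], obs[0]]
        a = hbonds.acceptor_pair(site, obs)
        b = hbonds.acceptor_pair(site, obs_rev)
        assert [x.residue_number for x in a[2]] == [x.residue_number for x in b[2]]

    def test_non_dual_raises(self):
        st = make_geometry_probe(scenario=1)
        site = probe_site(st)
        passing = [o for o in hbonds.evaluate_amine(site, st, CRIT) if o.passes]
        with pytest.raises(ContractViolation):
            hbonds.acceptor_pair(site, passing)

    def test_sheared_ga_pair_identity(self, sheared_ga):
        sites, _ = protonate_amines(sheared_ga)
        cls = hbonds.classify_structure(sheared_ga, sites)
        a_cl = next(c for c in cls if c.amine.base_type == "A")
        assert a_cl.klass == "dual"
        assert tuple(str(l) for l in a_cl.acceptor_pair) == ("G(N3)", "N(O2')")
        assert a_cl.same_residue is True

    def test_trans_aa_pair_identity(self, trans_aa):
        sites, _ = protonate_amines(trans_aa)
        cls = hbonds.classify_structure(trans_aa, sites)
        a1 = next(c for c in cls if c.amine.residue_key == ("A", 1, ""))
        assert a1.klass == "dual"
        assert tuple(str(l) for l in a1.acceptor_pair) == ("A(N7)", "N(NPO)")
        assert a1.same_residue is True


class TestCanonicalGC:
    def test_helix_pairs_detected(self, helix):
        sites, _ = protonate_amines(helix)
        cls = hbonds.classify_structure(helix, sites)
        assert len(hbonds.detect_canonical_gc(helix, cls)) == 6

    def test_broken_bond_not_detected(self, wc_gc):
        sites, _ = protonate_amines(wc_gc)
        cls = hbonds.classify_structure(wc_gc, sites)
        assert len(hbonds.detect_canonical_gc(wc_gc, cls)) == 1
        # displace the G O6 acceptor so the C(N4)->G(O6) bond breaks
        broken = wc_gc.copy()
        for a in broken.atoms:
            if a.atom_name == "O6":
                a.position = a.position + np.array([0.0, 0.0, 3.0])
        sites2, _ = protonate_amines(broken)
        cls2 = hbonds.classify_structure(broken, sites2)
        assert hbonds.detect_canonical_gc(broken, cls2) == set()

    def test_au_never_reported(self):
        from amine_profiler.fixtures import make_helix
        au = make_helix("AAAA", entry_id="AUHX")
        sites, _ = protonate_amines(au)
        cls = hbonds.classify_structure(au, sites)
        assert hbonds.detect_canonical_gc(au, cls) == set()


class TestGeometryHistogram:
    def test_single_pair_one_count(self):
        st = make_geometry_probe(scenario=1)
        site = probe_site(st)
        cls = [hbonds.classify(site, hbonds.evaluate_amine(site, st, CRIT))]
        counts, d_edges, a_edges = hbonds.geometry_histogram(cls)
        assert counts.sum() == 1
        di = np.searchsorted(d_edges, 2.0, side="right") - 1
        ai = np.searchsorted(a_edges, 160.0, side="right") - 1
        assert counts[di, ai] == 1

    def test_canonical_exclusions_applied(self, wc_gc):
        sites, _ = protonate_amines(wc_gc)
        cls = hbonds.classify_structure(wc_gc, sites)
        excluded, _, _ = hbonds.geometry_histogram(cls)
        kept, _, _ = hbonds.geometry_histogram(cls, exclusions=frozenset())
        # all three canonical-pair measurements (G-C(O2), G-C(N3),
        # C-G(O6)) vanish from the plot but not from classification
        assert excluded.sum() == 0
        assert kept.sum() == 3
        assert all(c.klass == "single" for c in cls)

    def test_sum_equals_non_excluded_pairs(self):
        st = random_structure(11, n_residues=10)
        sites, _ = protonate_amines(st)
        cls = hbonds.classify_structure(st, sites)
        n_pairs = sum(len({(o.acceptor.chain, o.acceptor.residue_number,
                            o.acceptor.icode, o.acceptor.atom_name)
                           for o in c.observations}) for c in cls)
        counts, _, _ = hbonds.geometry_histogram(cls, exclusions=frozenset())
        assert counts.sum() == n_pairs
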