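"""Interface decomposition, IP/HB detection, surfaces, IP networks."""

import numpy as np
import pytest

from oligoflex import interfaces as ifc
from oligoflex import synthetic as syn
from oligoflex.structure_io import Atom, Structure


class TestDefineInterfaces:
    def test_three_specs_six_distinct_pairs(self, tetramer):
        specs = ifc.define_interfaces(tetramer)
        assert set(specs) == {"m", "d", "c"}
        assert specs["m"].pairs == (("A", "B"), ("D", "C"))
        all_pairs = {frozenset(p) for s in specs.values() for p in s.pairs}
        assert len(all_pairs) == 6

    def test_d_c_assignment_configurable(self, tetramer):
        specs = ifc.define_interfaces(tetramer, d_pairs=(("A", "C"), ("B", "D")))
        assert {frozenset(p) for p in specs["d"].pairs} == {
            frozenset({"A", "C"}),
            frozenset({"B", "D"}),
        }
        assert {frozenset(p) for p in specs["c"].pairs} == {
            frozenset({"A", "D"}),
            frozenset({"B", "C"}),
        }

    def test_wrong_chain_count_errors(self, helix_chain):
        with pytest.raises(ValueError):
            ifc.define_interfaces(helix_chain)


def brute_force_ion_pairs(structure, coords, interface, cutoff=4.0):
    """O(N^2) oracle over all basic-N x acidic-O atom pairs."""
    found = set()
    for i, a in enumerate(structure.atoms):
        if a.name not in ifc.BASIC_SIDECHAIN_N.get(a.resname, ()):
            continue
        for j, b in enumerate(structure.atoms):
            if b.name not in ifc.ACIDIC_SIDECHAIN_O.get(b.resname, ()):
                continue
            if not interface.spans(a.chain, b.chain):
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                found.add((a.chain, a.resid, b.chain, b.resid))
    return found


class TestIonPairs:
    def test_designed_pairs_found(self, dimer_with_contacts, ab_interface):
        structure, contacts = dimer_with_contacts
        ips = ifc.detect_ion_pairs(structure.coords, structure, ab_interface)
        designed = {(c.res_a[0], c.res_a[1], c.res_b[0], c.res_b[1]) for c in contacts if c.kind == "IP"}
        assert {c.key for c in ips} == designed
        assert len(ips) == 3

    def test_separated_chains_none(self, dimer_with_contacts, ab_interface):
        structure, _ = dimer_with_contacts
        coords = structure.coords.copy()
        b_mask = np.array([a.chain == "B" for a in structure.atoms])
        coords[b_mask] += np.array([100.0, 0, 0])
        assert ifc.detect_ion_pairs(coords, structure, ab_interface) == []

    def test_matches_brute_force_on_decoy(self, ab_interface):
        rng = np.random.default_rng(8)
        atoms, coords = [], []
        resid = 0
        for chain in "AB":
            for _ in range(60):
                resid += 1
                resname = ["ARG", "LYS", "ASP", "GLU", "GLY"][rng.integers(5)]
                base = rng.random(3) * 25.0
                atoms.append(Atom("CA", "C", resname, resid, chain))
                coords.append(base)
                for name in {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",),
                             "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "GLY": ()}[resname]:
                    atoms.append(Atom(name, name[0], resname, resid, chain))
                    coords.append(base + rng.standard_normal(3))
        s = Structure(atoms, np.array(coords))
        ips = ifc.detect_ion_pairs(s.coords, s, ab_interface)
        assert {c.key for c in ips} == brute_force_ion_pairs(s, s.coords, ab_interface)

    def test_rigid_motion_invariant(self, dimer_with_contacts, ab_interface):
        from scipy.spatial.transform import Rotation

        structure, _ = dimer_with_contacts
        R = Rotation.from_euler("xyz", [0.5, 1.0, -0.3]).as_matrix()
        moved = structure.coords @ R.T + 33.0
        a = {c.key for c in ifc.detect_ion_pairs(structure.coords, structure, ab_interface)}
        b = {c.key for c in ifc.detect_ion_pairs(moved, structure, ab_interface)}
        assert a == b


class TestHydrogenBonds:
    def _no_pair(self, distance, with_h=False, angle=165.0):
        """Backbone N(A)...O(B) geometry with controllable distance/angle."""
        atoms = [
            Atom("CA", "C", "GLY", 1, "A"),
            Atom("N", "N", "GLY", 1, "A"),
            Atom("O", "O", "GLY", 1, "B"),
            Atom("C", "C", "GLY", 1, "B"),
        ]
        # antecedent CA placed so that angle(CA, N, O) = angle
        theta = np.radians(angle)
        coords = [
            [np.cos(theta) * 1.5, np.sin(theta) * 1.5, 0.0],
            [0.0, 0.0, 0.0],
            [distance, 0.0, 0.0],
            [distance + 1.2, 0.0, 0.0],
        ]
        if with_h:
            atoms.append(Atom("H", "H", "GLY", 1, "A"))
            coords.append([1.0, 0.0, 0.0])
        return Structure(atoms, np.array(coords))

    def test_good_geometry_accepted(self, ab_interface):
        s = self._no_pair(2.9)
        assert len(ifc.detect_hydrogen_bonds(s.coords, s, ab_interface)) == 1

    def test_long_distance_rejected(self, ab_interface):
        s = self._no_pair(4.2)
        assert ifc.detect_hydrogen_bonds(s.coords, s, ab_interface) == []

    def test_bad_proxy_angle_rejected(self, ab_interface):
        s = self._no_pair(2.9, angle=80.0)
        assert ifc.detect_hydrogen_bonds(s.coords, s, ab_interface) == []

    def test_explicit_hydrogen_angle_used(self, ab_interface):
        s = self._no_pair(2.9, with_h=True)  # H on the N-O axis: 180 deg
        assert len(ifc.detect_hydrogen_bonds(s.coords, s, ab_interface)) == 1

    def test_designed_hb_contacts_detected(self, dimer_with_contacts, ab_interface):
        structure, contacts = dimer_with_contacts
        hbs = {c.key for c in ifc.detect_hydrogen_bonds(structure.coords, structure, ab_interface)}
        designed = {(c.res_a[0], c.res_a[1], c.res_b[0], c.res_b[1]) for c in contacts if c.kind == "HB"}
        assert designed <= hbs  # designed salt bridges also satisfy HB geometry


class TestContactTimelines:
    def test_static_occupancy_one(self, dimer_with_contacts, ab_interface):
        structure, contacts = dimer_with_contacts
        traj, _ = syn.make_contact_telegraph(
            structure, [c for c in contacts if c.kind == "IP"], (1.0, 0.0), 50, 4.0, seed=1
        )
        tl = ifc.contact_timelines(traj, ab_interface, "ip")
        assert tl.distinct_pairs() == 3
        assert all(v == 1.0 for v in tl.occupancy.values())
        assert tl.mean_count == 3.0

    def test_half_occupancy(self, dimer_with_contacts, ab_interface):
        structure, contacts = dimer_with_contacts
        ips = [c for c in contacts if c.kind == "IP"]
        traj, bound = syn.make_contact_telegraph(structure, ips, (0.5, 0.5), 3000, 4.0, seed=2)
        tl = ifc.contact_timelines(traj, ab_interface, "ip")
        for j, c in enumerate(ips):
            key = (c.res_a[0], c.res_a[1], c.res_b[0], c.res_b[1])
            assert tl.occupancy[key] == pytest.approx(bound[:, j].mean())
            assert tl.occupancy[key] == pytest.approx(0.5, abs=0.05)

    def test_telegraph_two_to_one_rates(self, dimer_with_contacts, ab_interface):
        structure, contacts = dimer_with_contacts
        ips = [c for c in contacts if c.kind == "IP"]
        traj, _ = syn.make_contact_telegraph(structure, ips, (0.2, 0.1), 4000, 4.0, seed=3)
        tl = ifc.contact_timelines(traj, ab_interface, "ip")
        # stationary occupancy 2/3, binomial-correlated bound: allow 3 sigma of
        # the effective sample size n/(2 tau) with tau ~ 1/(p_on+p_off)
        n_eff = 4000 * 0.3 / 2
        tol = 3 * np.sqrt((2 / 3) * (1 / 3) / n_eff)
        for occ in tl.occupancy.values():
            assert occ == pytest.approx(2.0 / 3.0, abs=tol)

    def test_per_frame_count_mean_is_sum_of_occupancies(self, dimer_with_contacts, ab_interface):
        structure, contacts = dimer_with_contacts
        ips = [c for c in contacts if c.kind == "IP"]
        traj, _ = syn.make_contact_telegraph(structure, ips, (0.3, 0.2), 2000, 4.0, seed=4)
        tl = ifc.contact_timelines(traj, ab_interface, "ip")
        assert tl.mean_count == pytest.approx(sum(tl.occupancy.values()), rel=1e-9)


class TestSurfaceClassification:
    def _two_slabs(self, el_a, el_b):
        """Two facing 3x3 atom slabs of the given elements, 4 Å apart."""
        atoms, coords = [], []
        rid = 0
        for chain, el, x in (("A", el_a, 0.0), ("B", el_b, 4.0)):
            for y in range(3):
                for z in range(3):
                    rid += 1
                    atoms.append(Atom("X", el, "UNK", rid, chain))
                    coords.append([x, y * 3.0, z * 3.0])
        return Structure(atoms, np.array(coords))

    def test_all_carbon_interface_is_hydrophobic(self, ab_interface):
        s = self._two_slabs("C", "C")
        surf = ifc.classify_interface_surface(s.coords, s, ab_interface)
        assert surf.fractions[0] == pytest.approx(1.0)
        assert sum(surf.fractions) == pytest.approx(1.0, abs=1e-9)

    def test_carbon_vs_oxygen_is_mixed(self, ab_interface):
        s = self._two_slabs("C", "O")
        surf = ifc.classify_interface_surface(s.coords, s, ab_interface)
        assert surf.fractions[2] == pytest.approx(1.0)

    def test_fractions_sum_to_one_on_real_interface(self, dimer_with_contacts, ab_interface):
        structure, _ = dimer_with_contacts
        surf = ifc.classify_interface_surface(structure.coords, structure, ab_interface)
        assert sum(surf.fractions) == pytest.approx(1.0, abs=1e-9)
        assert all(f >= 0 for f in surf.fractions)

    def test_empty_interface_errors(self, ab_interface):
        s = self._two_slabs("C", "C")
        coords = s.coords.copy()
        coords[9:] += np.array([500.0, 0, 0])
        with pytest.raises(ValueError, match="empty"):
            ifc.classify_interface_surface(coords, s, ab_interface)


class TestIPNetwork:
    def _timeline(self, pairs, n_frames=100):
        """Hand-built timeline set: pairs = {(resA, resB): occupancy}."""
        presence, contacts = {}, {}
        spec = ifc.InterfaceSpec("m", (("A", "B"), ("D", "C")))
        for (ra, rb), occ in pairs.items():
            c = ifc.Contact("IP", "A", ra, "ARG", "B", rb, "GLU")
            pres = np.zeros(n_frames, dtype=bool)
            pres[: int(round(occ * n_frames))] = True
            presence[c.key] = pres
            contacts[c.key] = c
        counts = np.sum(np.array(list(presence.values())), axis=0)
        return ifc.ContactTimelineSet("IP", spec, np.arange(n_frames) * 4.0, counts, presence, contacts)

    def test_single_persistent_pair(self):
        g = ifc.build_ip_network([self._timeline({(1, 2): 1.0})])
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 1
        (u, v, data), = g.edges(data=True)
        assert data["weight"] == 1.0
        assert g.nodes[u]["weight"] == 1.0

    def test_two_partner_weights(self):
        g = ifc.build_ip_network([self._timeline({(1, 2): 0.6, (1, 5): 0.4})])
        node = "A:1:ARG"
        assert g.degree[node] == 2
        assert g.nodes[node]["weight"] >= 0.6
        weights = sorted(d["weight"] for _, _, d in g.edges(data=True))
        assert weights == pytest.approx([0.4, 0.6])

    def test_node_weight_bounds_incident_edges(self):
        g = ifc.build_ip_network([self._timeline({(1, 2): 0.5, (3, 2): 0.3, (3, 6): 0.7})])
        for n in g.nodes:
            incident = [d["weight"] for _, _, d in g.edges(n, data=True)]
            assert g.nodes[n]["weight"] >= max(incident) - 1e-12

    def test_degree_distribution_matches_construction(self):
        pairs = {(1, 2): 0.9, (1, 5): 0.5, (1, 8): 0.2, (3, 2): 0.4}
        g = ifc.build_ip_network([self._timeline(pairs)])
        assert g.degree["A:1:ARG"] == 3
        assert g.degree["B:2:GLU"] == 2
        assert g.degree["A:3:ARG"] == 1


class TestHydrophobicCensus:
    def test_no_cross_chain_hydrophobics(self, dimer_with_contacts, ab_interface):
        structure, _ = dimer_with_contacts  # GLY/ARG/GLU/SER only
        census = ifc.hydrophobic_proximity_census(structure, ab_interface)
        assert census == {"A": 0, "B": 0}

    def test_designed_patch_counted(self, ab_interface):
        structure, _ = syn.make_interface_dimer(n_ip=0, n_hb=0, n_phobic=4, phobic_distance=4.0)
        census = ifc.hydrophobic_proximity_census(structure, ab_interface, cutoff=4.5)
        assert census == {"A": 4, "B": 4}

    def test_matches_brute_force(self, ab_interface):
        structure, _ = syn.make_interface_dimer(n_ip=1, n_hb=1, n_phobic=3, seed=2)
        census = ifc.hydrophobic_proximity_census(structure, ab_interface, cutoff=4.5)
        sc = structure.select("sidechain-heavy")
        phob = [i for i in sc if structure.atoms[i].resname in ifc.HYDROPHOBIC_RESNAMES]
        expected = {"A": set(), "B": set()}
        for i in phob:
            for j in phob:
                ai, aj = structure.atoms[i], structure.atoms[j]
                if ai.chain != aj.chain and np.linalg.norm(structure.coords[i] - structure.coords[j]) <= 4.5:
                    expected[ai.chain].add(ai.resid)
        assert census == {c: len(v) for c, v in expected.items()}
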