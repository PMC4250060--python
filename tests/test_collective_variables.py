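"""Collective variables: Rg, superposition/RMSD, native contacts, torsions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oligoflex import collective_variables as cv
from oligoflex import synthetic as syn
from oligoflex.structure_io import Structure, Trajectory


def brute_force_rotation_grid_rmsd(mobile, reference, n_grid=40):
    """Independent oracle: minimize RMSD over a fine rotation grid."""
    mobile = mobile - mobile.mean(axis=0)
    reference = reference - reference.mean(axis=0)
    best = np.inf
    angles = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    # coarse Euler grid is enough to bracket the optimum for the tolerance used
    for a in angles:
        for b in np.linspace(0, np.pi, n_grid // 2):
            for c in angles:
                R = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                r = np.sqrt(np.mean(np.sum((mobile @ R.T - reference) ** 2, axis=1)))
                if r < best:
                    best = r
    return best


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert cv.radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_unit_cube_corners(self):
        corners = np.array(
            [[x, y, z] for x in (-0.5, 0.5) for y in (-0.5, 0.5) for z in (-0.5, 0.5)]
        )
        assert cv.radius_of_gyration(corners) == pytest.approx(np.sqrt(0.75), abs=1e-12)

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError):
            cv.radius_of_gyration(np.zeros((5, 3)), np.array([], dtype=int))

    def test_translation_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((30, 3))
        assert cv.radius_of_gyration(x + 17.0) == pytest.approx(cv.radius_of_gyration(x))


class TestSuperpose:
    def test_identity(self):
        x = np.random.default_rng(1).standard_normal((10, 3))
        t = cv.superpose(x, x)
        assert t.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-8)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(2)
        ref = rng.standard_normal((12, 3)) * 4
        R = Rotation.from_rotvec(np.radians(37.0) * np.array([1.0, 2.0, 2.0]) / 3.0).as_matrix()
        mob = ref @ R.T + np.array([5.0, -3.0, 2.0])
        assert cv.superpose(mob, ref).rmsd == pytest.approx(0.0, abs=1e-8)

    def test_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((10, 3)) * 3
        b = rng.standard_normal((10, 3)) * 3
        exact = cv.superpose(a, b).rmsd
        grid = brute_force_rotation_grid_rmsd(a, b, n_grid=40)
        assert exact <= grid + 1e-9  # optimal fit beats any grid rotation
        assert grid - exact < 0.05  # and the grid brackets it closely

    def test_too_few_or_collinear_points(self):
        with pytest.raises(ValueError):
            cv.superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError, match="degenerate"):
            cv.superpose(line, line)

    def test_batch_equals_scalar_path(self):
        rng = np.random.default_rng(4)
        ref = rng.standard_normal((8, 3)) * 2
        frames = rng.standard_normal((25, 8, 3)) * 2
        _, batch = cv.superpose_batch(frames, ref)
        single = np.array([cv.superpose(f, ref).rmsd for f in frames])
        np.testing.assert_allclose(batch, single, atol=1e-9)


class TestRMSDSeries:
    def test_copies_of_reference_are_zero(self, helix_chain):
        frames = np.tile(helix_chain.coords, (5, 1, 1))
        traj = Trajectory(helix_chain, frames, dt=1.0)
        series = cv.rmsd_series(traj, helix_chain, "ca")
        np.testing.assert_allclose(series.values, 0.0, atol=1e-8)

    def test_rigid_translation_removed(self, helix_chain):
        frames = np.tile(helix_chain.coords, (3, 1, 1))
        frames[1] += 5.0
        traj = Trajectory(helix_chain, frames, dt=1.0)
        series = cv.rmsd_series(traj, helix_chain, "ca")
        assert series.values[1] == pytest.approx(0.0, abs=1e-8)

    def test_hand_built_frame(self):
        atoms, coords = syn.make_chain(["GLY"] * 4, "A")
        ref = Structure(atoms, coords)
        rng = np.random.default_rng(5)
        frame = coords + rng.standard_normal(coords.shape) * 0.3
        traj = Trajectory(ref, frame[None], dt=1.0)
        series = cv.rmsd_series(traj, ref, "ca")
        ca = ref.select("ca")
        oracle = brute_force_rotation_grid_rmsd(frame[ca], coords[ca], n_grid=60)
        assert series.values[0] <= oracle + 1e-9
        assert oracle - series.values[0] < 0.05


class TestContactReference:
    def test_cutoff_and_separation_rules(self):
        # two CB atoms 4.9 Å apart; vary sequence separation
        atoms, coords = syn.make_chain(["ALA"] * 8, "A")
        s = Structure(atoms, coords)
        names = [(a.resid, a.name) for a in s.atoms]
        i1 = names.index((1, "CB"))
        i6 = names.index((6, "CB"))
        i3 = names.index((3, "CB"))
        s.coords[i6] = s.coords[i1] + [4.9, 0, 0]
        s.coords[i3] = s.coords[i1] + [0, 4.9, 0]
        ref = cv.build_contact_reference(s, cutoff=5.0, min_sep=3)
        sc = list(ref.atom_indices)
        k1, k6, k3 = sc.index(i1), sc.index(i6), sc.index(i3)
        assert k6 in ref.partners[k1] and k1 in ref.partners[k6]  # 5 apart in sequence
        assert k3 not in ref.partners[k1]  # only 2 apart in sequence

    def test_matches_brute_force_double_loop(self, helix_chain):
        ref = cv.build_contact_reference(helix_chain, cutoff=5.0, min_sep=3)
        idx = ref.atom_indices
        coords = helix_chain.coords[idx]
        resids = [helix_chain.atoms[i].resid for i in idx]
        for k in range(len(idx)):
            expected = sorted(
                j
                for j in range(len(idx))
                if j != k
                and abs(resids[j] - resids[k]) > 3
                and np.linalg.norm(coords[j] - coords[k]) <= 5.0
            )
            assert ref.partners[k].tolist() == expected

    def test_q_is_one_on_reference(self, helix_chain):
        ref = cv.build_contact_reference(helix_chain)
        assert np.array_equal(
            ref.n_counts, [len(p) for p in ref.partners]
        )
        assert cv.fraction_native_contacts(helix_chain.coords, ref) == 1.0

    def test_q_zero_when_exploded(self, helix_chain):
        ref = cv.build_contact_reference(helix_chain)
        exploded = helix_chain.coords * 50.0
        assert cv.fraction_native_contacts(exploded, ref) == 0.0

    def test_q_rotation_invariant(self, helix_chain):
        ref = cv.build_contact_reference(helix_chain)
        R = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        rotated = helix_chain.coords @ R.T + 4.0
        assert cv.fraction_native_contacts(rotated, ref) == pytest.approx(1.0)

    def test_empty_reference_errors(self):
        atoms, coords = syn.make_chain(["GLY"] * 6, "A")
        s = Structure(atoms, coords)
        ref = cv.build_contact_reference(s)
        with pytest.raises(ValueError, match="empty"):
            cv.fraction_native_contacts(s.coords, ref)


class TestNativeTorsions:
    def test_reference_is_one(self, helix_chain):
        ref = cv.build_torsion_reference(helix_chain)
        assert cv.fraction_native_torsions(helix_chain.coords, ref) == 1.0

    def test_invalid_tolerance(self, helix_chain):
        with pytest.raises(ValueError):
            cv.build_torsion_reference(helix_chain, tolerance=200.0)

    def test_half_perturbed_gives_half(self, helix_chain):
        ref = cv.build_torsion_reference(helix_chain, tolerance=60.0)
        n = len(ref.torsions)
        half = n // 2
        shifted = cv.TorsionReference(
            ref.torsions,
            np.concatenate([ref.native[:half] + 180.0, ref.native[half:]]),
            60.0,
        )
        a = cv.fraction_native_torsions(helix_chain.coords, shifted)
        assert a == pytest.approx((n - half) / n)

    def test_rotation_invariant(self, helix_chain):
        ref = cv.build_torsion_reference(helix_chain)
        R = Rotation.from_euler("zxz", [1.0, 0.4, 2.2]).as_matrix()
        rotated = helix_chain.coords @ R.T - 11.0
        assert cv.fraction_native_torsions(rotated, ref) == pytest.approx(1.0)

    def test_circular_deviation_uses_shorter_arc(self):
        assert cv.circular_deviation(179.0, -179.0) == pytest.approx(2.0)
        assert cv.circular_deviation(-170.0, 170.0) == pytest.approx(20.0)


class TestPocketRMSD:
    def test_two_state_hopping_alternates(self, helix_chain):
        apo = helix_chain
        rng = np.random.default_rng(9)
        d = rng.standard_normal(apo.coords.shape)
        d *= 4.0 / np.sqrt(np.mean(np.sum(d**2, axis=1)))
        holo = apo.with_coords(apo.coords + d)
        frames = np.array([apo.coords, holo.coords, apo.coords, holo.coords])
        traj = Trajectory(apo, frames, dt=1.0)
        s_apo, s_holo = cv.pocket_rmsd_to_references(traj, apo, holo, "backbone and resid 5-15")
        assert s_apo.values[0] == pytest.approx(0.0, abs=1e-6)
        assert s_holo.values[1] == pytest.approx(0.0, abs=1e-6)
        # symmetry: frame==holo gives apo-RMSD equal to apo<->holo pocket distance
        assert s_apo.values[1] == pytest.approx(s_apo.values[3])
        assert s_apo.values[1] > 1.0

    def test_unmappable_residues_listed(self, helix_chain, tetramer):
        traj = Trajectory(helix_chain, helix_chain.coords[None], dt=1.0)
        with pytest.raises(ValueError, match="not mappable"):
            cv.pocket_rmsd_to_references(traj, helix_chain, tetramer.subset(tetramer.select("chain B")), "backbone")
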