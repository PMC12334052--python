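"""Trajectory metrics against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from presyn.synth import gen_toy_trajectory
from presyn.trajectory import (
    KB_KJ_PER_MOL_K,
    StructureTrajectory,
    count_hydrogen_bonds,
    free_energy_landscape,
    kabsch_align,
    pca_modes,
    radius_of_gyration,
    rmsd_series,
    rmsf_per_atom,
    sasa,
)


def random_points(n, seed=0, scale=5.0):
    return np.random.default_rng(seed).normal(scale=scale, size=(n, 3))


class TestKabsch:
    def test_identity_superposition(self):
        pts = random_points(10, 1)
        rot, t, rmsd = kabsch_align(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_is_removed(self):
        pts = random_points(12, 2)
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot90.T + np.array([1.0, -2.0, 3.0])
        _, _, rmsd = kabsch_align(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_is_proper(self):
        # near-planar cloud that tempts a reflection solution
        pts = random_points(8, 3)
        pts[:, 2] *= 1e-3
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        rot, _, _ = kabsch_align(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_rotation_grid_search(self):
        """Brute-force minimisation over a fine rotation grid agrees."""
        ref = random_points(5, 4, scale=2.0)
        rng = np.random.default_rng(5)
        mobile = ref + rng.normal(scale=0.3, size=ref.shape)
        _, _, rmsd = kabsch_align(mobile, ref)

        ref_c = ref - ref.mean(0)
        mob_c = mobile - mobile.mean(0)

        def cost(rot: Rotation) -> float:
            d = mob_c @ rot.as_matrix().T - ref_c
            return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

        grid_rng = np.random.default_rng(6)
        cands = Rotation.random(4000, rng=grid_rng)
        best_rot = min(cands, key=cost)
        for scale in (0.3, 0.1, 0.03, 0.01, 0.003):  # shrinking local grids
            perturb = Rotation.from_rotvec(
                grid_rng.normal(scale=scale, size=(2000, 3))
            )
            best_rot = min((p * best_rot for p in perturb), key=cost,
                           default=best_rot)
        best = cost(best_rot)
        assert rmsd <= best + 1e-9
        assert best - rmsd < 1e-3

    def test_degenerate_input_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_align(line, line)
        with pytest.raises(ValueError):
            kabsch_align(random_points(2, 0), random_points(2, 0))


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self):
        traj = gen_toy_trajectory(10, 5, per_atom_sigma=0.0, seed=0)
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-10)

    def test_rigid_body_motion_only_is_zero(self):
        base = random_points(15, 7)
        frames = [base]
        for ang in (10, 40, 90):
            rot = Rotation.from_euler("y", ang, degrees=True).as_matrix()
            frames.append(base @ rot.T + ang * 0.1)
        traj = StructureTrajectory(np.stack(frames))
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-9)

    def test_two_state_step_profile(self):
        shift = np.array([1.0, 0.0, 0.0])
        traj = gen_toy_trajectory(
            60, 200, per_atom_sigma=0.01, displacement_event=(100, shift), seed=1
        )
        series = rmsd_series(traj, reference_frame=0)
        # the rigid shift of *all* atoms is removed by superposition up to
        # jitter; use a half-shifted subset instead for a real step
        traj2 = gen_toy_trajectory(60, 200, per_atom_sigma=0.01, seed=2)
        coords = traj2.coords.copy()
        coords[100:, :30, :] += shift  # half the atoms move after frame 100
        stepped = StructureTrajectory(coords)
        s2 = rmsd_series(stepped)
        early, late = s2[:100].mean(), s2[100:].mean()
        # optimal fit splits a half-population unit shift into ~0.5 residual
        assert late - early == pytest.approx(0.5, rel=0.05)

    def test_empty_selection_rejected(self):
        traj = gen_toy_trajectory(5, 4, 0.1, seed=3)
        with pytest.raises(ValueError):
            rmsd_series(traj, selection=np.array([], dtype=int))


class TestRmsf:
    def test_static_is_zero(self):
        traj = gen_toy_trajectory(8, 10, 0.0, seed=0)
        np.testing.assert_allclose(rmsf_per_atom(traj), 0.0, atol=1e-12)

    def test_isotropic_jitter_moment(self):
        # many atoms so the 6 rigid-body DOF absorb a negligible share
        traj = gen_toy_trajectory(125, 2000, 0.1, seed=4)
        rmsf = rmsf_per_atom(traj)
        assert rmsf.mean() == pytest.approx(0.1 * np.sqrt(3), rel=0.05)

    def test_two_sigma_ratio(self):
        sigma = np.full(125, 0.05)
        sigma[0], sigma[1] = 0.1, 0.2
        traj = gen_toy_trajectory(125, 2000, sigma, seed=5)
        rmsf = rmsf_per_atom(traj)
        assert rmsf[1] / rmsf[0] == pytest.approx(2.0, rel=0.05)

    def test_single_frame_rejected(self):
        traj = gen_toy_trajectory(5, 2, 0.1, seed=6)
        traj.coords = traj.coords[:1]
        with pytest.raises(ValueError):
            rmsf_per_atom(traj)


class TestRadiusOfGyration:
    def test_coincident_atoms(self):
        assert radius_of_gyration(np.zeros((4, 3))) == 0.0

    def test_two_equal_masses(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(pts) == pytest.approx(1.0)

    def test_unit_square(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        assert radius_of_gyration(pts) == pytest.approx(np.sqrt(2) / 2, rel=1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((3, 3)), np.zeros(3))


class TestSasa:
    def test_single_sphere_closed_form(self):
        total, _ = sasa(np.zeros((1, 3)), np.array([1.5]), 1.4, 960)
        assert total == pytest.approx(4 * np.pi * 2.9**2, rel=0.01)

    def test_buried_atom_has_no_area(self):
        # centre atom caged by 26 neighbours on a dense shell
        shell = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) != (0, 0, 0):
                        shell.append([dx, dy, dz])
        coords = np.vstack([[0, 0, 0], 1.8 * np.asarray(shell, float)])
        radii = np.full(len(coords), 1.5)
        _, per_atom = sasa(coords, radii, 1.4, 192)
        assert per_atom[0] == pytest.approx(0.0, abs=1e-9)

    def test_coincident_atoms_total_one_sphere(self):
        coords = np.zeros((2, 3))
        radii = np.array([1.5, 1.5])
        total, per_atom = sasa(coords, radii, 1.4, 960)
        assert total == pytest.approx(4 * np.pi * 2.9**2, rel=0.01)

    def test_converges_with_more_sphere_points(self):
        coords = np.array([[0, 0, 0], [2.0, 0, 0], [0, 2.0, 0]], float)
        radii = np.full(3, 1.5)
        exact, _ = sasa(coords, radii, 1.4, 15360)
        err = [abs(sasa(coords, radii, 1.4, n)[0] - exact) for n in (92, 960)]
        assert err[1] < err[0]

    def test_point_count_floor(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), np.array([1.5]), 1.4, 50)


class TestHydrogenBonds:
    def test_inside_both_cutoffs_counts(self):
        # D at origin, H towards A, A at 2.8 A, angle ~0
        frame = np.array([[0, 0, 0], [1.0, 0, 0], [2.8, 0, 0]])
        n = count_hydrogen_bonds(frame, [0], [1], [2])
        assert n == 1

    def test_outside_distance_does_not_count(self):
        frame = np.array([[0, 0, 0], [1.0, 0, 0], [4.0, 0, 0]])
        assert count_hydrogen_bonds(frame, [0], [1], [2]) == 0

    def test_outside_angle_does_not_count(self):
        # acceptor at 90 degrees from the D-H direction
        frame = np.array([[0, 0, 0], [1.0, 0, 0], [0.0, 3.0, 0]])
        assert count_hydrogen_bonds(frame, [0], [1], [2]) == 0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        frame = rng.uniform(0, 6, size=(12, 3))
        donors, hydrogens = [0, 2, 4, 6, 8], [1, 3, 5, 7, 9]
        acceptors = [10, 11, 0, 4]
        got = count_hydrogen_bonds(frame, donors, hydrogens, acceptors)
        expect = 0
        for d, h in zip(donors, hydrogens):
            for a in acceptors:
                if a == d:
                    continue
                da = frame[a] - frame[d]
                dist = np.linalg.norm(da)
                dh = frame[h] - frame[d]
                cosang = np.dot(da, dh) / (dist * np.linalg.norm(dh))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if dist <= 3.5 and ang <= 30.0:
                    expect += 1
        assert got == expect

    def test_mismatched_lists_rejected(self):
        with pytest.raises(ValueError):
            count_hydrogen_bonds(np.zeros((3, 3)), [0, 1], [2], [0])


class TestPca:
    def test_single_axis_motion_is_rank_one(self):
        base = random_points(6, 10)
        frames = np.stack([base + np.array([a, 0, 0]) * np.linspace(-1, 1, 6)[:, None][0]
                           for a in np.linspace(-1, 1, 50)])
        # move only atom 0 along x to avoid rigid-body absorption
        frames = np.repeat(base[None], 50, axis=0)
        frames[:, 0, 0] += np.linspace(-1, 1, 50)
        traj = StructureTrajectory(frames)
        modes = pca_modes(traj, n_modes=1)
        # superposition onto the mean leaks a sliver of variance into the
        # rigid-body directions; the first mode still dominates completely
        assert modes.variance_fractions[0] == pytest.approx(1.0, abs=1e-3)

    def test_eigenvalue_sum_equals_total_variance(self):
        traj = gen_toy_trajectory(20, 400, 0.2, seed=11)
        modes = pca_modes(traj, n_modes=2)
        from presyn.trajectory import _aligned_stack

        frames = _aligned_stack(traj, np.arange(20))
        flat = frames.reshape(400, -1)
        total_var = flat.var(axis=0, ddof=1).sum()
        assert modes.eigenvalues.sum() == pytest.approx(total_var, rel=1e-9)

    def test_cumulative_fractions_monotone_and_bounded(self):
        traj = gen_toy_trajectory(10, 300, 0.1, seed=12)
        modes = pca_modes(traj, n_modes=2)
        cum = np.cumsum(modes.variance_fractions)
        assert np.all(np.diff(cum) >= -1e-15)
        assert cum[-1] <= 1.0 + 1e-9

    def test_projections_are_centred(self):
        traj = gen_toy_trajectory(10, 500, 0.1, seed=13)
        modes = pca_modes(traj, n_modes=2)
        np.testing.assert_allclose(modes.projections.mean(axis=0), 0.0, atol=1e-9)

    def test_over_requesting_modes_errors(self):
        traj = gen_toy_trajectory(4, 3, 0.0, seed=14)
        with pytest.raises(ValueError):
            pca_modes(traj, n_modes=12)


class TestFreeEnergyLandscape:
    def test_single_occupied_bin_is_zero(self):
        pts = np.tile([[0.5, 0.5]], (200, 1))
        grid = free_energy_landscape(pts, 300.0, n_bins=4)
        finite = grid.delta_g[np.isfinite(grid.delta_g)]
        assert finite.size == 1
        assert finite[0] == 0.0

    def test_two_bin_ratio_closed_form(self):
        # occupancy 2/3 vs 1/3 at 300 K: dG = kT ln 2 = 1.729 kJ/mol
        pts = np.vstack([np.tile([[0.25, 0.5]], (200, 1)),
                         np.tile([[0.75, 0.5]], (100, 1))])
        grid = free_energy_landscape(pts, 300.0, n_bins=2)
        finite = np.sort(grid.delta_g[np.isfinite(grid.delta_g)])
        expect = KB_KJ_PER_MOL_K * 300.0 * np.log(2.0)
        assert finite[0] == 0.0
        assert finite[1] == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(1.729, abs=2e-3)

    def test_uniform_occupancy_is_flat(self):
        rng = np.random.default_rng(15)
        pts = rng.uniform(0, 1, size=(40000, 2))
        grid = free_energy_landscape(pts, 300.0, n_bins=5)
        assert np.nanmax(grid.delta_g[np.isfinite(grid.delta_g)]) < 0.3

    def test_occupancy_normalised(self):
        pts = np.random.default_rng(16).normal(size=(500, 2))
        grid = free_energy_landscape(pts)
        assert grid.occupancy.sum() == pytest.approx(1.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            free_energy_landscape(np.zeros((10, 2)))


class TestRigidBodyInvariance:
    def test_metrics_invariant_under_global_motion(self):
        traj = gen_toy_trajectory(30, 60, 0.1, seed=17)
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        moved = StructureTrajectory(traj.coords @ rot.T + np.array([3.0, -1.0, 7.0]))

        np.testing.assert_allclose(
            rmsd_series(traj), rmsd_series(moved), atol=1e-9
        )
        np.testing.assert_allclose(
            rmsf_per_atom(traj), rmsf_per_atom(moved), atol=1e-9
        )
        for f in (0, 30):
            assert radius_of_gyration(traj.coords[f]) == pytest.approx(
                radius_of_gyration(moved.coords[f]), rel=1e-12
            )
        radii = np.full(30, 1.7)
        # the point lattice is fixed in space, so SASA is rotation-invariant
        # only up to its discretisation error
        assert sasa(traj.coords[0], radii)[0] == pytest.approx(
            sasa(moved.coords[0], radii)[0], rel=0.01
        )
        a = pca_modes(traj, n_modes=2).eigenvalues
        b = pca_modes(moved, n_modes=2).eigenvalues
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestSelectAtoms:
    @staticmethod
    def _named_traj():
        from presyn.trajectory import StructureTrajectory

        coords = np.zeros((2, 6, 3))
        coords[1] += 0.1
        return StructureTrajectory(
            coords,
            atom_names=np.array(["CA", "CB", "CA", "N", "CA", "O"], dtype=object),
            residue_index=np.array([1, 1, 2, 2, 3, 3]),
        )

    def test_name_clause(self):
        from presyn.trajectory import select_atoms

        traj = self._named_traj()
        np.testing.assert_array_equal(select_atoms(traj, "name CA"), [0, 2, 4])

    def test_resid_range_and_name(self):
        from presyn.trajectory import select_atoms

        traj = self._named_traj()
        np.testing.assert_array_equal(
            select_atoms(traj, "name CA and resid 2-3"), [2, 4]
        )

    def test_all_and_errors(self):
        from presyn.trajectory import select_atoms

        traj = self._named_traj()
        assert len(select_atoms(traj, "all")) == 6
        with pytest.raises(ValueError):
            select_atoms(traj, "name ZZ")
        with pytest.raises(ValueError):
            select_atoms(traj, "chain A")
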