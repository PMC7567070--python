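"""RMSD / RMSF / B-factor / pseudo-dihedral metrics and circular summaries."""

import numpy as np
import pytest
from MDAnalysis.lib.distances import calc_dihedrals
from scipy.spatial.transform import Rotation

from trajmetrics import (
    DihedralSeries,
    QuadrupleSpec,
    RigidTransform,
    apply_transform,
    build_ideal_helix,
    compare_distributions,
    compute_pseudo_dihedral,
    compute_rmsd,
    compute_rmsf,
    rmsf_to_bfactor,
    select,
    simulate_angle_trajectory,
    summarize_angles,
)
from trajmetrics.metrics import BFACTOR_PREFACTOR, dihedral_from_points, wrap_angle
from trajmetrics.errors import SelectionError, UndefinedAngleError, WindowError
from trajmetrics.synthetic import HelixSpec

from conftest import trajectory_from_frames
from test_superposition import min_rmsd_numeric


def series_from_angles(angles, times=None):
    angles = np.asarray(angles, float)
    if times is None:
        times = np.arange(len(angles), dtype=float)
    return DihedralSeries(times=times, angles=angles, quadruple=QuadrupleSpec())


SQUARE = np.array([[0.0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]])


class TestRmsd:
    def test_identical_frames_give_zero(self):
        traj = trajectory_from_frames(np.stack([SQUARE] * 4))
        sel = select(traj, "all")
        series = compute_rmsd(traj, sel, fit=True)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)
        assert series.mean_value == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_without_fit(self):
        moved = SQUARE.copy()
        moved[0, 0] -= 2.0  # one of 4 equal-mass atoms displaced 2 A
        traj = trajectory_from_frames([SQUARE, moved])
        series = compute_rmsd(traj, select(traj, "all"), fit=False)
        assert series.values[1] == pytest.approx(2.0 / np.sqrt(4.0))

    def test_fitted_value_matches_rotation_space_oracle(self):
        moved = SQUARE.copy()
        moved[0, 0] -= 2.0
        traj = trajectory_from_frames([SQUARE, moved])
        series = compute_rmsd(traj, select(traj, "all"), fit=True)
        oracle = min_rmsd_numeric(moved, SQUARE)
        assert series.values[1] == pytest.approx(oracle, abs=1e-6)
        assert series.values[1] < 2.0 / np.sqrt(4.0)  # fitting can only reduce

    def test_fitted_rmsd_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(0)
        frames = SQUARE[None] + rng.normal(0, 0.3, size=(5, 4, 3))
        traj = trajectory_from_frames(frames)
        sel = select(traj, "all")
        base = compute_rmsd(traj, sel, fit=True).values
        motion = RigidTransform(
            Rotation.from_rotvec([0.4, -1.0, 0.2]).as_matrix(), np.array([5.0, -3.0, 1.0])
        )
        moved = apply_transform(traj, motion)
        np.testing.assert_allclose(
            compute_rmsd(moved, sel, fit=True).values, base, atol=1e-6
        )

    def test_reference_structure_and_mean_window(self):
        frames = np.stack([SQUARE, SQUARE + [0.0, 0.0, 1.0], SQUARE + [0.0, 0.0, 2.0]])
        traj = trajectory_from_frames(frames)
        sel = select(traj, "all")
        series = compute_rmsd(traj, sel, fit=False, mean_window=(1.0, 2.0))
        assert series.mean_value == pytest.approx(1.5)

    def test_atom_count_mismatch_rejected(self):
        from conftest import structure_from_coords

        traj = trajectory_from_frames(np.stack([SQUARE] * 2))
        ref = structure_from_coords(SQUARE[:3])
        with pytest.raises(ValueError):
            compute_rmsd(traj, select(traj, "all"), reference=ref)


class TestRmsf:
    def test_static_trajectory_gives_zero(self):
        traj = trajectory_from_frames(np.stack([SQUARE] * 10))
        prof = compute_rmsf(traj, select(traj, "all"), window=(0.0, 9.0), fit=False)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_square_wave_oscillation_closed_form(self):
        # one atom alternating +/- 1 A along x about its mean: RMSF exactly 1
        frames = []
        for k in range(10):
            f = SQUARE.copy()
            f[0, 0] += 1.0 if k % 2 == 0 else -1.0
            frames.append(f)
        traj = trajectory_from_frames(frames)
        prof = compute_rmsf(traj, select(traj, "all"), window=(0.0, 9.0), fit=False)
        assert prof.rmsf[0] == pytest.approx(1.0)
        np.testing.assert_allclose(prof.rmsf[1:], 0.0, atol=1e-12)

    def test_isotropic_jitter_converges_to_sigma_sqrt3(self, jitter_trajectory):
        traj = jitter_trajectory
        prof = compute_rmsf(
            traj, select(traj, "all"), window=(0.0, traj.times[-1]), fit=False
        )
        expected = 0.5 * np.sqrt(3.0)
        np.testing.assert_allclose(prof.rmsf, expected, rtol=0.02)

    def test_convergence_rate_in_frame_count(self):
        # estimation error shrinks roughly like 1/sqrt(F)
        from trajmetrics import FluctuationSpec, simulate_fluctuations

        base = build_ideal_helix(HelixSpec(n_residues=5))
        expected = 0.5 * np.sqrt(3.0)
        errs = []
        for n in (100, 1000, 10_000):
            traj = simulate_fluctuations(
                base, FluctuationSpec(sigma=0.5, n_frames=n, seed=99)
            )
            prof = compute_rmsf(
                traj, select(traj, "all"), window=(0.0, traj.times[-1]), fit=False
            )
            errs.append(np.abs(prof.rmsf - expected).mean())
        assert errs[2] < errs[0]
        slope = np.polyfit(np.log10([100, 1000, 10_000]), np.log10(errs), 1)[0]
        assert -1.0 < slope < -0.2  # consistent with ~n^(-1/2)

    def test_window_outside_trajectory_is_error(self):
        traj = trajectory_from_frames(np.stack([SQUARE] * 5))
        with pytest.raises(WindowError):
            compute_rmsf(traj, select(traj, "all"), window=(100.0, 200.0))


class TestBFactor:
    def test_zero_rmsf_gives_zero_b(self):
        traj = trajectory_from_frames(np.stack([SQUARE] * 4))
        prof = compute_rmsf(traj, select(traj, "all"), window=(0.0, 3.0), fit=False)
        bfac = rmsf_to_bfactor(prof)
        np.testing.assert_allclose(bfac.b, 0.0, atol=1e-12)

    def test_unit_rmsf_value_and_algebraic_identity(self, jitter_trajectory):
        assert BFACTOR_PREFACTOR == pytest.approx(26.3189, abs=1e-3)
        traj = jitter_trajectory
        prof = compute_rmsf(traj, select(traj, "all"), window=(0.0, 500.0), fit=False)
        bfac = rmsf_to_bfactor(prof)
        # identity holds exactly on the stored fields
        np.testing.assert_array_equal(bfac.b, BFACTOR_PREFACTOR * prof.rmsf**2)

    def test_quadratic_scaling(self):
        frames = []
        for k in range(6):
            f = SQUARE.copy()
            f[0, 0] += (1.0 if k % 2 == 0 else -1.0)
            f[1, 0] += (2.0 if k % 2 == 0 else -2.0)
            frames.append(f)
        traj = trajectory_from_frames(frames)
        prof = compute_rmsf(traj, select(traj, "all"), window=(0.0, 5.0), fit=False)
        bfac = rmsf_to_bfactor(prof)
        assert bfac.b[1] == pytest.approx(4.0 * bfac.b[0])


class TestPseudoDihedral:
    P1, P2, P3 = np.array([1.0, 0, 0]), np.array([0.0, 0, 0]), np.array([0.0, 0, 1])

    def test_cis_is_zero(self):
        assert dihedral_from_points(self.P1, self.P2, self.P3, [1.0, 0, 1])[0] == pytest.approx(0.0)

    def test_trans_is_180(self):
        assert dihedral_from_points(self.P1, self.P2, self.P3, [-1.0, 0, 1])[0] == pytest.approx(180.0)

    @pytest.mark.parametrize("p4,expected", [([0.0, 1, 1], 90.0), ([0.0, -1, 1], -90.0)])
    def test_sign_matches_vector_algebra_oracle(self, p4, expected):
        got = dihedral_from_points(self.P1, self.P2, self.P3, p4)[0]
        assert got == pytest.approx(expected)
        # independent cross-product-sign oracle (MDAnalysis implementation)
        oracle = np.degrees(
            calc_dihedrals(
                self.P1[None], self.P2[None], self.P3[None], np.asarray(p4, float)[None]
            )
        )[0]
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_random_quadruples_match_independent_implementation(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(0, 2, size=(200, 4, 3))
        mine = dihedral_from_points(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        oracle = np.degrees(
            calc_dihedrals(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        )
        # the reference implementation computes in single precision
        np.testing.assert_allclose(wrap_angle(mine - oracle), 0.0, atol=1e-4)

    def test_mirror_image_negates_angle(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(0, 2, size=(50, 4, 3))
        mine = dihedral_from_points(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        neg = dihedral_from_points(-pts[:, 0], -pts[:, 1], -pts[:, 2], -pts[:, 3])
        np.testing.assert_allclose(wrap_angle(mine + neg), 0.0, atol=1e-6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(22)
        pts = rng.normal(0, 2, size=(30, 4, 3))
        t = RigidTransform(
            Rotation.from_rotvec([0.5, 0.5, -0.3]).as_matrix(), np.array([1.0, 2.0, 3.0])
        )
        moved = t.apply(pts.reshape(-1, 3)).reshape(pts.shape)
        a = dihedral_from_points(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        b = dihedral_from_points(moved[:, 0], moved[:, 1], moved[:, 2], moved[:, 3])
        np.testing.assert_allclose(wrap_angle(a - b), 0.0, atol=1e-6)

    def test_collinear_points_name_the_frame(self):
        good = np.array([[1.0, 0, 0], [0.0, 0, 0], [0.0, 0, 1], [0.0, 1, 1]])
        bad = good.copy()
        bad[0] = [0.0, 0, -1]  # p1, p2, p3 collinear
        traj = trajectory_from_frames([good, bad], atoms=None)
        with pytest.raises(UndefinedAngleError, match="frame 1"):
            dihedral_from_points(
                traj.frames[:, 0], traj.frames[:, 1], traj.frames[:, 2], traj.frames[:, 3]
            )

    def test_quadruple_resolution_on_trajectory(self):
        from conftest import make_atoms

        atoms = make_atoms(120)
        rng = np.random.default_rng(5)
        frames = rng.normal(0, 5, size=(3, 120, 3))
        traj = trajectory_from_frames(frames, atoms=atoms)
        series = compute_pseudo_dihedral(traj)  # default 67/74/104/87 quadruple
        idx = QuadrupleSpec().resolve(atoms)
        assert [atoms[i].residue_seq for i in idx] == [67, 74, 104, 87]
        expected = dihedral_from_points(
            frames[:, idx[0]], frames[:, idx[1]], frames[:, idx[2]], frames[:, idx[3]]
        )
        np.testing.assert_allclose(series.angles, expected)

    def test_unresolvable_quadruple_is_error(self):
        from conftest import make_atoms

        traj = trajectory_from_frames(np.zeros((1, 5, 3)), atoms=make_atoms(5))
        with pytest.raises(SelectionError):
            compute_pseudo_dihedral(traj)


class TestSummarizeAngles:
    def test_constant_angles(self):
        dist = summarize_angles(series_from_angles([-55.3] * 100), window=(0.0, 99.0))
        assert dist.arithmetic_mean == pytest.approx(-55.3)
        assert dist.circular_mean == pytest.approx(-55.3)
        assert dist.circular_std == pytest.approx(0.0, abs=1e-6)
        assert dist.mode_bin_center == pytest.approx(-55.5)  # 1-degree grid anchored at 0

    def test_von_mises_recovery(self):
        series = simulate_angle_trajectory(mu=-62.0, kappa=50.0, n_frames=3000, seed=42)
        dist = summarize_angles(series, window=(series.times[0], series.times[-1]))
        assert abs(wrap_angle(dist.circular_mean - (-62.0))) < 0.5

    def test_wraparound_branch_artifact(self):
        dist = summarize_angles(series_from_angles([179.0, -179.0]), window=(0.0, 1.0))
        assert dist.circular_mean == pytest.approx(180.0)
        assert dist.arithmetic_mean == pytest.approx(0.0)

    def test_counts_conserve_frames_and_density_normalizes(self):
        series = simulate_angle_trajectory(mu=10.0, kappa=5.0, n_frames=777, seed=3)
        dist = summarize_angles(series, window=(series.times[0], series.times[-1]), bin_width=2.0)
        assert dist.counts.sum() == dist.n_frames == 777
        assert np.sum(dist.density) * dist.bin_width == pytest.approx(1.0)
        assert dist.mode_bin_center in dist.bin_centers[dist.counts == dist.counts.max()]

    def test_default_window_takes_last_30ns(self):
        times = np.arange(0.0, 50_001.0, 100.0)  # 50 ns
        angles = np.where(times < 20_000.0, 100.0, -60.0)
        dist = summarize_angles(series_from_angles(angles, times=times))
        assert dist.window[0] >= 20_000.0
        assert dist.circular_mean == pytest.approx(-60.0)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            summarize_angles(series_from_angles([0.0, 1.0]), window=(0.0, 1.0), bin_width=7.0)


class TestCompareDistributions:
    def test_self_comparison_is_null(self):
        series = simulate_angle_trajectory(mu=-55.3, kappa=50.0, n_frames=1000, seed=1)
        dist = summarize_angles(series, window=(0.0, 1e9))
        shift = compare_distributions(dist, dist)
        assert shift.delta_circular_mean == 0.0
        assert shift.delta_mode == 0.0
        assert shift.circular_std_ratio == pytest.approx(1.0)
        assert shift.overlap == pytest.approx(1.0)
        assert not shift.left_shifted

    def test_k104q_like_left_shift(self):
        wt = summarize_angles(
            simulate_angle_trajectory(mu=-55.3, kappa=50.0, n_frames=3000, seed=4),
            window=(0.0, 1e9),
        )
        mut = summarize_angles(
            simulate_angle_trajectory(mu=-62.0, kappa=50.0, n_frames=3000, seed=3),
            window=(0.0, 1e9),
        )
        shift = compare_distributions(mut, wt)
        assert shift.delta_circular_mean == pytest.approx(-6.7, abs=1.0)
        assert shift.left_shifted

    def test_k104a_like_right_shift_and_wider(self):
        wt = summarize_angles(
            simulate_angle_trajectory(mu=-55.3, kappa=50.0, n_frames=3000, seed=4),
            window=(0.0, 1e9),
        )
        mut = summarize_angles(
            simulate_angle_trajectory(mu=-50.3, kappa=30.0, n_frames=3000, seed=9),
            window=(0.0, 1e9),
        )
        shift = compare_distributions(mut, wt)
        assert shift.delta_circular_mean == pytest.approx(5.0, abs=1.0)
        assert shift.circular_std_ratio > 1.0
        assert not shift.left_shifted

    def test_mismatched_grids_rejected(self):
        a = summarize_angles(series_from_angles([0.0, 1.0]), window=(0.0, 1.0), bin_width=1.0)
        b = summarize_angles(series_from_angles([0.0, 1.0]), window=(0.0, 1.0), bin_width=2.0)
        with pytest.raises(ValueError):
            compare_distributions(a, b)
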