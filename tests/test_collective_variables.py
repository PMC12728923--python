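"""Collective variables: switching function, coordination, distances, angle."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helpers import two_group_trajectory

from bindscape import collective_variables as cv
from bindscape.model_io import Trajectory


def brute_coordination(coords_a, coords_b, p):
    total = 0.0
    for a in coords_a:
        for b in coords_b:
            total += cv.switching_value(float(np.linalg.norm(a - b)), p)
    return total


class TestSwitchingFunction:
    def test_contact_limit_is_one(self):
        assert cv.switching_value(0.0) == pytest.approx(1.0)

    def test_removable_singularity_matches_two_sided_limit(self):
        p = cv.SwitchingParams()
        at = cv.switching_value(p.r0, p)
        below = cv.switching_value(p.r0 * (1 - 1e-8), p)
        above = cv.switching_value(p.r0 * (1 + 1e-8), p)
        assert at == pytest.approx(p.n / p.m, abs=1e-9)
        assert below == pytest.approx(at, abs=1e-6)
        assert above == pytest.approx(at, abs=1e-6)

    def test_closed_form_at_twice_r0(self):
        assert cv.switching_value(1.8) == pytest.approx(63.0 / 4095.0, abs=1e-12)

    def test_monotone_decay_and_clamp(self):
        p = cv.SwitchingParams(d0=0.2)
        r = np.linspace(0.2, 5.0, 200)
        s = cv.switching_value(r, p)
        assert np.all(np.diff(s) <= 1e-12)
        assert cv.switching_value(0.05, p) == 1.0  # r < d0 clamps to contact
        assert cv.switching_value(200.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            cv.SwitchingParams(n=12, m=6)
        with pytest.raises(ValueError):
            cv.switching_value(-0.1)


class TestCoordinationNumber:
    def test_single_pair_at_r0_gives_half(self):
        traj = two_group_trajectory([[0, 0, 0]], [[0.9, 0, 0]])
        series = cv.coordination_number(traj, [0], [1])
        assert series.values[0] == pytest.approx(0.5, abs=1e-12)

    def test_far_field_decays_below_tolerance(self, rng):
        a = rng.uniform(0, 1, (4, 3))
        b = rng.uniform(0, 1, (5, 3)) + 20.0  # every pair >> 5 r0
        traj = two_group_trajectory(a, b)
        series = cv.coordination_number(traj, np.arange(4), 4 + np.arange(5))
        assert series.values[0] < 4 * 5 * 1e-3

    def test_matches_brute_force_double_loop(self, rng):
        p = cv.SwitchingParams()
        a = rng.uniform(0, 3, (20, 3))
        b = rng.uniform(0, 3, (20, 3)) + [1.0, 0, 0]
        traj = two_group_trajectory(a, b)
        series = cv.coordination_number(traj, np.arange(20), 20 + np.arange(20), p)
        assert series.values[0] == pytest.approx(brute_coordination(a, b, p), abs=1e-10)

    def test_overlapping_selections_rejected(self, rng):
        traj = two_group_trajectory(rng.uniform(size=(3, 3)), rng.uniform(size=(3, 3)))
        with pytest.raises(ValueError, match="overlap"):
            cv.coordination_number(traj, [0, 1], [1, 2])

    def test_continuity_under_small_perturbation(self, rng):
        a = rng.uniform(0, 2, (5, 3))
        b = rng.uniform(0, 2, (5, 3)) + [2.5, 0, 0]
        base = brute_coordination(a, b, cv.SwitchingParams())
        b_eps = b.copy()
        b_eps[0] += 1e-7
        assert abs(brute_coordination(a, b_eps, cv.SwitchingParams()) - base) < 1e-4


class TestDistances:
    def test_com_distance_three_four_five(self):
        traj = two_group_trajectory([[0, 0, 0]], [[3, 4, 0]])
        assert cv.com_distance(traj, [0], [1]).values[0] == pytest.approx(5.0)

    def test_com_distance_translation_covariance(self, rng):
        a = rng.uniform(0, 2, (6, 3))
        b = rng.uniform(0, 2, (4, 3)) + [4, 0, 0]
        sep_axis = (b.mean(0) - a.mean(0)) / np.linalg.norm(b.mean(0) - a.mean(0))
        d0 = cv.com_distance(two_group_trajectory(a, b), np.arange(6), 6 + np.arange(4))
        d1 = cv.com_distance(
            two_group_trajectory(a, b + 2 * sep_axis), np.arange(6), 6 + np.arange(4)
        )
        assert d1.values[0] - d0.values[0] == pytest.approx(2.0, abs=1e-9)

    def test_mixture_pose_matches_spec_arithmetic(self, toy_complex, default_poses):
        import bindscape.synthetic_data as sd

        pose = default_poses[0]
        coords = sd.place_ligand(toy_complex, pose)[None]
        traj = Trajectory(toy_complex.topology, coords)
        rec = np.arange(toy_complex.n_receptor)
        lig = toy_complex.n_receptor + np.arange(toy_complex.n_ligand)
        expected = np.linalg.norm(
            pose.translation - toy_complex.receptor_coords.mean(axis=0)
        )
        assert cv.com_distance(traj, rec, lig).values[0] == pytest.approx(
            expected, abs=1e-9
        )

    def test_min_distance_matches_brute_force(self, rng):
        a = rng.uniform(0, 3, (7, 3))
        b = rng.uniform(0, 3, (9, 3))
        traj = two_group_trajectory(a, b)
        expected = min(np.linalg.norm(x - y) for x in a for y in b)
        got = cv.min_distance(traj, np.arange(7), 7 + np.arange(9)).values[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_min_distance_set_monotonicity(self, rng):
        a = rng.uniform(0, 3, (5, 3))
        far = np.array([[50.0, 0, 0]])
        b = rng.uniform(0, 3, (5, 3))
        traj = two_group_trajectory(np.vstack([a, far]), b)
        sub = cv.min_distance(traj, np.arange(5), 6 + np.arange(5)).values[0]
        full = cv.min_distance(traj, np.arange(6), 6 + np.arange(5)).values[0]
        assert full <= sub

    def test_empty_selection_rejected(self, rng):
        traj = two_group_trajectory(rng.uniform(size=(3, 3)), rng.uniform(size=(3, 3)))
        with pytest.raises(ValueError, match="non-empty"):
            cv.min_distance(traj, [], [3])


class TestOrientationAngle:
    @pytest.mark.parametrize(
        "vec_b,expected",
        [([1, 0, 0], 0.0), ([-1, 0, 0], 180.0), ([0, 1, 0], 90.0)],
    )
    def test_canonical_angles(self, vec_b, expected):
        a = np.array([[0, 0, 0], [1, 0, 0]])
        b = np.array([[5, 5, 5], [5, 5, 5] + np.asarray(vec_b, float)])
        traj = two_group_trajectory(a, b)
        angle = cv.orientation_angle(traj, [0], [1], [2], [3]).values[0]
        assert angle == pytest.approx(expected, abs=1e-9)

    def test_zero_length_axis_rejected(self):
        a = np.array([[0, 0, 0], [0, 0, 0]])
        b = np.array([[1, 1, 1], [2, 1, 1]])
        traj = two_group_trajectory(a, b)
        with pytest.raises(ValueError, match="zero-length"):
            cv.orientation_angle(traj, [0], [1], [2], [3])


class TestRigidMotionInvariance:
    def test_all_cvs_invariant_under_global_rigid_motion(self, rng):
        a = rng.uniform(0, 2, (6, 3))
        b = rng.uniform(0, 2, (6, 3)) + [3, 0, 0]
        base = two_group_trajectory(a, b)
        R = Rotation.from_euler("xyz", [20, -40, 75], degrees=True).as_matrix()
        t = np.array([5.0, -2.0, 1.0])
        moved = two_group_trajectory(a @ R.T + t, b @ R.T + t)
        sa, sb = np.arange(6), 6 + np.arange(6)
        for func in (
            lambda tr: cv.com_distance(tr, sa, sb),
            lambda tr: cv.min_distance(tr, sa, sb),
            lambda tr: cv.coordination_number(tr, sa, sb),
            lambda tr: cv.orientation_angle(tr, [0], [5], [6], [11]),
        ):
            assert func(moved).values[0] == pytest.approx(
                func(base).values[0], abs=1e-9
            )


class TestNtermDistance:
    def test_delegates_to_com_distance_and_permutation_invariant(self, toy_complex, mixture):
        _, traj, _ = mixture
        sub = traj.subset_frames(range(20))
        top, regions = sub.topology, toy_complex.regions
        series = cv.nterm_nterm_distance(sub, regions)
        direct = cv.com_distance(
            sub,
            regions.indices(top, "RECEPTOR_NTERM_CV"),
            np.flip(regions.indices(top, "LIGAND_NTERM_CV")),
        )
        np.testing.assert_allclose(series.values, direct.values, atol=1e-12)

    def test_missing_region_rejected(self, mixture):
        from bindscape.model_io import regions_from_dict

        _, traj, _ = mixture
        bare = regions_from_dict({"CRS1": {"chain": "R", "ranges": [[1, 31]]}})
        with pytest.raises(ValueError, match="LIGAND_NTERM_CV|RECEPTOR_NTERM_CV"):
            cv.nterm_nterm_distance(traj, bare)
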