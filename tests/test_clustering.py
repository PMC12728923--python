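"""Kabsch superposition, GROMOS clustering and density-peak clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helpers import two_group_trajectory

from bindscape import clustering as cl
from bindscape import synthetic_data as sd
from bindscape.model_io import Trajectory


def moving_ligand_trajectory(frames_b, n_static=3):
    """Static 3-bead chain A plus a per-frame mobile chain B."""
    from bindscape.model_io import Particle, Topology

    static_a = np.eye(3)[:n_static]
    n_b = frames_b.shape[1]
    particles = [
        Particle(i, "BB", i + 1, "ALA", "A") for i in range(n_static)
    ] + [Particle(n_static + i, "BB", i + 1, "ALA", "B") for i in range(n_b)]
    coords = np.concatenate(
        [np.repeat(static_a[None], frames_b.shape[0], axis=0), frames_b], axis=1
    )
    return Trajectory(Topology(particles), coords)


def brute_force_gromos(rmsd_matrix, cutoff):
    """Independent reference implementation of greedy neighbour clustering."""
    n = rmsd_matrix.shape[0]
    labels = np.zeros(n, dtype=int)
    remaining = set(range(n))
    label = 0
    reps = []
    while remaining:
        label += 1
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if rmsd_matrix[i, j] < cutoff)
            if count > best_count:
                best, best_count = i, count
        members = [j for j in sorted(remaining) if rmsd_matrix[best, j] < cutoff]
        for j in members:
            labels[j] = label
        remaining -= set(members)
        reps.append(best)
    return labels, reps


class TestKabsch:
    def test_exact_recovery_of_rigid_motion(self, rng):
        X = rng.uniform(size=(30, 3))
        R = Rotation.from_euler("zyx", [10, 30, -50], degrees=True).as_matrix()
        Y = (X - [1, 2, 3]) @ R.T
        _, _, rmsd = cl.kabsch_superpose(X, Y)
        assert rmsd < 1e-9

    def test_noise_rmsd_within_expected_band(self, rng):
        sigma = 0.01
        X = rng.uniform(size=(100, 3))
        Y = X + rng.normal(scale=sigma, size=X.shape)
        _, _, rmsd = cl.kabsch_superpose(X, Y)
        assert 0 < rmsd < 2 * sigma * np.sqrt(3)

    def test_mirror_image_keeps_proper_rotation(self, rng):
        X = rng.uniform(size=(20, 3))
        Y = X * [-1, 1, 1]
        R, _, rmsd = cl.kabsch_superpose(X, Y)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.0

    def test_agrees_with_scipy_align_vectors(self, rng):
        X = rng.uniform(size=(25, 3))
        Y = rng.uniform(size=(25, 3))
        _, _, rmsd = cl.kabsch_superpose(X, Y)
        rot, rssd = Rotation.align_vectors(
            X - X.mean(0), Y - Y.mean(0)
        )
        assert rmsd == pytest.approx(rssd / np.sqrt(25), abs=1e-9)

    @pytest.mark.parametrize(
        "X,Y",
        [
            (np.zeros((2, 3)), np.zeros((2, 3))),
            (np.outer(np.arange(5.0), [1, 0, 0]), np.outer(np.arange(5.0), [1, 0, 0])),
        ],
    )
    def test_degenerate_sets_rejected(self, X, Y):
        with pytest.raises(ValueError):
            cl.kabsch_superpose(X, Y)


class TestGromosCluster:
    def test_identical_frames_single_cluster(self, rng):
        base = two_group_trajectory(rng.uniform(size=(5, 3)), rng.uniform(size=(5, 3)))
        traj = Trajectory(base.topology, np.repeat(base.coordinates, 20, axis=0))
        assignment = cl.gromos_cluster(traj, np.arange(5), 5 + np.arange(5), 0.5)
        assert assignment.n_clusters == 1
        assert assignment.sizes[0] == 20
        assert assignment.representatives == [0]

    def test_two_pose_mixture_recovers_exact_sizes(self, toy_complex, default_poses):
        spec = sd.MixtureSpec(
            poses=default_poses, weights=[0.65, 0.35], n_frames=400, seed=8
        )
        traj, labels = sd.sample_mixture(spec, toy_complex)
        regions, top = toy_complex.regions, traj.topology
        assignment = cl.gromos_cluster(
            traj,
            regions.indices(top, "RECEPTOR_BB"),
            regions.indices(top, "LIGAND_BB"),
            cutoff=0.9,
        )
        assert assignment.n_clusters == 2
        np.testing.assert_array_equal(
            assignment.sizes, [np.sum(labels == 0), np.sum(labels == 1)]
        )
        # label-for-label agreement with the ground truth up to renaming
        assert np.all((assignment.labels == 1) == (labels == 0))

    def test_matches_brute_force_label_for_label(self, rng):
        centers = rng.uniform(0, 5, size=(4, 6, 3))
        frames = np.concatenate(
            [c[None] + rng.normal(scale=0.05, size=(50, 6, 3)) for c in centers]
        )
        rng.shuffle(frames, axis=0)
        traj = moving_ligand_trajectory(frames)
        fit_sel, rmsd_sel = np.arange(3), 3 + np.arange(6)
        assignment = cl.gromos_cluster(traj, fit_sel, rmsd_sel, cutoff=0.8)
        mat = cl.pairwise_rmsd_matrix(traj, fit_sel, rmsd_sel)
        expected_labels, expected_reps = brute_force_gromos(mat, 0.8)
        np.testing.assert_array_equal(assignment.labels, expected_labels)
        assert assignment.representatives == expected_reps

    def test_sizes_non_increasing_and_sum_to_n(self, rng):
        traj = moving_ligand_trajectory(rng.uniform(size=(120, 5, 3)))
        assignment = cl.gromos_cluster(traj, np.arange(3), 3 + np.arange(5), 0.6)
        assert np.all(np.diff(assignment.sizes) <= 0)
        assert assignment.sizes.sum() == 120

    def test_nonpositive_cutoff_rejected(self, rng):
        traj = two_group_trajectory(np.eye(3), rng.uniform(size=(4, 3)))
        with pytest.raises(ValueError):
            cl.gromos_cluster(traj, np.arange(3), 3 + np.arange(4), 0.0)


class TestDensityPeakCluster:
    def test_two_separated_blobs(self, rng):
        a = rng.normal([0, 0], 0.1, size=(700, 2))
        b = rng.normal([10, 0], 0.1, size=(300, 2))
        X = np.vstack([a, b])
        truth = np.r_[np.zeros(700, int), np.ones(300, int)]
        assignment = cl.density_peak_cluster(X)
        assert assignment.n_clusters == 2
        majority = {
            k + 1: np.bincount(truth[assignment.labels == k + 1]).argmax()
            for k in range(2)
        }
        err = np.mean(
            [majority[l] != t for l, t in zip(assignment.labels, truth)]
        )
        assert err <= 0.02

    def test_single_blob_single_cluster(self, rng):
        assignment = cl.density_peak_cluster(rng.normal(size=(400, 2)))
        assert assignment.n_clusters == 1

    def test_labels_invariant_under_global_scaling(self, rng):
        a = rng.normal([0, 0], 0.1, size=(300, 2))
        b = rng.normal([8, 1], 0.1, size=(200, 2))
        X = np.vstack([a, b])
        l1 = cl.density_peak_cluster(X).labels
        l2 = cl.density_peak_cluster(X * 10.0).labels
        np.testing.assert_array_equal(l1, l2)

    def test_identical_items_collapse_to_one_cluster(self):
        assignment = cl.density_peak_cluster(np.ones((30, 2)))
        assert assignment.n_clusters == 1

    def test_representative_belongs_to_its_cluster(self, rng):
        a = rng.normal([0, 0], 0.2, size=(200, 2))
        b = rng.normal([6, 0], 0.2, size=(100, 2))
        assignment = cl.density_peak_cluster(np.vstack([a, b]))
        for k, rep in enumerate(assignment.representatives, start=1):
            assert assignment.labels[rep] == k

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            cl.density_peak_cluster(np.zeros((5, 2)))
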