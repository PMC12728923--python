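"""Conformational clustering: GROMOS RMSD clustering and density peaks.

Two complementary modes mirror common practice in binding-trajectory
analysis:

* :func:`gromos_cluster` - the greedy neighbour-count algorithm of
  GROMOS-style structural clustering: take the frame with the most
  neighbours within an RMSD cutoff as a cluster centre, assign it and its
  neighbours, remove them, repeat.  For two-chain complexes every frame is
  first superposed on a receptor *fit* selection of a common reference so
  the pairwise RMSD over the *rmsd* selection measures relative ligand
  pose; pair-by-pair mutual fitting is available for single-chain use.
* :func:`density_peak_cluster` - density-peak clustering in a low-
  dimensional CV feature space (e.g. coordination vs COM distance):
  cluster centres are points that combine high local density with a large
  distance to any denser point; everything else follows its nearest
  denser neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .model_io import Trajectory

__all__ = [
    "ClusterAssignment",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "density_peak_cluster",
]

NOISE_LABEL = -1


@dataclass
class ClusterAssignment:
    """Per-item labels (1-based; -1 = unassigned) with representatives."""

    labels: np.ndarray
    representatives: list[int]  # item index of each cluster centre, label order
    parameters: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    @property
    def sizes(self) -> np.ndarray:
        return np.array(
            [int(np.sum(self.labels == k + 1)) for k in range(self.n_clusters)]
        )


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of Y onto X.

    Returns ``(R, t, rmsd)`` with ``Y @ R.T + t`` the superposed copy.  The
    rotation is proper (det +1): mirror images are never matched by an
    improper transform.  Degenerate inputs (< 3 points, or a collinear /
    coincident point set) raise ``ValueError``.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must both have shape (n, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 particles for a rigid fit")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    if np.linalg.matrix_rank(X0, tol=1e-10) < 2 or np.linalg.matrix_rank(Y0, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear or coincident) particle set")
    H = Y0.T @ X0
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = xc - yc @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((Y @ R.T + t - X) ** 2, axis=1))))
    return R, t, rmsd


def _aligned_coordinates(
    traj: Trajectory, fit_sel: np.ndarray, measure_sel: np.ndarray, ref_frame: int = 0
) -> np.ndarray:
    """Superpose every frame on the fit selection of a reference frame."""
    fit_sel = np.asarray(fit_sel, int)
    measure_sel = np.asarray(measure_sel, int)
    if fit_sel.size == 0 or measure_sel.size == 0:
        raise ValueError("selections must be non-empty")
    ref = traj.coordinates[ref_frame][fit_sel]
    out = np.empty((traj.n_frames, measure_sel.size, 3))
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(ref, traj.coordinates[f][fit_sel])
        out[f] = traj.coordinates[f][measure_sel] @ R.T + t
    return out


def pairwise_rmsd_matrix(
    traj: Trajectory,
    fit_sel: np.ndarray,
    rmsd_sel: np.ndarray,
    mutual_fit: bool = False,
) -> np.ndarray:
    """All-against-all RMSD over ``rmsd_sel`` (nm).

    Default: common-reference fitting on ``fit_sel`` (frame 0), then plain
    coordinate RMSD - appropriate when the fit selection is a rigid
    receptor and the RMSD selection the ligand, so the matrix measures
    relative binding pose.  ``mutual_fit=True`` refits every pair on
    ``fit_sel`` before measuring (single-chain convention).
    """
    n = traj.n_frames
    if mutual_fit:
        fit_sel = np.asarray(fit_sel, int)
        rmsd_sel = np.asarray(rmsd_sel, int)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                R, t, _ = kabsch_superpose(
                    traj.coordinates[i][fit_sel], traj.coordinates[j][fit_sel]
                )
                moved = traj.coordinates[j][rmsd_sel] @ R.T + t
                mat[i, j] = mat[j, i] = np.sqrt(
                    np.mean(np.sum((moved - traj.coordinates[i][rmsd_sel]) ** 2, axis=1))
                )
        return mat
    aligned = _aligned_coordinates(traj, fit_sel, rmsd_sel)
    flat = aligned.reshape(n, -1)
    sq = squareform(pdist(flat, metric="sqeuclidean"))
    return np.sqrt(sq / aligned.shape[1])


def gromos_cluster(
    traj: Trajectory,
    fit_sel: np.ndarray,
    rmsd_sel: np.ndarray,
    cutoff: float,
    mutual_fit: bool = False,
) -> ClusterAssignment:
    """Greedy neighbour-count clustering under an RMSD cutoff (nm).

    Ties in neighbour count resolve to the lowest frame index; the cluster
    representative is its centre frame.  Cluster sizes are non-increasing
    in label order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mat = pairwise_rmsd_matrix(traj, fit_sel, rmsd_sel, mutual_fit=mutual_fit)
    n = mat.shape[0]
    labels = np.zeros(n, dtype=int)
    remaining = np.ones(n, dtype=bool)
    reps: list[int] = []
    label = 0
    neighbour = mat < cutoff  # includes self (diagonal 0 < cutoff)
    while remaining.any():
        label += 1
        counts = (neighbour & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        centre = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbour[centre] & remaining)
        labels[members] = label
        remaining[members] = False
        reps.append(centre)
    return ClusterAssignment(
        labels, reps, parameters={"cutoff": cutoff, "mutual_fit": mutual_fit}
    )


def density_peak_cluster(
    features: np.ndarray,
    dc_percentile: float = 2.0,
    max_centers: int = 20,
    gap_factor: float = 2.0,
    standardize: bool = True,
) -> ClusterAssignment:
    """Density-peak clustering of per-item feature vectors.

    For each item, the local density ``rho`` is a Gaussian kernel sum at
    scale ``d_c`` (the ``dc_percentile``-th percentile of pairwise
    distances) and ``delta`` is the distance to the nearest denser item.
    Cluster centres are the decision-graph outliers: candidates are the
    ``max_centers`` items with the largest ``gamma = rho * delta`` (true
    centres combine high density with a large distance to anything
    denser, while periphery points and cluster cores both score low), and
    the centre set is cut at the largest multiplicative gap in the
    candidates' sorted delta values - true centres sit an order of
    magnitude above the within-cluster delta floor.  If no gap exceeds
    ``gap_factor`` the data are treated as one cluster.
    Remaining items inherit the cluster of their nearest denser
    neighbour.  Features are centred and divided by one pooled scale (the
    RMS of the per-feature standard deviations), which makes the labels
    invariant under a global rescaling of the feature space without
    distorting its geometry.
    """
    X = np.asarray(features, float)
    if X.ndim != 2:
        raise ValueError("features must be a 2D array (items x features)")
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 items")
    if standardize:
        scale = np.sqrt(np.mean(X.std(axis=0) ** 2))
        if scale > 0:
            X = (X - X.mean(axis=0)) / scale
    dist = squareform(pdist(X))
    off_diag = dist[np.triu_indices(n, k=1)]
    if off_diag.max() == 0:  # all items identical
        return ClusterAssignment(
            np.ones(n, dtype=int), [0], parameters={"degenerate": True}
        )
    dc = np.percentile(off_diag, dc_percentile)
    if dc == 0:
        dc = off_diag[off_diag > 0].min()
    rho = np.exp(-((dist / dc) ** 2)).sum(axis=1) - 1.0  # exclude self

    order = np.argsort(-rho, kind="stable")  # densest first
    delta = np.empty(n)
    nearest_denser = np.full(n, -1, dtype=int)
    delta[order[0]] = dist[order[0]].max()
    for rank in range(1, n):
        i = order[rank]
        denser = order[:rank]
        j = denser[np.argmin(dist[i, denser])]
        nearest_denser[i] = j
        delta[i] = dist[i, j]

    gamma = rho * delta
    cand = np.argsort(-gamma, kind="stable")[:max_centers]
    cand = cand[np.argsort(-delta[cand], kind="stable")]
    cand_delta = delta[cand]
    n_centres = 1
    if cand.size > 1:
        with np.errstate(divide="ignore"):
            ratios = cand_delta[:-1] / np.where(cand_delta[1:] > 0, cand_delta[1:], np.nan)
        ratios = np.nan_to_num(ratios, nan=np.inf)
        k = int(np.argmax(ratios))
        if ratios[k] > gap_factor:
            n_centres = k + 1
    centres = np.sort(cand[:n_centres])

    labels = np.zeros(n, dtype=int)
    for k, c in enumerate(centres, start=1):
        labels[c] = k
    for i in order:  # descending density guarantees the parent is labelled
        if labels[i] == 0:
            labels[i] = labels[nearest_denser[i]]

    # relabel by decreasing cluster size (ties keep centre order)
    sizes = [(int(np.sum(labels == k + 1)), k + 1) for k in range(centres.size)]
    sizes.sort(key=lambda t: (-t[0], t[1]))
    remap = {old: new + 1 for new, (_, old) in enumerate(sizes)}
    labels = np.array([remap[l] for l in labels])
    reps = [int(centres[old - 1]) for _, old in sizes]
    return ClusterAssignment(
        labels,
        reps,
        parameters={
            "dc": float(dc),
            "dc_percentile": dc_percentile,
            "gap_factor": gap_factor,
        },
    )
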