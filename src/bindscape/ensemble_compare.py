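"""Ensemble similarity in a global-descriptor PCA space.

Each binding-mode ensemble is summarised per frame by three global
descriptors: (i) receptor-ligand COM distance, (ii) total number of
inter-chain residue contacts, and (iii) the orientation angle between the
chains' N->C axes.  All compared ensembles are pooled, z-standardised per
feature and projected onto the top two principal components; similarity is
then quantified by the Euclidean distance between ensemble centroids and
the Jensen-Shannon divergence between 2D histograms in PC space.

JSD uses base-2 logarithms so its range is [0, 1] (disjoint distributions
reach exactly 1); published ensemble JSD values above ln 2 only make sense
on this scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import jensenshannon
from sklearn.decomposition import PCA

from .binding_kinetics import contact_trace
from .collective_variables import com_distance, orientation_angle
from .model_io import RegionSet, Trajectory

__all__ = [
    "DescriptorEnsemble",
    "compute_descriptors",
    "pca_embed",
    "centroid_distance",
    "jsd",
]

DESCRIPTOR_NAMES = ("com_distance", "total_contacts", "orientation_angle")


@dataclass
class DescriptorEnsemble:
    """Per-frame 3-descriptor vectors for one ensemble, plus PC projections."""

    label: str
    descriptors: np.ndarray  # (n_frames, 3) raw values
    projection: np.ndarray | None = None  # (n_frames, 2) PC coordinates

    @property
    def n_frames(self) -> int:
        return self.descriptors.shape[0]


def compute_descriptors(
    traj: Trajectory,
    regions: RegionSet,
    contact_cutoff: float = 0.5,
    label: str = "",
) -> DescriptorEnsemble:
    """Extract the three global descriptors from a trajectory.

    Requires regions ``RECEPTOR_BB``/``LIGAND_BB`` (COM selections),
    ``RECEPTOR_ALL``/``LIGAND_ALL`` (contact counting) and the four
    ``*_N_ANCHOR``/``*_C_ANCHOR`` selections for the orientation axes.
    """
    top = traj.topology
    idx = lambda name: regions.indices(top, name)
    d = com_distance(traj, idx("RECEPTOR_BB"), idx("LIGAND_BB")).values
    contacts = contact_trace(
        traj, idx("LIGAND_ALL"), idx("RECEPTOR_ALL"), cutoff=contact_cutoff
    ).values
    angle = orientation_angle(
        traj,
        idx("RECEPTOR_N_ANCHOR"),
        idx("RECEPTOR_C_ANCHOR"),
        idx("LIGAND_N_ANCHOR"),
        idx("LIGAND_C_ANCHOR"),
    ).values
    return DescriptorEnsemble(label, np.column_stack([d, contacts, angle]))


def pca_embed(
    ensembles: list[DescriptorEnsemble],
) -> tuple[list[DescriptorEnsemble], np.ndarray, np.ndarray]:
    """Project pooled, standardised descriptors onto the top 2 PCs.

    All ensembles share one embedding: frames are pooled, each feature is
    z-standardised with the pooled mean/SD, and the principal axes come
    from the pooled covariance.  Zero-variance features are dropped with a
    warning.  Component signs follow a deterministic convention (the
    largest-magnitude loading of each PC is positive).  Returns the
    updated ensembles, the explained-variance ratios and the loadings.
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    pooled = np.vstack([e.descriptors for e in ensembles])
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 total frames")
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [DESCRIPTOR_NAMES[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping zero-variance descriptor(s): {dropped}")
    if keep.sum() < 2:
        raise ValueError("fewer than 2 descriptors with variance; PCA undefined")
    z = (pooled[:, keep] - mean[keep]) / sd[keep]
    pca = PCA(n_components=2, svd_solver="full")
    proj = pca.fit_transform(z)
    loadings = pca.components_
    # deterministic sign: largest-|loading| entry of each PC is positive
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            proj[:, k] *= -1.0
    start = 0
    for e in ensembles:
        e.projection = proj[start : start + e.n_frames]
        start += e.n_frames
    return ensembles, pca.explained_variance_ratio_, loadings


def centroid_distance(emb_a: DescriptorEnsemble, emb_b: DescriptorEnsemble) -> float:
    """Euclidean distance between the ensembles' mean PC vectors."""
    for e in (emb_a, emb_b):
        if e.projection is None or e.projection.shape[0] == 0:
            raise ValueError("ensemble has no PC projection; run pca_embed first")
    return float(
        np.linalg.norm(emb_a.projection.mean(axis=0) - emb_b.projection.mean(axis=0))
    )


def jsd(
    emb_a: DescriptorEnsemble,
    emb_b: DescriptorEnsemble,
    bins: tuple[int, int] = (30, 30),
) -> float:
    """Jensen-Shannon divergence between 2D PC histograms, base 2, in [0, 1].

    Bin edges span the pooled range of both ensembles so the histograms are
    directly comparable; empty bins follow the 0 log 0 = 0 convention.
    """
    for e in (emb_a, emb_b):
        if e.projection is None or e.projection.shape[0] == 0:
            raise ValueError("ensemble has no PC projection; run pca_embed first")
    pooled = np.vstack([emb_a.projection, emb_b.projection])
    edges = [
        np.linspace(pooled[:, k].min(), pooled[:, k].max() + 1e-12, bins[k] + 1)
        for k in range(2)
    ]
    pa, _, _ = np.histogram2d(emb_a.projection[:, 0], emb_a.projection[:, 1], bins=edges)
    pb, _, _ = np.histogram2d(emb_b.projection[:, 0], emb_b.projection[:, 1], bins=edges)
    return float(
        jensenshannon(pa.ravel() / pa.sum(), pb.ravel() / pb.sum(), base=2) ** 2
    )
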