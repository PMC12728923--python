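"""Residue-pair contact frequencies, hotspot maps and Delta-contact maps.

A residue pair is in contact in a frame when any inter-particle distance is
strictly below the cutoff (4.0 A for atomistic, 5.0 A for coarse-grained
resolutions).  Frequencies are contact frames divided by either all frames
(default) or only bound frames.  Maps from two conformational ensembles are
compared by thresholding each (strictly greater than tau survives) and
subtracting; positive Delta values mark contacts enriched in the first
ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .collective_variables import iter_cross_distances
from .model_io import Trajectory

__all__ = [
    "ContactFrequencyMap",
    "DeltaContactMap",
    "contact_frequency",
    "threshold_map",
    "delta_map",
    "hotspots",
]


@dataclass
class ContactFrequencyMap:
    """Receptor-residue x ligand-residue matrix of contact fractions."""

    receptor_residues: np.ndarray
    ligand_residues: np.ndarray
    frequencies: np.ndarray  # (n_rec, n_lig) in [0, 1]
    cutoff: float  # nm
    n_frames: int  # denominator frame count
    denominator: str  # "all_frames" or "bound_frames"

    def entry(self, receptor_residue: int, ligand_residue: int) -> float:
        i = int(np.flatnonzero(self.receptor_residues == receptor_residue)[0])
        j = int(np.flatnonzero(self.ligand_residues == ligand_residue)[0])
        return float(self.frequencies[i, j])

    def same_axes(self, other: "ContactFrequencyMap") -> bool:
        return bool(
            np.array_equal(self.receptor_residues, other.receptor_residues)
            and np.array_equal(self.ligand_residues, other.ligand_residues)
        )


@dataclass
class DeltaContactMap:
    """Signed difference of two thresholded contact maps (A minus B)."""

    receptor_residues: np.ndarray
    ligand_residues: np.ndarray
    delta: np.ndarray
    threshold: float


def contact_frequency(
    traj: Trajectory,
    receptor_chain: str,
    ligand_chain: str,
    cutoff: float = 0.5,
    denominator: str = "all_frames",
    bound_mask: np.ndarray | None = None,
) -> ContactFrequencyMap:
    """Per-residue-pair contact fraction between two chains.

    ``denominator="bound_frames"`` restricts both the counting and the
    normalisation to frames flagged in ``bound_mask``.
    """
    top = traj.topology
    if receptor_chain not in top.chains or ligand_chain not in top.chains:
        raise ValueError("both chains must be present in the topology")
    if denominator not in ("all_frames", "bound_frames"):
        raise ValueError("denominator must be 'all_frames' or 'bound_frames'")
    sel_r = top.chain_particles(receptor_chain)
    sel_l = top.chain_particles(ligand_chain)
    rec_res, rec_codes = np.unique(top.residue_indices[sel_r], return_inverse=True)
    lig_res, lig_codes = np.unique(top.residue_indices[sel_l], return_inverse=True)

    if denominator == "bound_frames":
        if bound_mask is None:
            raise ValueError("bound_frames denominator requires a bound_mask")
        frame_mask = np.asarray(bound_mask, bool)
        if frame_mask.size != traj.n_frames:
            raise ValueError("bound_mask must have one flag per frame")
    else:
        frame_mask = np.ones(traj.n_frames, dtype=bool)
    n_denom = int(frame_mask.sum())
    if n_denom == 0:
        raise ValueError("no frames in the denominator")

    counts = np.zeros((rec_res.size, lig_res.size))
    for sl, d in iter_cross_distances(traj, sel_r, sel_l):
        keep = frame_mask[sl]
        if not keep.any():
            continue
        contact = d[keep] < cutoff
        pair = np.zeros((int(keep.sum()), rec_res.size, lig_res.size), dtype=bool)
        fidx, ii, jj = np.nonzero(contact)
        pair[fidx, rec_codes[ii], lig_codes[jj]] = True
        counts += pair.sum(axis=0)
    return ContactFrequencyMap(
        rec_res, lig_res, counts / n_denom, cutoff, n_denom, denominator
    )


def threshold_map(cmap: ContactFrequencyMap, tau: float) -> ContactFrequencyMap:
    """Zero every entry not strictly greater than ``tau``; keep survivors."""
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must lie in [0, 1)")
    kept = np.where(cmap.frequencies > tau, cmap.frequencies, 0.0)
    return ContactFrequencyMap(
        cmap.receptor_residues,
        cmap.ligand_residues,
        kept,
        cmap.cutoff,
        cmap.n_frames,
        cmap.denominator,
    )


def delta_map(
    map_a: ContactFrequencyMap, map_b: ContactFrequencyMap, tau: float
) -> DeltaContactMap:
    """Thresholded difference map A - B; positive = enriched in A."""
    if not map_a.same_axes(map_b):
        raise ValueError("contact maps have different residue axes")
    ta = threshold_map(map_a, tau)
    tb = threshold_map(map_b, tau)
    return DeltaContactMap(
        map_a.receptor_residues,
        map_a.ligand_residues,
        ta.frequencies - tb.frequencies,
        tau,
    )


def hotspots(
    cmap: ContactFrequencyMap, tau: float
) -> tuple[list[tuple[int, float]], list[tuple[int, float]]]:
    """Residues with at least one surviving contact after thresholding.

    Returns ``(receptor_hotspots, ligand_hotspots)``; each entry is
    ``(residue_index, peak_frequency)`` sorted by decreasing peak frequency
    (ties by residue index).
    """
    kept = threshold_map(cmap, tau).frequencies

    def collect(axis_residues: np.ndarray, peak: np.ndarray):
        out = [
            (int(res), float(p))
            for res, p in zip(axis_residues, peak)
            if p > 0.0
        ]
        out.sort(key=lambda t: (-t[1], t[0]))
        return out

    return (
        collect(cmap.receptor_residues, kept.max(axis=1, initial=0.0)),
        collect(cmap.ligand_residues, kept.max(axis=0, initial=0.0)),
    )
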