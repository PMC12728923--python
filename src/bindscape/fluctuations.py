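"""RMSD with subset fitting, per-residue RMSF, and ligand-core COM tracking."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import kabsch_superpose
from .collective_variables import CVSeries
from .model_io import Trajectory

__all__ = ["FitSpec", "rmsd_series", "rmsf", "com_track"]


@dataclass(frozen=True)
class FitSpec:
    """Which particles to fit on, which to measure, and the reference."""

    fit_sel: np.ndarray
    measure_sel: np.ndarray
    reference: str = "first_frame"  # or "mean_structure"

    def __post_init__(self) -> None:
        if np.asarray(self.fit_sel).size == 0 or np.asarray(self.measure_sel).size == 0:
            raise ValueError("fit and measure selections must be non-empty")
        if self.reference not in ("first_frame", "mean_structure"):
            raise ValueError("reference must be 'first_frame' or 'mean_structure'")


def _fit_all(traj: Trajectory, fit_sel: np.ndarray, ref_fit: np.ndarray) -> np.ndarray:
    """Superpose every full frame on a reference fit-selection geometry."""
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(ref_fit, traj.coordinates[f][fit_sel])
        out[f] = traj.coordinates[f] @ R.T + t
    return out


def rmsd_series(traj: Trajectory, spec: FitSpec) -> CVSeries:
    """Per-frame RMSD over the measure selection after subset fitting.

    Each frame is superposed on the fit selection of the reference (first
    frame, or the mean structure after a first-frame prealignment), then
    the RMSD is taken over the measure selection - so motion of the
    measured region relative to the fitted region is what is reported.
    """
    fit_sel = np.asarray(spec.fit_sel, int)
    measure_sel = np.asarray(spec.measure_sel, int)
    if spec.reference == "first_frame":
        ref_full = traj.coordinates[0]
    else:
        pre = _fit_all(traj, fit_sel, traj.coordinates[0][fit_sel])
        ref_full = pre.mean(axis=0)
    ref_fit = ref_full[fit_sel]
    ref_measure = ref_full[measure_sel]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(ref_fit, traj.coordinates[f][fit_sel])
        moved = traj.coordinates[f][measure_sel] @ R.T + t
        values[f] = np.sqrt(np.mean(np.sum((moved - ref_measure) ** 2, axis=1)))
    return CVSeries("rmsd", "nm", values, traj.times)


def rmsf(traj: Trajectory, sel: np.ndarray, fit_sel: np.ndarray | None = None):
    """Per-residue RMSF (nm) over a selection, fitted to the mean structure.

    Two-pass procedure: superpose all frames on the fit selection of frame
    0, compute the mean coordinates, re-superpose on the mean, then
    ``RMSF_i = sqrt(<|x_i - <x_i>|^2>)`` per particle, averaged over each
    residue's selected particles.  Returns a DataFrame with columns
    ``chain``, ``residue`` and ``rmsf_nm``.
    """
    import pandas as pd

    sel = np.asarray(sel, int)
    fit_sel = sel if fit_sel is None else np.asarray(fit_sel, int)
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    pass1 = _fit_all(traj, fit_sel, traj.coordinates[0][fit_sel])
    mean1 = pass1.mean(axis=0)
    pass2 = _fit_all(traj, fit_sel, mean1[fit_sel])
    mean2 = pass2.mean(axis=0)
    msf = np.mean(np.sum((pass2[:, sel, :] - mean2[sel]) ** 2, axis=2), axis=0)
    top = traj.topology
    df = pd.DataFrame(
        {
            "chain": top.chain_ids[sel],
            "residue": top.residue_indices[sel],
            "rmsf_nm": np.sqrt(msf),
        }
    )
    return df.groupby(["chain", "residue"], as_index=False, sort=True)[
        "rmsf_nm"
    ].mean()


def com_track(
    traj: Trajectory,
    core_sel: np.ndarray,
    n_samples: int = 150,
    bound_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Geometric centre of a core selection at uniformly spaced frames.

    With a bound mask, only bound frames are eligible (the bound-state
    convention for spatial-distribution dot plots).  If fewer eligible
    frames than requested exist, all of them are used with a warning.
    """
    core_sel = np.asarray(core_sel, int)
    if core_sel.size == 0:
        raise ValueError("core selection must be non-empty")
    eligible = (
        np.arange(traj.n_frames)
        if bound_mask is None
        else np.flatnonzero(np.asarray(bound_mask, bool))
    )
    if eligible.size == 0:
        warnings.warn("no eligible frames for COM tracking")
        return np.empty((0, 3))
    if eligible.size < n_samples:
        warnings.warn(
            f"only {eligible.size} eligible frames < n_samples={n_samples}; using all"
        )
        picked = eligible
    else:
        picked = eligible[
            np.linspace(0, eligible.size - 1, n_samples).round().astype(int)
        ]
    return traj.coordinates[picked][:, core_sel, :].mean(axis=1)
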