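"""Per-frame collective variables (CVs) for binding trajectories.

The workhorse CVs are the centre-of-mass separation ``d`` between receptor
and ligand and the smooth coordination number ``c``,

    c = sum_{i in A} sum_{j in B} s(r_ij),
    s(r) = (1 - x^n) / (1 - x^m),   x = (r - d0) / r0,

a rational switching function with defaults d0 = 0 nm, r0 = 0.9 nm, n = 6,
m = 12, which counts inter-group contacts in a continuous, differentiable
way.  Orientation-sensitive alternatives (N-terminal/N-terminal distance,
inter-chain orientation angle) and the minimum inter-particle distance are
provided for bound-state classification and ensemble descriptors.

Selections are particle-index arrays, typically produced by
:meth:`bindscape.model_io.RegionSet.indices`.  Centres of geometry are
unweighted: coarse-grained beads carry no masses here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .model_io import Trajectory

__all__ = [
    "SwitchingParams",
    "CVSeries",
    "switching_value",
    "coordination_number",
    "com_distance",
    "min_distance",
    "orientation_angle",
    "nterm_nterm_distance",
    "iter_cross_distances",
]

#: frames per chunk when streaming pair-distance blocks
_CHUNK = 512


@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function parameters (lengths in nm)."""

    d0: float = 0.0
    r0: float = 0.9
    n: int = 6
    m: int = 12

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not (self.m > self.n > 0):
            raise ValueError("need m > n > 0 for a decaying switching function")


@dataclass
class CVSeries:
    """One scalar per frame, with a name and unit for provenance."""

    name: str
    unit: str
    values: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("CVSeries values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CVSeries values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def switching_value(r, params: SwitchingParams = SwitchingParams()):
    """Evaluate the switching function s(r); scalar or array input.

    The removable singularity at x = 1 is bridged by the analytic limit
    n/m, applied on a guard band |x - 1| < 1e-6.  Distances below d0
    clamp to x = 0 and return 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    x = (r - params.d0) / params.r0
    x = np.clip(x, 0.0, None)
    near_one = np.abs(x - 1.0) < 1e-6
    x_safe = np.where(near_one, 2.0, x)  # dummy value off the singularity
    with np.errstate(over="ignore"):
        s = (1.0 - x_safe**params.n) / (1.0 - x_safe**params.m)
    s = np.where(near_one, params.n / params.m, s)
    # guard against overflow at huge x: s -> x^(n-m) -> 0
    s = np.where(np.isfinite(s), s, 0.0)
    return float(s) if s.ndim == 0 else s


def _check_selections(sel_a: np.ndarray, sel_b: np.ndarray, disjoint: bool = False):
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("selections must be non-empty")
    if disjoint and np.intersect1d(sel_a, sel_b).size:
        raise ValueError("selections overlap; cross-pair sums are undefined")
    return sel_a, sel_b


def iter_cross_distances(traj: Trajectory, sel_a, sel_b, chunk: int = _CHUNK):
    """Yield ``(frame_slice, dists)`` blocks of cross pair distances.

    ``dists`` has shape ``(n_frames_in_chunk, |A|, |B|)``; streaming keeps
    memory bounded for long trajectories.
    """
    sel_a, sel_b = _check_selections(sel_a, sel_b)
    coords = traj.coordinates
    for start in range(0, traj.n_frames, chunk):
        sl = slice(start, min(start + chunk, traj.n_frames))
        a = coords[sl][:, sel_a, :]
        b = coords[sl][:, sel_b, :]
        diff = a[:, :, None, :] - b[:, None, :, :]
        yield sl, np.sqrt(np.einsum("fijk,fijk->fij", diff, diff))


def coordination_number(
    traj: Trajectory,
    sel_a,
    sel_b,
    params: SwitchingParams = SwitchingParams(),
) -> CVSeries:
    """Smooth contact count between two disjoint selections, per frame."""
    sel_a, sel_b = _check_selections(sel_a, sel_b, disjoint=True)
    out = np.empty(traj.n_frames)
    for sl, d in iter_cross_distances(traj, sel_a, sel_b):
        out[sl] = switching_value(d, params).sum(axis=(1, 2))
    return CVSeries("coordination", "dimensionless", out, traj.times)


def com_distance(traj: Trajectory, sel_a, sel_b) -> CVSeries:
    """Distance between the geometric centres of two selections, per frame."""
    sel_a, sel_b = _check_selections(sel_a, sel_b)
    com_a = traj.coordinates[:, sel_a, :].mean(axis=1)
    com_b = traj.coordinates[:, sel_b, :].mean(axis=1)
    return CVSeries(
        "com_distance", "nm", np.linalg.norm(com_a - com_b, axis=1), traj.times
    )


def min_distance(traj: Trajectory, sel_a, sel_b) -> CVSeries:
    """Minimum cross-pair particle distance, per frame."""
    sel_a, sel_b = _check_selections(sel_a, sel_b)
    out = np.empty(traj.n_frames)
    for sl, d in iter_cross_distances(traj, sel_a, sel_b):
        out[sl] = d.min(axis=(1, 2))
    return CVSeries("min_distance", "nm", out, traj.times)


def orientation_angle(
    traj: Trajectory,
    n_anchor_a,
    c_anchor_a,
    n_anchor_b,
    c_anchor_b,
) -> CVSeries:
    """Angle between the two chains' N->C axis vectors, in degrees.

    Each axis runs from the centre of an N-anchor selection to the centre
    of a C-anchor selection; the angle is arccos of the normalised dot
    product, in [0, 180].
    """
    vecs = []
    for n_sel, c_sel in ((n_anchor_a, c_anchor_a), (n_anchor_b, c_anchor_b)):
        n_sel, c_sel = _check_selections(n_sel, c_sel)
        v = traj.coordinates[:, c_sel, :].mean(axis=1) - traj.coordinates[
            :, n_sel, :
        ].mean(axis=1)
        norm = np.linalg.norm(v, axis=1)
        if np.any(norm < 1e-12):
            raise ValueError("zero-length N->C vector; orientation angle undefined")
        vecs.append(v / norm[:, None])
    cosang = np.clip(np.einsum("ij,ij->i", vecs[0], vecs[1]), -1.0, 1.0)
    return CVSeries(
        "orientation_angle", "degrees", np.degrees(np.arccos(cosang)), traj.times
    )


def nterm_nterm_distance(traj: Trajectory, regions, topology=None) -> CVSeries:
    """Centre distance between the two N-terminal selections.

    Expects the region set to define ``RECEPTOR_NTERM_CV`` and
    ``LIGAND_NTERM_CV`` (backbone selections of the receptor N-terminal
    segment and the first ligand backbone particles); this is the
    orientation-sensitive replacement for the global COM distance.
    """
    top = topology or traj.topology
    for name in ("RECEPTOR_NTERM_CV", "LIGAND_NTERM_CV"):
        if name not in regions:
            raise ValueError(f"region set must define {name!r}")
    series = com_distance(
        traj,
        regions.indices(top, "RECEPTOR_NTERM_CV"),
        regions.indices(top, "LIGAND_NTERM_CV"),
    )
    series.name = "nterm_nterm_distance"
    return series
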