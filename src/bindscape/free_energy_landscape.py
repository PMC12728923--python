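"""2D free-energy landscapes by Boltzmann inversion of CV histograms.

The landscape over (COM distance d, coordination number c) is

    F(d, c) = -kB T ln P(d, c),

with P the normalised 2D histogram of the per-frame CV values, shifted so
the lowest occupied bin has F = 0.  Empty bins are masked (treated as
infinite energy), never reported as F = 0.  No smoothing is applied, so the
free-energy difference between two occupied bins is exactly
-kB T ln(count ratio).

Basins are grown from local minima: a basin is the connected component
(8-neighbour) of occupied bins within ``depth`` of its minimum; overlapping
components merge into the deeper minimum's basin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .collective_variables import CVSeries

__all__ = ["FELGrid", "Basin", "build_fel", "find_basins", "basin_frames", "KB_KJ_PER_MOL_K"]

KB_KJ_PER_MOL_K = 0.008314


@dataclass
class Basin:
    """One free-energy basin: its minimum bin, depth and total probability."""

    basin_id: int
    min_bin: tuple[int, int]
    min_free_energy: float
    d_center: float
    coord_center: float
    n_bins: int
    probability: float


@dataclass
class FELGrid:
    """Binned probability and free-energy surface over (d, coord)."""

    d_edges: np.ndarray
    coord_edges: np.ndarray
    counts: np.ndarray  # (nd, nc) integer histogram
    probability: np.ndarray  # normalised, sums to 1 over occupied bins
    free_energy: np.ndarray  # shifted so min occupied F = 0; inf where empty
    temperature: float  # K
    energy_unit: str  # "kT" or "kJ/mol"
    basin_labels: np.ndarray | None = None  # (nd, nc) int, 0 = unassigned
    basins: list[Basin] = field(default_factory=list)

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    @property
    def d_centers(self) -> np.ndarray:
        return 0.5 * (self.d_edges[:-1] + self.d_edges[1:])

    @property
    def coord_centers(self) -> np.ndarray:
        return 0.5 * (self.coord_edges[:-1] + self.coord_edges[1:])

    @property
    def kT(self) -> float:
        """One thermal energy quantum in the grid's energy unit."""
        return 1.0 if self.energy_unit == "kT" else KB_KJ_PER_MOL_K * self.temperature

    def basin_free_energy(self, basin_id: int) -> float:
        """-kBT ln of the total probability captured by a basin.

        Integrating the basin probability (rather than reading the minimum
        bin) makes the free-energy difference between two basins estimate
        the log population ratio directly.
        """
        basin = self._get_basin(basin_id)
        return -self.kT * np.log(basin.probability)

    def _get_basin(self, basin_id: int) -> Basin:
        for basin in self.basins:
            if basin.basin_id == basin_id:
                return basin
        raise KeyError(f"unknown basin id {basin_id}")


def _bin_edges(values: np.ndarray, bins: int, pad_fraction: float = 0.05) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    span = hi - lo
    if span == 0:  # degenerate axis: synthesise a small span
        span = max(abs(lo), 1.0) * 1e-6
    pad = pad_fraction * span
    return np.linspace(lo - pad, hi + pad, bins + 1)


def build_fel(
    d: CVSeries | np.ndarray,
    coord: CVSeries | np.ndarray,
    bins: tuple[int, int] = (60, 60),
    temperature: float = 303.0,
    energy_unit: str = "kT",
    d_edges: np.ndarray | None = None,
    coord_edges: np.ndarray | None = None,
) -> FELGrid:
    """Histogram two CV series and Boltzmann-invert into a free energy.

    Bin edges default to the observed range of each axis padded by 5 %;
    explicit edges allow several ensembles to share a common grid.
    """
    dv = np.asarray(getattr(d, "values", d), dtype=float)
    cv_ = np.asarray(getattr(coord, "values", coord), dtype=float)
    if dv.size != cv_.size:
        raise ValueError("CV series must have equal length")
    if dv.size == 0:
        raise ValueError("empty CV series")
    if bins[0] < 2 or bins[1] < 2:
        raise ValueError("need at least 2 bins per axis")
    if energy_unit not in ("kT", "kJ/mol"):
        raise ValueError("energy_unit must be 'kT' or 'kJ/mol'")
    if d_edges is None:
        d_edges = _bin_edges(dv, bins[0])
    if coord_edges is None:
        coord_edges = _bin_edges(cv_, bins[1])
    counts, _, _ = np.histogram2d(dv, cv_, bins=(d_edges, coord_edges))
    if np.count_nonzero(counts) == 1:
        warnings.warn("all frames fall in a single bin: degenerate landscape")
    prob = counts / counts.sum()
    kT = 1.0 if energy_unit == "kT" else KB_KJ_PER_MOL_K * temperature
    free = np.full_like(prob, np.inf)
    occ = counts > 0
    free[occ] = -kT * np.log(prob[occ])
    free[occ] -= free[occ].min()
    return FELGrid(d_edges, coord_edges, counts, prob, free, temperature, energy_unit)


_NEIGHBOURS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def find_basins(grid: FELGrid, depth: float = 2.0) -> list[Basin]:
    """Label free-energy basins on the grid (stored on ``grid`` and returned).

    Local minima are occupied bins whose F does not exceed any occupied
    8-neighbour.  Each basin is grown as the connected occupied component
    with F <= local-minimum F + ``depth``; a component that reaches an
    already-labelled bin merges into that (deeper) basin.
    """
    F = grid.free_energy
    occ = grid.occupied
    nd, nc = F.shape
    labels = np.zeros((nd, nc), dtype=int)

    def neighbours(i: int, j: int):
        for di, dj in _NEIGHBOURS:
            ni, nj = i + di, j + dj
            if 0 <= ni < nd and 0 <= nj < nc:
                yield ni, nj

    minima = []
    for i in range(nd):
        for j in range(nc):
            if not occ[i, j]:
                continue
            if all(F[i, j] <= F[ni, nj] for ni, nj in neighbours(i, j) if occ[ni, nj]):
                minima.append((F[i, j], i, j))
    minima.sort()  # ascending F: deepest minima claim their bins first

    basins: list[Basin] = []
    next_id = 1
    for fmin, i0, j0 in minima:
        if labels[i0, j0]:
            continue  # already swallowed by a deeper basin
        # flood the component with F <= fmin + depth
        stack = [(i0, j0)]
        component = []
        seen = {(i0, j0)}
        merged_into = 0
        while stack:
            i, j = stack.pop()
            if labels[i, j]:
                merged_into = labels[i, j]
                continue
            component.append((i, j))
            for ni, nj in neighbours(i, j):
                if (ni, nj) not in seen and occ[ni, nj] and F[ni, nj] <= fmin + depth:
                    seen.add((ni, nj))
                    stack.append((ni, nj))
        if merged_into:
            label = merged_into
            for i, j in component:
                labels[i, j] = label
            target = next(b for b in basins if b.basin_id == label)
            target.n_bins += len(component)
            target.probability += float(
                sum(grid.probability[i, j] for i, j in component)
            )
        else:
            label = next_id
            next_id += 1
            for i, j in component:
                labels[i, j] = label
            basins.append(
                Basin(
                    basin_id=label,
                    min_bin=(i0, j0),
                    min_free_energy=float(fmin),
                    d_center=float(grid.d_centers[i0]),
                    coord_center=float(grid.coord_centers[j0]),
                    n_bins=len(component),
                    probability=float(
                        sum(grid.probability[i, j] for i, j in component)
                    ),
                )
            )
    grid.basin_labels = labels
    grid.basins = basins
    return basins


def basin_frames(
    grid: FELGrid,
    basin_id: int,
    d: CVSeries | np.ndarray,
    coord: CVSeries | np.ndarray,
) -> np.ndarray:
    """Indices of frames whose (d, coord) falls in a basin's bins."""
    if grid.basin_labels is None:
        raise ValueError("run find_basins first")
    grid._get_basin(basin_id)  # raises KeyError on unknown id
    dv = np.asarray(getattr(d, "values", d), dtype=float)
    cv_ = np.asarray(getattr(coord, "values", coord), dtype=float)
    di = np.digitize(dv, grid.d_edges) - 1
    cj = np.digitize(cv_, grid.coord_edges) - 1
    nd, nc = grid.counts.shape
    inside = (di >= 0) & (di < nd) & (cj >= 0) & (cj < nc)
    out = np.zeros(dv.size, dtype=bool)
    out[inside] = grid.basin_labels[di[inside], cj[inside]] == basin_id
    return np.flatnonzero(out)
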