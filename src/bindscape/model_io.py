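"""Shared data model and file I/O.

Topologies and trajectories are held in memory as a :class:`Topology`
(per-particle labels) plus a dense ``(n_frames, n_particles, 3)`` coordinate
array in nanometres.  Residue indices follow author (1-based) numbering
verbatim from the input file; nothing is ever re-indexed on read.

Supported trajectory formats:

* multi-model PDB (``MODEL``/``ENDMDL`` delimits frames), read and written
  through :mod:`biotite` with an A <-> nm conversion at the boundary;
* a plain-text XYZ-frames format: first line ``N``, second line ``t=<ns>``,
  then ``N`` lines ``chain resid resname name x y z`` with coordinates in nm.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Particle",
    "Topology",
    "Frame",
    "Trajectory",
    "RegionSet",
    "Region",
    "read_topology_and_frames",
    "write_frames",
    "load_regions",
    "regions_from_dict",
    "write_table",
    "read_table",
    "ANGSTROM_PER_NM",
]

ANGSTROM_PER_NM = 10.0

#: atom/bead names treated as backbone particles
BACKBONE_NAMES = frozenset({"BB", "CA", "C", "N", "O"})


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared format."""


@dataclass(frozen=True)
class Particle:
    """One atom or coarse-grained bead."""

    particle_id: int
    name: str
    residue_index: int  # 1-based author numbering
    residue_name: str
    chain_id: str
    is_backbone: bool = True


class Topology:
    """Ordered collection of particles with chain/residue bookkeeping."""

    def __init__(self, particles: Sequence[Particle]):
        particles = list(particles)
        ids = [p.particle_id for p in particles]
        if len(set(ids)) != len(ids):
            raise ValueError("particle_id values must be unique within a topology")
        self.particles: list[Particle] = particles
        self.chain_ids = np.array([p.chain_id for p in particles])
        self.residue_indices = np.array([p.residue_index for p in particles], dtype=int)
        self.residue_names = np.array([p.residue_name for p in particles])
        self.names = np.array([p.name for p in particles])
        self.backbone_mask = np.array([p.is_backbone for p in particles], dtype=bool)
        # residue numbering must be non-decreasing within each chain
        for cid in self.chains:
            resid = self.residue_indices[self.chain_ids == cid]
            if np.any(np.diff(resid) < 0):
                raise ValueError(f"residue indices decrease within chain {cid!r}")

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def chains(self) -> set[str]:
        return set(self.chain_ids.tolist())

    def chain_particles(self, chain_id: str) -> np.ndarray:
        """Indices of all particles in a chain, in file order."""
        return np.flatnonzero(self.chain_ids == chain_id)

    def chain_residues(self, chain_id: str) -> np.ndarray:
        """Sorted unique author residue indices of a chain."""
        return np.unique(self.residue_indices[self.chain_ids == chain_id])

    def select(
        self,
        chain_id: str,
        residues: Iterable[int] | None = None,
        backbone_only: bool = False,
    ) -> np.ndarray:
        """Particle indices matching chain, residue set and backbone filter."""
        mask = self.chain_ids == chain_id
        if residues is not None:
            mask &= np.isin(self.residue_indices, np.fromiter(residues, dtype=int))
        if backbone_only:
            mask &= self.backbone_mask
        return np.flatnonzero(mask)


@dataclass
class Frame:
    """A single snapshot: coordinates in nm plus optional box and time."""

    coordinates: np.ndarray  # (n_particles, 3), nm
    time: float = 0.0  # ns
    box: np.ndarray | None = None  # orthorhombic lengths, nm

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_particles, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


class Trajectory:
    """A topology with an ordered stack of frames.

    Coordinates are stored as one dense float array ``(n_frames, n, 3)``.
    """

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        times: np.ndarray | None = None,
        box: np.ndarray | None = None,
    ):
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.ndim != 3 or coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_particles, 3)")
        if coordinates.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if coordinates.shape[1] != topology.n_particles:
            raise ValueError(
                f"coordinate count {coordinates.shape[1]} != particle count "
                f"{topology.n_particles}"
            )
        if not np.all(np.isfinite(coordinates)):
            raise ValueError("coordinates must be finite")
        if times is None:
            times = np.arange(coordinates.shape[0], dtype=float)
        times = np.asarray(times, dtype=float)
        if times.shape[0] != coordinates.shape[0]:
            raise ValueError("one time per frame required")
        if np.any(np.diff(times) < 0):
            raise ValueError("frame times must be non-decreasing")
        self.topology = topology
        self.coordinates = coordinates
        self.times = times
        self.box = None if box is None else np.asarray(box, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], time=float(self.times[i]), box=self.box)

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def subset_frames(self, indices: Sequence[int]) -> "Trajectory":
        idx = np.asarray(indices, dtype=int)
        return Trajectory(self.topology, self.coordinates[idx], self.times[idx], self.box)


# ---------------------------------------------------------------------------
# Regions


@dataclass(frozen=True)
class Region:
    """A named residue-range selection on one chain."""

    chain_id: str
    ranges: tuple[tuple[int, int], ...]  # inclusive (start, stop) author numbering
    backbone_only: bool = False

    def residues(self) -> np.ndarray:
        """Sorted union of all residue indices covered by the ranges."""
        out: set[int] = set()
        for start, stop in self.ranges:
            out.update(range(start, stop + 1))
        return np.array(sorted(out), dtype=int)


class RegionSet:
    """Mapping of region name -> :class:`Region`, validated against a topology."""

    def __init__(self, regions: Mapping[str, Region], topology: Topology | None = None):
        self._regions = dict(regions)
        if topology is not None:
            self.validate(topology)

    def __contains__(self, name: str) -> bool:
        return name in self._regions

    def __getitem__(self, name: str) -> Region:
        return self._regions[name]

    def names(self) -> list[str]:
        return list(self._regions)

    def validate(self, topology: Topology) -> None:
        """Ensure every referenced residue exists; list offenders otherwise."""
        problems = []
        for name, region in self._regions.items():
            if not region.ranges:
                problems.append(f"{name}: empty range list")
                continue
            present = set(topology.chain_residues(region.chain_id).tolist())
            missing = [int(r) for r in region.residues() if r not in present]
            if missing:
                problems.append(
                    f"{name}: residues {missing} absent from chain {region.chain_id!r}"
                )
        if problems:
            raise ValueError("invalid region definitions: " + "; ".join(problems))

    def indices(self, topology: Topology, name: str) -> np.ndarray:
        """Particle indices selected by a named region."""
        region = self._regions[name]
        return topology.select(
            region.chain_id, region.residues(), backbone_only=region.backbone_only
        )


def regions_from_dict(
    data: Mapping[str, Mapping], topology: Topology | None = None
) -> RegionSet:
    """Build a RegionSet from a plain mapping (the YAML schema).

    Schema per region::

        NAME:
          chain: A
          ranges: [[1, 31]]          # inclusive, author numbering
          backbone_only: false       # optional
    """
    regions: dict[str, Region] = {}
    for name, entry in data.items():
        try:
            chain = str(entry["chain"])
            raw_ranges = entry["ranges"]
        except (KeyError, TypeError) as exc:
            raise ValueError(f"region {name!r}: need 'chain' and 'ranges'") from exc
        if not raw_ranges:
            raise ValueError(f"region {name!r}: empty range list")
        ranges = []
        for rng in raw_ranges:
            if isinstance(rng, int):
                start = stop = int(rng)
            else:
                start, stop = (int(rng[0]), int(rng[-1]))
            if stop < start:
                raise ValueError(f"region {name!r}: range {rng} runs backwards")
            ranges.append((start, stop))
        regions[name] = Region(
            chain_id=chain,
            ranges=tuple(ranges),
            backbone_only=bool(entry.get("backbone_only", False)),
        )
    return RegionSet(regions, topology)


def load_regions(path: str | os.PathLike, topology: Topology | None = None) -> RegionSet:
    """Load region definitions from a YAML config file.

    When a topology is given, every referenced residue is checked for
    existence and a validation error lists the offending residues.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping) or not data:
        raise ValueError(f"{path}: region config must be a non-empty mapping")
    return regions_from_dict(data, topology)


# ---------------------------------------------------------------------------
# Trajectory I/O


def _detect_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".pdb":
        return "pdb_multimodel"
    if ext in {".xyz", ".xyzf"}:
        return "xyz_frames"
    raise ValueError(f"cannot infer trajectory format from {path!r}; pass format=")


def read_topology_and_frames(
    path: str | os.PathLike, format: str | None = None
) -> Trajectory:
    """Read a multi-model PDB or XYZ-frames file into a Trajectory."""
    fmt = _detect_format(path, format)
    if fmt == "pdb_multimodel":
        return _read_pdb(path)
    if fmt == "xyz_frames":
        return _read_xyz_frames(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def write_frames(
    traj: Trajectory, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a Trajectory as multi-model PDB or XYZ-frames."""
    fmt = _detect_format(path, format)
    if fmt == "pdb_multimodel":
        _write_pdb(traj, path)
    elif fmt == "xyz_frames":
        _write_xyz_frames(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def _read_pdb(path: str | os.PathLike) -> Trajectory:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises assorted parse exceptions
        raise ParseError(f"{path}: malformed PDB ({exc})") from exc
    if isinstance(stack, struc.AtomArray):  # single model
        arr0 = stack
        coords = stack.coord[None, :, :]
    else:
        if stack.stack_depth() == 0:
            raise ParseError(f"{path}: no models found")
        arr0 = stack[0]
        coords = stack.coord
    particles = [
        Particle(
            particle_id=i,
            name=str(arr0.atom_name[i]),
            residue_index=int(arr0.res_id[i]),
            residue_name=str(arr0.res_name[i]),
            chain_id=str(arr0.chain_id[i]),
            is_backbone=str(arr0.atom_name[i]) in BACKBONE_NAMES,
        )
        for i in range(arr0.array_length())
    ]
    return Trajectory(Topology(particles), coords / ANGSTROM_PER_NM)


def _write_pdb(traj: Trajectory, path: str | os.PathLike) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    top = traj.topology
    n = top.n_particles
    arrays = []
    for f in range(traj.n_frames):
        arr = struc.AtomArray(n)
        arr.coord = traj.coordinates[f] * ANGSTROM_PER_NM
        arr.chain_id = top.chain_ids
        arr.res_id = top.residue_indices
        arr.res_name = top.residue_names
        arr.atom_name = top.names
        arr.element = np.array(["C"] * n)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _read_xyz_frames(path: str | os.PathLike) -> Trajectory:
    particles: list[Particle] | None = None
    frames: list[np.ndarray] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    lineno = 0
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(f"{path}:{pos + 1}: expected particle count") from exc
        if pos + 1 >= len(lines) or not lines[pos + 1].strip().startswith("t="):
            raise ParseError(f"{path}:{pos + 2}: expected 't=<ns>' comment line")
        times.append(float(lines[pos + 1].strip()[2:]))
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}:{pos + 2 + len(block)}: truncated frame")
        coords = np.empty((n, 3))
        frame_particles: list[Particle] = []
        for i, line in enumerate(block):
            lineno = pos + 3 + i
            fields = line.split()
            if len(fields) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 fields, got {len(fields)}")
            chain, resid, resname, name = fields[:4]
            try:
                coords[i] = [float(v) for v in fields[4:]]
                resid_i = int(resid)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad numeric field") from exc
            frame_particles.append(
                Particle(
                    particle_id=i,
                    name=name,
                    residue_index=resid_i,
                    residue_name=resname,
                    chain_id=chain,
                    is_backbone=name in BACKBONE_NAMES,
                )
            )
        if particles is None:
            particles = frame_particles
        frames.append(coords)
        pos += 2 + n
    if particles is None:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(Topology(particles), np.stack(frames), np.array(times))


def _write_xyz_frames(traj: Trajectory, path: str | os.PathLike) -> None:
    top = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{top.n_particles}\n")
            fh.write(f"t={traj.times[f]:.6f}\n")
            for i in range(top.n_particles):
                x, y, z = traj.coordinates[f, i]
                fh.write(
                    f"{top.chain_ids[i]} {top.residue_indices[i]} "
                    f"{top.residue_names[i]} {top.names[i]} "
                    f"{x:.9g} {y:.9g} {z:.9g}\n"
                )


# ---------------------------------------------------------------------------
# Tabular output


def write_table(records, path: str | os.PathLike, format: str | None = None) -> None:
    """Write homogeneous records to CSV or JSON.

    Floats keep >= 9 significant digits; NaN is serialised as an empty CSV
    field / JSON ``null`` and restored as NaN by :func:`read_table`.
    """
    fmt = format or os.path.splitext(str(path))[1].lstrip(".").lower()
    df = pd.DataFrame(records)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        cleaned = df.where(pd.notna(df), None)
        with open(path, "w") as fh:
            json.dump(cleaned.to_dict(orient="records"), fh, indent=1, default=_jsonify)
    else:
        raise ValueError(f"unknown table format {fmt!r}")


def _jsonify(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        v = float(value)
        return None if math.isnan(v) else v
    raise TypeError(f"cannot serialise {type(value)}")


def read_table(path: str | os.PathLike, format: str | None = None) -> pd.DataFrame:
    fmt = format or os.path.splitext(str(path))[1].lstrip(".").lower()
    if fmt == "csv":
        return pd.read_csv(path, float_precision="round_trip")
    if fmt == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown table format {fmt!r}")
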