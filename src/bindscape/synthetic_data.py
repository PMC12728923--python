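"""Synthetic receptor-ligand binding trajectories with known ground truth.

The toy system emulates a membrane-anchored chemokine-like receptor bound by
a small rigid protein ligand:

* the receptor (chain ``R``) is a static bead model with a transmembrane
  core stub, three extracellular loops (the CRS2 recognition site) and a
  long N-terminal arm (the CRS1 recognition site);
* the ligand (chain ``L``) is a rigid three-strand sheet with labelled
  subregions (``BETA1``, ``LOOP3``, ``CTERM``) mimicking the
  beta1-strand / loop3 / C-terminal recognition elements of a chemerin-like
  ligand.

Two generators cover complementary ground truths:

* :func:`sample_mixture` draws i.i.d. frames from a mixture of rigid bound
  poses plus a diffuse unbound shell.  Pose weights are exact stationary
  populations, so free-energy differences, contact frequencies and cluster
  sizes are known in closed form.
* :func:`simulate_langevin` integrates overdamped rigid-body dynamics of
  the ligand in attractive wells anchored at the two recognition sites,
  optionally gating the CRS2 well on prior CRS1 engagement; it supplies the
  temporal ground truth (engagement ordering, dwell structure).

The receptor is static (infinite friction), mirroring a membrane-embedded
receptor with restrained termini; this isolates ligand-association
statistics from receptor internal motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .model_io import Particle, RegionSet, Topology, Trajectory, regions_from_dict

__all__ = [
    "ToyComplex",
    "Placement",
    "MixtureSpec",
    "LangevinSpec",
    "BindingEventLog",
    "InstabilityError",
    "make_toy_complex",
    "make_default_poses",
    "default_mixture_spec",
    "designed_contacts",
    "place_ligand",
    "sample_mixture",
    "simulate_langevin",
]

UNBOUND_LABEL = -1


class InstabilityError(RuntimeError):
    """Raised when integrator steps are too large for the repulsive core."""


# ---------------------------------------------------------------------------
# Toy complex geometry


def _receptor_coords() -> np.ndarray:
    """Bead coordinates (nm) for the 76-residue receptor model."""
    coords = []
    # N-terminal arm, residues 1-31: residue 1 at the distal (extracellular) tip
    tip, base = np.array([1.6, 0.0, 3.4]), np.array([1.1, 0.0, 0.4])
    for k in range(31):
        coords.append(tip + (base - tip) * k / 30.0)
    # extracellular loops, residues 32-52: arcs on a ring (radius 1 nm, z=0.4)
    for center_deg, n in ((45.0, 7), (135.0, 7), (270.0, 7)):
        angles = np.radians(center_deg + np.linspace(-25.0, 25.0, n))
        for a in angles:
            coords.append(np.array([np.cos(a), np.sin(a), 0.4]))
    # transmembrane core stub, residues 53-76: four 6-bead helices going down
    for helix_deg in (0.0, 90.0, 180.0, 270.0):
        a = np.radians(helix_deg)
        for k in range(6):
            coords.append(np.array([np.cos(a), np.sin(a), -0.25 * (k + 1)]))
    return np.array(coords)


def _ligand_local_coords() -> np.ndarray:
    """Ligand beads in the body frame: three strands, centred at the origin."""
    coords = []
    for y, z in ((0.0, 0.0), (0.6, 0.15), (1.2, 0.0)):  # beta1, loop3, cterm
        for i in range(8):
            coords.append(np.array([0.3 * i, y, z]))
    coords = np.array(coords)
    return coords - coords.mean(axis=0)


_REGION_SCHEMA = {
    # receptor chain R
    "CRS1": {"chain": "R", "ranges": [[1, 31]]},
    "ECL1": {"chain": "R", "ranges": [[32, 38]]},
    "ECL2": {"chain": "R", "ranges": [[39, 45]]},
    "ECL3": {"chain": "R", "ranges": [[46, 52]]},
    "CRS2": {"chain": "R", "ranges": [[32, 52]]},
    "CORE": {"chain": "R", "ranges": [[53, 76]]},
    "RECEPTOR_ALL": {"chain": "R", "ranges": [[1, 76]]},
    "RECEPTOR_BB": {"chain": "R", "ranges": [[1, 76]], "backbone_only": True},
    "RECEPTOR_NTERM_CV": {"chain": "R", "ranges": [[10, 20]], "backbone_only": True},
    "RECEPTOR_N_ANCHOR": {"chain": "R", "ranges": [[1, 3]]},
    "RECEPTOR_C_ANCHOR": {"chain": "R", "ranges": [[74, 76]]},
    # ligand chain L
    "BETA1": {"chain": "L", "ranges": [[1, 8]]},
    "LOOP3": {"chain": "L", "ranges": [[9, 16]]},
    "CTERM": {"chain": "L", "ranges": [[17, 24]]},
    "LIGAND_ALL": {"chain": "L", "ranges": [[1, 24]]},
    "LIGAND_BB": {"chain": "L", "ranges": [[1, 24]], "backbone_only": True},
    "LIGAND_NTERM_CV": {"chain": "L", "ranges": [[1, 10]], "backbone_only": True},
    "LIGAND_N_ANCHOR": {"chain": "L", "ranges": [[1, 2]]},
    "LIGAND_C_ANCHOR": {"chain": "L", "ranges": [[23, 24]]},
}


def region_schema() -> dict:
    """The toy complex's region definitions in the YAML config schema."""
    return {name: dict(entry) for name, entry in _REGION_SCHEMA.items()}


@dataclass
class ToyComplex:
    """Static receptor beads plus a rigid ligand bead cluster."""

    topology: Topology
    receptor_coords: np.ndarray  # (n_rec, 3) nm, fixed
    ligand_local: np.ndarray  # (n_lig, 3) nm, centred body frame
    regions: RegionSet
    jitter_sigma: float = 0.03  # nm, per-bead thermal noise

    @property
    def n_receptor(self) -> int:
        return self.receptor_coords.shape[0]

    @property
    def n_ligand(self) -> int:
        return self.ligand_local.shape[0]

    @property
    def ligand_slice(self) -> slice:
        return slice(self.n_receptor, self.n_receptor + self.n_ligand)


def make_toy_complex(jitter_sigma: float = 0.03) -> ToyComplex:
    """Build the standard two-chain toy complex with labelled regions."""
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be non-negative")
    rec = _receptor_coords()
    lig = _ligand_local_coords()
    particles = [
        Particle(i, "BB", i + 1, "ALA", "R") for i in range(rec.shape[0])
    ] + [
        Particle(rec.shape[0] + i, "BB", i + 1, "ALA", "L")
        for i in range(lig.shape[0])
    ]
    topology = Topology(particles)
    regions = regions_from_dict(_REGION_SCHEMA, topology)
    return ToyComplex(topology, rec, lig, regions, jitter_sigma)


@dataclass(frozen=True)
class Placement:
    """Rigid placement of the ligand body frame into the receptor frame."""

    name: str
    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,) nm, ligand COM position

    def apply(self, local: np.ndarray) -> np.ndarray:
        return local @ np.asarray(self.rotation).T + np.asarray(self.translation)


def place_ligand(complex_: ToyComplex, placement: Placement) -> np.ndarray:
    """Full-system coordinates (receptor + placed ligand), noise-free."""
    return np.vstack([complex_.receptor_coords, placement.apply(complex_.ligand_local)])


def _solve_approach(
    complex_: ToyComplex,
    rotation: np.ndarray,
    anchor: np.ndarray,
    direction: np.ndarray,
    gap: float,
) -> np.ndarray:
    """Smallest outward COM offset with every receptor-ligand gap >= ``gap``.

    Walks the ligand COM along ``anchor + t * direction`` and returns the
    first translation at which no bead pair is closer than ``gap``; the
    pairs sitting exactly at the gap define the designed contacts.
    """
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    local = complex_.ligand_local @ np.asarray(rotation).T
    for t in np.arange(0.0, 8.0, 0.005):
        pos = anchor + t * u
        dmin = cdist(local + pos, complex_.receptor_coords).min()
        if dmin >= gap:
            return pos
    raise RuntimeError("no clash-free placement found along approach axis")


def make_default_poses(complex_: ToyComplex, gap: float = 0.35) -> list[Placement]:
    """Two designed bound poses with distinct interfaces.

    * ``poseA``: ligand tilted so its BETA1 edge rests on the ECL2 loop
      (the dominant loop interface of the bound state);
    * ``poseB``: ligand docked sideways against the middle of the CRS1
      N-terminal arm through its CTERM edge.
    """
    top = complex_.topology
    ecl2 = complex_.receptor_coords[complex_.regions.indices(top, "ECL2")]
    rot_a = Rotation.from_euler("x", 35, degrees=True).as_matrix()
    pos_a = _solve_approach(complex_, rot_a, ecl2.mean(axis=0), [0.0, 0.0, 1.0], gap)

    crs1 = complex_.receptor_coords[complex_.regions.indices(top, "CRS1")]
    # anchor at the arm bead nearest z = 2 nm, approach radially outward
    anchor = crs1[np.argmin(np.abs(crs1[:, 2] - 2.0))]
    rot_b = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    pos_b = _solve_approach(complex_, rot_b, anchor, [1.0, 0.0, 0.0], gap)
    return [
        Placement("poseA", rot_a, pos_a),
        Placement("poseB", rot_b, pos_b),
    ]


def make_docked_pose(complex_: ToyComplex, gap: float = 0.35) -> Placement:
    """Two-site bound pose wedged between the CRS1 arm base and ECL1.

    The final state of the two-step mechanism keeps the first recognition
    site engaged while the second forms, so this placement contacts both
    the lower N-terminal arm and the nearest extracellular loop.
    """
    rot = Rotation.from_euler("x", 60, degrees=True).as_matrix()
    pos = _solve_approach(
        complex_, rot, np.array([1.0, 0.2, 0.4]), [0.3, 0.1, 0.2], gap
    )
    return Placement("poseAB", rot, pos)


def designed_contacts(
    complex_: ToyComplex, placement: Placement, cutoff: float = 0.5
) -> set[tuple[int, int]]:
    """Residue pairs (receptor_resid, ligand_resid) in contact, noise-free."""
    top = complex_.topology
    lig = placement.apply(complex_.ligand_local)
    d = cdist(complex_.receptor_coords, lig)
    rec_resid = top.residue_indices[: complex_.n_receptor]
    lig_resid = top.residue_indices[complex_.ligand_slice]
    ii, jj = np.nonzero(d < cutoff)
    return {(int(rec_resid[i]), int(lig_resid[j])) for i, j in zip(ii, jj)}


# ---------------------------------------------------------------------------
# Mixture sampler


@dataclass
class MixtureSpec:
    """I.i.d. frame sampler: bound poses with weights plus an unbound shell."""

    poses: Sequence[Placement]
    weights: Sequence[float]  # one per pose
    unbound_weight: float = 0.0
    shell_r_min: float = 6.0  # nm, inner radius of the unbound COM shell
    shell_r_max: float = 9.0
    n_frames: int = 50_000
    seed: int = 0
    frame_dt: float = 1.0  # ns between frames (bookkeeping only)

    def __post_init__(self) -> None:
        w = np.asarray(list(self.weights) + [self.unbound_weight], float)
        if np.any(w < 0):
            raise ValueError("mixture weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {w.sum()}, expected 1")
        if len(self.poses) != len(self.weights):
            raise ValueError("one weight per pose required")
        if self.unbound_weight > 0 and not (self.shell_r_max > self.shell_r_min > 0):
            raise ValueError("need shell_r_max > shell_r_min > 0")


def default_mixture_spec(
    complex_: ToyComplex, n_frames: int = 50_000, seed: int = 0
) -> MixtureSpec:
    """Study conditions: two bound poses (60 % / 30 %) plus 10 % unbound."""
    poses = make_default_poses(complex_)
    return MixtureSpec(
        poses=poses,
        weights=[0.6, 0.3],
        unbound_weight=0.1,
        n_frames=n_frames,
        seed=seed,
    )


def sample_mixture(
    spec: MixtureSpec, complex_: ToyComplex
) -> tuple[Trajectory, np.ndarray]:
    """Draw i.i.d. frames; returns the trajectory and per-frame labels.

    Labels are pose indices (0-based, order of ``spec.poses``) or
    ``UNBOUND_LABEL`` (-1) for shell frames.  Per-bead Gaussian jitter of
    ``complex_.jitter_sigma`` is applied to every bead of every frame.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    k = len(spec.poses)
    weights = np.asarray(list(spec.weights) + [spec.unbound_weight], float)
    choice = rng.choice(k + 1, size=n, p=weights)
    labels = np.where(choice == k, UNBOUND_LABEL, choice)

    n_total = complex_.n_receptor + complex_.n_ligand
    coords = np.empty((n, n_total, 3))
    coords[:, : complex_.n_receptor, :] = complex_.receptor_coords

    lig = complex_.ligand_slice
    for p, pose in enumerate(spec.poses):
        idx = np.flatnonzero(labels == p)
        coords[idx, lig, :] = pose.apply(complex_.ligand_local)

    unbound = np.flatnonzero(labels == UNBOUND_LABEL)
    if unbound.size:
        # uniform orientation and COM uniform in the spherical shell volume
        mats = Rotation.random(num=unbound.size, random_state=rng).as_matrix()
        direction = rng.normal(size=(unbound.size, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radius = np.cbrt(
            rng.uniform(spec.shell_r_min**3, spec.shell_r_max**3, unbound.size)
        )
        coms = direction * radius[:, None]
        coords[unbound, lig, :] = (
            np.einsum("kij,mj->kmi", mats, complex_.ligand_local) + coms[:, None, :]
        )

    if complex_.jitter_sigma > 0:
        coords += rng.normal(scale=complex_.jitter_sigma, size=coords.shape)

    traj = Trajectory(
        complex_.topology, coords, times=np.arange(n) * spec.frame_dt
    )
    return traj, labels


# ---------------------------------------------------------------------------
# Langevin binder


@dataclass
class LangevinSpec:
    """Overdamped rigid-body ligand dynamics with capture-and-dock binding.

    While free, the ligand diffuses in attractive Gaussian wells anchored
    at the CRS1 (N-terminal arm) beads - and, when ``gated=False``, also
    the CRS2 (loop) beads.  The first CRS1 contact captures the ligand:
    it relaxes onto the designed CRS1-bound pose and, after a residence of
    ``gate_delay_steps`` (the two-step mechanism's dwell at the first
    recognition site), docks into the two-site pose that keeps CRS1
    engaged while CRS2 forms.  In the bound state the effective mobility
    is reduced by ``bound_mobility_factor`` (bound ligands feel higher
    friction), so engagement, once formed, persists.  A soft-core
    bead-bead repulsion plus an exact post-step projection keep the rigid
    bodies from interpenetrating.  Lengths nm, energies kBT, time ns.
    """

    well_depth_crs1: float = 0.3  # kBT per CRS1 receptor bead
    well_range_crs1: float = 2.0  # nm (Gaussian sigma)
    well_depth_crs2: float = 0.6
    well_range_crs2: float = 0.8
    gated: bool = True
    gate_delay_steps: int = 5000  # CRS1 residence before two-site docking
    tether_relax: float = 0.05  # per-step fractional relaxation to the dock pose
    orient_relax: float = 0.02  # per-step fractional orientation relaxation
    bound_mobility_factor: float = 0.15  # translational D scale when docked
    repulsion_radius: float = 0.4  # nm bead-bead core
    repulsion_k: float = 200.0  # kBT / nm^2 soft shoulder
    diffusion: float = 0.05  # nm^2 / ns translational
    rot_sigma: float = 0.03  # rad per step
    dt: float = 0.02  # ns
    n_steps: int = 40_000
    stride: int = 10  # steps between recorded frames
    box: tuple = ((-5.0, 5.0), (-5.0, 5.0), (-2.5, 8.0))  # reflecting walls
    start_position: tuple = (1.5, 0.0, 6.5)
    contact_cutoff: float = 0.5  # nm, event-log contact criterion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gated and not self.well_range_crs1 > self.well_range_crs2:
            raise ValueError(
                "ordering ground truth requires well_range_crs1 > well_range_crs2"
            )


@dataclass
class BindingEventLog:
    """First frame at which each recognition site forms a contact.

    Contacts are detected every integration step; the reported index is
    the recorded-frame index containing that step, so events separated by
    less than one stride still order correctly via ``first_steps``.
    """

    crs1_first_frame: int | None
    crs2_first_frame: int | None
    crs1_first_step: int | None = None
    crs2_first_step: int | None = None

    @property
    def ordering(self) -> str:
        a = self.crs1_first_step if self.crs1_first_step is not None else self.crs1_first_frame
        b = self.crs2_first_step if self.crs2_first_step is not None else self.crs2_first_frame
        if a is None and b is None:
            return "none"
        if b is None or (a is not None and a < b):
            return "CRS1_first"
        if a is None or b < a:
            return "CRS2_first"
        return "simultaneous"


def simulate_langevin(
    spec: LangevinSpec, complex_: ToyComplex
) -> tuple[Trajectory, BindingEventLog]:
    """Integrate x <- x - D grad(U) dt / kBT + sqrt(2 D dt) xi for the ligand COM.

    Small random rigid rotations are applied each step; walls reflect the
    COM.  Raises :class:`InstabilityError` when more than 0.1 % of steps
    displace the COM by over half the repulsion radius (advice: reduce dt).
    """
    rng = np.random.default_rng(spec.seed)
    top = complex_.topology
    rec = complex_.receptor_coords
    crs1 = complex_.regions.indices(top, "CRS1")
    crs2 = complex_.regions.indices(top, "CRS2")
    rec_crs1 = rec[crs1]
    rec_crs2 = rec[crs2]

    crs1_pose = make_default_poses(complex_)[1]  # CTERM docked on the arm
    two_site_pose = make_docked_pose(complex_)

    local0 = complex_.ligand_local
    orientation = Rotation.identity()
    com = np.array(spec.start_position, float)
    box = np.asarray(spec.box, float)

    noise_scale = np.sqrt(2.0 * spec.diffusion * spec.dt)
    n_frames = spec.n_steps // spec.stride
    coords = np.empty((n_frames, top.n_particles, 3))
    coords[:, : complex_.n_receptor, :] = rec
    times = np.empty(n_frames)

    crs1_step: int | None = None
    crs2_step: int | None = None
    big_steps = 0
    frame = 0

    def gaussian_well_force(com_pos, centers, depth, sigma):
        # U = -depth * sum_j exp(-|com - x_j|^2 / (2 sigma^2)); force on COM
        diff = com_pos[None, :] - centers  # (nc, 3)
        r2 = np.einsum("ij,ij->i", diff, diff)
        w = np.exp(-r2 / (2.0 * sigma**2))
        return -(depth / sigma**2) * np.einsum("i,ij->j", w, diff)

    def core_repulsion_force(lig_pos):
        diff = lig_pos[:, None, :] - rec[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        pen = spec.repulsion_radius - r
        mask = pen > 0
        if not np.any(mask):
            return np.zeros(3)
        # U = k/2 * pen^2 for r < radius; F = k * pen * rhat
        with np.errstate(invalid="ignore", divide="ignore"):
            rhat = diff / r[:, :, None]
        contrib = (spec.repulsion_k * pen)[:, :, None] * rhat
        return contrib[mask].sum(axis=0)

    def enforce_core(com_pos, local_pos):
        # project the COM out of any bead-bead core overlap (rigid body)
        for _ in range(20):
            d = cdist(local_pos + com_pos, rec)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            overlap = spec.repulsion_radius - d[i, j]
            if overlap <= 0:
                break
            direction = (local_pos[i] + com_pos) - rec[j]
            com_pos = com_pos + direction / d[i, j] * overlap
        return com_pos

    for step in range(spec.n_steps):
        local = local0 @ orientation.as_matrix().T
        captured = crs1_step is not None
        if captured:
            if spec.gated and step < crs1_step + spec.gate_delay_steps:
                target = crs1_pose
            else:
                target = two_site_pose
        else:
            target = None

        force = gaussian_well_force(
            com, rec_crs1, spec.well_depth_crs1, spec.well_range_crs1
        )
        if not spec.gated:
            force += gaussian_well_force(
                com, rec_crs2, spec.well_depth_crs2, spec.well_range_crs2
            )
        force += core_repulsion_force(local + com)

        # full mobility while free or in transit; damped once settled at the
        # dock pose (bound ligands feel higher effective friction)
        settled = target is not None and np.linalg.norm(com - target.translation) < 0.3
        mobility = spec.bound_mobility_factor if settled else 1.0
        dx = (
            mobility * spec.diffusion * force * spec.dt
            + np.sqrt(mobility) * noise_scale * rng.normal(size=3)
        )
        # instability is judged on the unconstrained dynamical step; the
        # docking pull below is displacement-capped by construction
        if np.linalg.norm(dx) > 0.5 * spec.repulsion_radius:
            big_steps += 1
        if target is not None:
            pull = spec.tether_relax * (target.translation - com)
            norm = np.linalg.norm(pull)
            if norm > 0.08:  # cap the per-step dock displacement
                pull *= 0.08 / norm
            dx = dx + pull
        com = com + dx
        # reflecting walls on the COM
        for ax in range(3):
            lo, hi = box[ax]
            if com[ax] < lo:
                com[ax] = 2 * lo - com[ax]
            elif com[ax] > hi:
                com[ax] = 2 * hi - com[ax]
        # random rigid rotation, plus relaxation toward the dock orientation
        orientation = (
            Rotation.from_rotvec(mobility * spec.rot_sigma * rng.normal(size=3))
            * orientation
        )
        if target is not None:
            delta = Rotation.from_matrix(target.rotation) * orientation.inv()
            orientation = (
                Rotation.from_rotvec(spec.orient_relax * delta.as_rotvec())
                * orientation
            )
        local = local0 @ orientation.as_matrix().T
        com = enforce_core(com, local)

        lig_pos = local + com
        if crs1_step is None and cdist(lig_pos, rec_crs1).min() < spec.contact_cutoff:
            crs1_step = step
        if crs2_step is None and cdist(lig_pos, rec_crs2).min() < spec.contact_cutoff:
            crs2_step = step

        if (step + 1) % spec.stride == 0:
            coords[frame, complex_.ligand_slice, :] = lig_pos
            times[frame] = (step + 1) * spec.dt
            frame += 1

    if big_steps > 0.001 * spec.n_steps:
        raise InstabilityError(
            f"{big_steps} of {spec.n_steps} steps exceeded half the repulsion "
            "radius; reduce dt or the diffusion coefficient"
        )
    traj = Trajectory(top, coords[:frame], times[:frame])
    log = BindingEventLog(
        crs1_first_frame=None if crs1_step is None else crs1_step // spec.stride,
        crs2_first_frame=None if crs2_step is None else crs2_step // spec.stride,
        crs1_first_step=crs1_step,
        crs2_first_step=crs2_step,
    )
    return traj, log
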