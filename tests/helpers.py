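"""Shared builders for small hand-constructed trajectories."""

import numpy as np

from bindscape.model_io import Particle, Topology, Trajectory


def two_group_trajectory(coords_a, coords_b, n_frames=1):
    """Trajectory with chains A/B holding the given single-frame coordinates."""
    coords_a, coords_b = np.atleast_2d(coords_a), np.atleast_2d(coords_b)
    particles = [
        Particle(i, "BB", i + 1, "ALA", "A") for i in range(len(coords_a))
    ] + [
        Particle(len(coords_a) + i, "BB", i + 1, "ALA", "B")
        for i in range(len(coords_b))
    ]
    frame = np.vstack([coords_a, coords_b])
    return Trajectory(Topology(particles), np.repeat(frame[None], n_frames, axis=0))
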