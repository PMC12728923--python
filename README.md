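# bindscape

Analysis toolkit for protein–protein **binding trajectories** of a
membrane-anchored receptor and a mobile protein ligand — the archetypal
system being an atypical chemokine receptor (such as CCRL2) engaging a
chemerin-like ligand through two recognition sites: the receptor
N-terminal arm (CRS1) and the extracellular loops (CRS2).

It is written for computational structural biologists who have
coarse-grained or atomistic association trajectories and want, from one
library:

* **collective variables** — centre-of-mass distance `d`, the smooth
  coordination number `c = Σ_i Σ_j s(r_ij)` with the rational switching
  function `s(r) = (1 − x⁶)/(1 − x¹²)`, `x = r/r₀`, `r₀ = 0.9 nm`,
  minimum inter-chain distance, and orientation-sensitive variants;
* **free-energy landscapes** by Boltzmann inversion,
  `F(d, c) = −k_B T ln P(d, c)`, with basin detection and
  basin-to-frame mapping;
* **bound-state segmentation** (min distance < 5 Å) and recognition-site
  **engagement order** via z-scored time-lag cross-correlation and
  persistent first-engagement calls;
* **contact-frequency maps**, thresholded hotspot lists and antisymmetric
  Δ-contact maps between conformational ensembles;
* **clustering** — GROMOS-style greedy RMSD clustering (Kabsch
  superposition with a receptor-fit/ligand-RMSD convention) and
  density-peak clustering in CV feature space;
* **ensemble comparison** — PCA of global descriptors (COM distance,
  total contacts, orientation angle), centroid distances and base-2
  Jensen–Shannon divergence in [0, 1];
* **missense-variant triage** — pathogenicity bins
  (benign 0–0.33 / ambiguous 0.34–0.564 / pathogenic 0.565–1), ΔΔG
  harmonisation across predictor sign conventions (±2 kcal/mol
  thresholds), interface flags from contact maps, and residue
  contact-network centralities;
* a **synthetic-data module** that generates binding trajectories with
  exact ground truth — an i.i.d. pose-mixture sampler for stationary
  populations and a gated two-step Langevin binder for temporal
  ordering — so every stage is testable without downloading trajectories.

Trajectories are read from multi-model PDB or a plain-text XYZ-frames
format; all internal lengths are nanometres and residue numbering follows
the input file verbatim.

## Worked example

Sample the study-condition mixture (two bound poses at 60 %/30 % plus 10 %
unbound), build the landscape, and recover the designed populations:

```python
import numpy as np
from bindscape import synthetic_data as sd, collective_variables as cv
from bindscape import free_energy_landscape as fel, binding_kinetics as bk
from bindscape import contact_maps as cm

complex_ = sd.make_toy_complex()
spec = sd.default_mixture_spec(complex_, n_frames=20_000, seed=0)
traj, labels = sd.sample_mixture(spec, complex_)

top, regions = traj.topology, complex_.regions
rb = regions.indices(top, "RECEPTOR_BB")
lb = regions.indices(top, "LIGAND_BB")
d = cv.com_distance(traj, rb, lb)
c = cv.coordination_number(traj, rb, lb)

mind = cv.min_distance(traj, regions.indices(top, "RECEPTOR_ALL"),
                       regions.indices(top, "LIGAND_ALL"))
print(f"bound fraction: {bk.classify_bound(mind, 0.5).bound_fraction:.3f}")

grid = fel.build_fel(d, c)
basins = fel.find_basins(grid, depth=np.inf)
bound = sorted((b for b in basins if b.d_center < 5.0),
               key=lambda b: -b.probability)
for b in bound:
    print(f"basin {b.basin_id}: d={b.d_center:.2f} nm  coord={b.coord_center:.0f}  "
          f"P={b.probability:.3f}  F={grid.basin_free_energy(b.basin_id):.3f} kT")
dF = (grid.basin_free_energy(bound[1].basin_id)
      - grid.basin_free_energy(bound[0].basin_id))
print(f"dF(poseA -> poseB) = {dF:.3f} kT   (ln 2 = {np.log(2):.3f})")

cmap = cm.contact_frequency(traj, "R", "L", cutoff=0.5)
rec_hot, _ = cm.hotspots(cmap, tau=0.25)
print("receptor hotspots:", [(r, round(f, 2)) for r, f in rec_hot[:5]])
```

Output:

```
bound fraction: 0.902
basin 1: d=1.41 nm  coord=108  P=0.597  F=0.516 kT
basin 2: d=2.17 nm  coord=120  P=0.305  F=1.188 kT
dF(poseA -> poseB) = 0.673 kT   (ln 2 = 0.693)
receptor hotspots: [(45, 0.6), (44, 0.59), (43, 0.32), (15, 0.3), (14, 0.3)]
```

The two bound basins recover the designed 0.6/0.3 pose weights (their
free-energy gap is k_BT·ln 2 up to multinomial sampling error), the bound
fraction matches the 90 % bound design, and the hotspot list finds the
designed interfaces: ECL2 residues 43–45 (the pose-A β1↔ECL2 interface,
frequency ≈ the 0.6 pose weight) and arm residues 14–15 (the pose-B
interface at ≈ 0.3).

## Command line

A thin `bindscape` CLI wraps the library: `simulate-mixture` /
`simulate-langevin` (synthetic trajectories + ground truth),
`cv`, `fel`, `order`, `cluster`, `contacts`, `delta-contacts`, `fluct`,
`ensemble`, `variants`, and `run` (a staged pipeline with a JSON manifest
of parameters, seeds and output hashes). Contact cutoffs quoted in
ångströms on the command line are converted once at the boundary; two
shipped profiles (`cg`: 5 Å, 303 K, τ = 0.10; `aa`: 4 Å,
300 K, τ = 0.25) centralise the resolution-dependent defaults.

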