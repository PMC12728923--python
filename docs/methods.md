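# Methods

`bindscape` analyses protein–protein binding trajectories of a
membrane-anchored receptor and a mobile ligand — the archetype being an
atypical chemokine receptor (CCRL2-like, the "receptor" chain) engaging a
chemerin-like protein ligand. This note records the models, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions.

## Collective variables

Two scalars summarise each frame:

* **COM distance** `d`: Euclidean distance between the unweighted geometric
  centres of the backbone particles of the two chains. Centres are
  unweighted because coarse-grained beads carry no masses in this data
  model; for Cα-only selections this equals the mass-weighted COM to within
  rounding.
* **Coordination number** `c = Σ_{i∈A} Σ_{j∈B} s(r_ij)` with the rational
  switching function `s(r) = (1 − x^n)/(1 − x^m)`, `x = (r − d0)/r0`.
  Defaults `d0 = 0`, `r0 = 0.9 nm`, `n = 6`, `m = 12`: `s` passes through
  1/2 at `r = r0` (the analytic limit `n/m` at the removable singularity
  `x = 1`, evaluated on a guard band `|x − 1| < 1e-6`) and decays as
  `x^(n−m)` far away. Distances below `d0` clamp to `s = 1`. Coordination
  is computed over backbone beads on both chains by default; the selection
  is configurable.

Orientation-sensitive alternatives: the **N-terminal/N-terminal distance**
(COM distance between the receptor's N-terminal-segment backbone and the
first ligand backbone particles) disambiguates poses that the global
(d, c) pair cannot, and the **orientation angle** is the angle between the
two chains' N→C axis vectors.

No periodic minimum-image convention is applied by default: the synthetic
systems are unwrapped, and silent imaging corrupts distances on externally
wrapped inputs; an orthorhombic box is carried on the trajectory for
adapters that need it.

## Free-energy landscapes

`F(d, c) = −kB T ln P(d, c)` on a 2D histogram (default 60×60 bins over the
observed range padded 5 %; the bin count separates the designed basins
while keeping ≥100 counts per occupied bin at the frame counts used here).
Energies are reported in kBT by default (kJ/mol optional, with
kB = 0.008314 kJ·mol⁻¹·K⁻¹ and T = 303 K for coarse-grained or 300 K for
atomistic conventions). No smoothing is applied, so ΔF between occupied
bins is exactly −kBT·ln of the count ratio; empty bins are masked as
infinite energy, never shown as F = 0.

Basins grow from local minima (occupied bins not exceeded by any occupied
8-neighbour) as connected occupied components within `depth` of the
minimum; components that meet merge into the deeper basin. The default
`depth = 2 kBT` suits landscapes whose wells connect through sampled
transition regions. For the i.i.d. mixture data the pose basins are
*disconnected occupied islands* — there are no finite barriers — so basin
integration there uses `depth = ∞`, which floods each island completely
and makes the basin probability an exact population estimate. A basin's
free energy is reported as `−kBT ln(Σ P)` over its bins: integrating the
probability (rather than reading the minimum bin) estimates the log
population ratio directly and is what the weight-recovery test checks.

## Bound-state segmentation and engagement order

A frame is bound when the minimum inter-chain particle distance is
strictly below 0.5 nm (the 5 Å coarse-grained contact criterion; 0.4 nm is
the atomistic profile's value). Engagement order between the receptor's
two recognition sites — CRS1, the N-terminal arm, and CRS2, the
extracellular loops — uses two statistics:

* **z-scored time-lag cross-correlation** of the per-frame residue-pair
  contact counts, normalised per lag by the overlap length `N − |ℓ|` so
  finite traces compare fairly across lags. The sign convention is fixed
  and recorded in the result object: a negative peak lag means the first
  trace (CRS1) leads. Calls within ±1 frame of zero are "simultaneous".
  `max_lag` must exceed the expected engagement offset; the synthetic
  two-step runs use 800 frames.
* **first persistent engagement**: the first frame at which a trace stays
  positive for a persistence window (default 5 frames), which suppresses
  single-frame fleeting contacts; the earlier site wins.

A constant trace makes the correlation undefined and raises rather than
silently returning zero.

## Clustering

* **GROMOS-style**: every frame is superposed on the *receptor fit
  selection* of a common reference (frame 0) and pairwise RMSD is taken
  over the *ligand RMSD selection*; this measures relative binding pose,
  which is what separates binding modes of a two-chain complex. Pair-by-
  pair mutual fitting is available behind a flag for single-chain use. The
  greedy neighbour-count algorithm then extracts clusters (most neighbours
  within the cutoff → centre; ties break to the lowest frame index), which
  makes cluster sizes non-increasing. Superposition is a proper-rotation
  Kabsch fit (SVD with determinant correction); degenerate point sets
  (< 3 points or collinear) are rejected.
* **Density peaks** in CV feature space (e.g. coordination vs COM
  distance): local density by a Gaussian kernel at `d_c` (2nd percentile
  of pairwise distances) and `δ` = distance to the nearest denser item.
  Centres are the decision-graph outliers: the `γ = ρ·δ` ranking proposes
  candidates, and the centre set is cut at the largest multiplicative gap
  in their sorted `δ` values (true centres sit an order of magnitude above
  the within-cluster δ floor; if no gap exceeds 2× the data are one
  cluster). Features are divided by one pooled scale rather than
  per-feature z-scores — per-feature standardisation inflates a
  low-variance axis's noise and can shred tight clusters, while a global
  scale preserves geometry and still makes labels invariant under feature
  rescaling.

## Contact maps

A residue pair is in contact when any inter-particle distance is strictly
below the cutoff (5.0 Å coarse-grained, 4.0 Å atomistic — strict
inequalities throughout, matching the usual "< cutoff", "> threshold"
phrasing, and unit-tested at the boundaries). Frequencies divide by all
frames by default; a bound-frames denominator is available since
bound-state analyses normalise that way. Thresholding keeps entries
strictly above τ (0.10 default, 0.25 for the persistent-contact view);
Δ-maps subtract thresholded maps entrywise (positive ⇒ enriched in the
first ensemble) and are antisymmetric by construction.

## Ensemble comparison

Three global descriptors per frame — COM distance, total inter-chain
residue-contact count, orientation angle — are pooled across all compared
ensembles, z-standardised per feature with the pooled moments, and
projected onto the top-2 principal components (deterministic sign: the
largest-magnitude loading of each PC is positive; zero-variance features
drop with a warning). Similarity is the Euclidean distance between
ensemble centroids in PC space and the Jensen–Shannon divergence between
2D histograms on shared 30×30 bin edges spanning the pooled range. JSD
uses base-2 logarithms so it lives in [0, 1] and reaches exactly 1 on
disjoint supports — published ensemble JSD values above ln 2 ≈ 0.69 only
make sense on this scale. The 2D joint histogram is the default (averaged
per-PC 1D histograms would discard the correlation structure the
embedding exists to expose).

## Fluctuations

RMSD uses subset fitting: superpose on a fit selection, measure over a
measure selection, so the statistic reports motion of the measured region
relative to the fitted one. "Innermost secondary-structure" fit groups are
not machine-derivable from bead models, so fit selections are explicit,
user-declared regions; the synthetic system ships its own. RMSF is the
standard two-pass procedure (fit to frame 0, compute the mean structure,
re-fit to the mean) with per-residue averaging over backbone particles;
an isotropically jittered particle with per-axis σ has expected RMSF
σ·√3. COM tracking samples the ligand-core geometric centre at 150
uniformly spaced eligible frames (all frames, or bound frames when a mask
is given).

## Variant triage

Pathogenicity scores bin as benign 0–0.33, ambiguous 0.34–0.564,
pathogenic 0.565–1. Scores are rounded to 3 decimals first; the printed
bins leave micro-gaps, and a rounded score inside one goes to the nearer
edge's class (exact midpoints to the more severe class). ΔΔG values are
unified to the positive-equals-destabilising convention before applying
the ±2 kcal/mol thresholds; FoldX and MutaBind2 already use it, DynaMut2
and DDMut-PPI report the opposite sign, and unknown tool names are
rejected so a value can never be double-flipped. Interface flags mark
variants whose residue keeps at least one contact above the map
threshold; raising the threshold can only unflag. Residue contact
networks join residues with any inter-particle distance below 0.5 nm
(configurable; the reference web tools do not publish their cutoff),
excluding sequence-adjacent pairs (|Δindex| < 2) so centralities reflect
tertiary structure; betweenness and closeness are computed within each
connected component. Solvent-accessible-surface quantities are out of
scope and accepted only as external inputs.

## Synthetic data: what it emulates, what it does not

The toy complex is a 76-residue receptor (one backbone bead per residue:
a 24-bead transmembrane stub, three 7-bead extracellular loops at
ECL-like positions — together the CRS2 recognition site — and a 31-bead
N-terminal arm, CRS1) plus a rigid 24-bead three-strand ligand with
labelled β1, loop3 and C-terminal subregions. The receptor is static
(infinite friction), mimicking a membrane-embedded receptor with
restrained termini and isolating ligand-association statistics.

Two generators provide complementary ground truth:

* **Mixture sampler** — i.i.d. frames from two designed bound poses
  (poseA: β1 edge on ECL2; poseB: C-terminal edge on the CRS1 arm) plus a
  diffuse unbound shell (ligand COM uniform in a 6–9 nm shell, uniform
  orientation; the shell clears the receptor so unbound frames can never
  register a contact). Study conditions are weights 0.6/0.3/0.1 with
  per-bead Gaussian jitter of 0.03 nm — a typical coarse-grained
  bound-state positional fluctuation — so stationary populations, contact
  frequencies and cluster sizes are exact binomial/multinomial ground
  truth. Poses are constructed by a deterministic line search that walks
  the ligand along an approach axis until clash-free at a 0.35 nm gap;
  "designed contacts" evaluated at a 0.37 nm cutoff are the pairs whose
  contact probability under jitter is ≈1, which is what frequency-recovery
  tests compare against.
* **Langevin binder** — overdamped rigid-body dynamics of the ligand COM
  (`x ← x − D∇U·dt/kBT + √(2D dt)·ξ`, D = 0.05 nm²/ns, dt = 0.02 ns,
  40 000 steps recorded every 10) with Gaussian capture wells on the CRS1
  beads, reflecting walls, a soft-core bead-bead repulsion and an exact
  post-step projection that resolves any core overlap (so the rigid
  bodies never interpenetrate at recorded frames). Binding is
  capture-and-dock: the first CRS1 contact (checked every step) starts a
  5 000-step residence at the designed CRS1 pose, after which the ligand
  docks into a two-site pose wedged between the arm base and ECL1 that
  keeps CRS1 engaged while CRS2 forms — the defining feature of the
  two-step recognition model. In the settled bound state the effective
  mobility is reduced (factor 0.15), reflecting the higher friction of a
  bound ligand and making engagement persist once formed. The event log
  records first-contact steps for both sites and is the temporal ground
  truth for the ordering statistics. The instability diagnostic flags
  runs in which more than 0.1 % of unconstrained dynamical steps exceed
  half the repulsion radius (the docking pull is displacement-capped by
  construction and excluded from the diagnostic).

Neither generator has membrane, solvent, internal flexibility or
force-field realism, and the bound-state kinetics are designed rather
than emergent. Passing tests therefore demonstrate that the *analysis
machinery* recovers known populations, interfaces, orderings and
ensemble relations exactly or within sampling error — not that any
physical binding mechanism has been validated on real trajectories.

## Problem sizes and reproducibility

The shipped analyses use 5·10⁴ mixture frames for population recovery
(multinomial standard errors ≈ 0.008 on the log weight ratio), 2·10³
frames for clustering and ensemble comparisons, ten independent binder
runs for ordering statistics, and 10⁴ frames for fluctuation recovery —
sizes at which every tolerance is set by the exact sampling error of the
generator. All stochastic operations take explicit seeds; one master seed
expands into per-component streams, and identical seeds reproduce
trajectories, event logs and output files bit-for-bit.

## Known limitations

* One bead per residue: "backbone vs all-atom" selection distinctions are
  degenerate on the toy system (they matter only for imported data).
* The GROMOS fit/RMSD group convention for two-chain complexes
  (receptor-fit, ligand-RMSD) is a documented choice; other tools may fit
  pair-by-pair on the whole complex.
* Density-peak centre selection uses a decision-graph gap heuristic; data
  with a continuum of densities and no clear gap default to one cluster.
* The cross-correlation ordering call is meaningful only when both traces
  have variance and the engagement offset is within `max_lag`.
* The chemerin-core residue-numbering ambiguity for imported region
  configs is deliberately left to the config author: region definitions
  name chains and author-numbered ranges explicitly and are validated
  against the topology rather than guessed.
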