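"""Missense-variant triage against an MD-derived binding interface.

Variants (typically gnomAD missense entries scored by AlphaMissense) are

* binned by pathogenicity score: benign 0-0.33, ambiguous 0.34-0.564,
  pathogenic 0.565-1.  Scores are rounded to 3 decimals first; a value
  falling in the micro-gap between printed bin edges goes to the nearer
  edge's class (ties to the more severe class);
* classified by predicted stability change: after unifying tool sign
  conventions to "positive = destabilising" (FoldX and MutaBind2 already
  use it; DynaMut2 and DDMut-PPI report the opposite sign), ddG > 2
  kcal/mol is destabilising and ddG < -2 kcal/mol stabilising;
* flagged as interface variants when their residue participates in at
  least one contact surviving the contact-map threshold;
* contextualised by residue contact-network centralities (degree,
  betweenness, closeness) computed on a single-structure residue graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .contact_maps import ContactFrequencyMap, threshold_map
from .model_io import Trajectory

__all__ = [
    "VariantRecord",
    "ResidueNetworkStats",
    "classify_pathogenicity",
    "classify_stability",
    "load_variants",
    "flag_interface",
    "residue_network",
    "BENIGN",
    "AMBIGUOUS",
    "PATHOGENIC",
]

BENIGN = "benign"
AMBIGUOUS = "ambiguous"
PATHOGENIC = "pathogenic"

DESTABILIZING = "destabilizing"
STABILIZING = "stabilizing"
NEUTRAL = "neutral"

#: tools whose positive ddG means destabilising (no sign flip needed)
_POSITIVE_DESTABILIZING = {"foldx", "mutabind2"}
#: tools reporting the opposite sign convention
_NEGATIVE_DESTABILIZING = {"dynamut2", "ddmut-ppi", "ddmutppi", "ddmut_ppi"}

DDG_THRESHOLD = 2.0  # kcal/mol


@dataclass
class VariantRecord:
    """One missense variant with optional stability predictions."""

    protein: str
    position: int  # 1-based author numbering
    ref: str
    alt: str
    score: float  # pathogenicity probability in [0, 1]
    ddg: list[tuple[str, float]] = field(default_factory=list)  # (tool, kcal/mol)
    pathogenicity_class: str | None = None
    interface: bool | None = None
    stability_class: str | None = None


def classify_pathogenicity(score: float) -> str:
    """Bin a pathogenicity score into benign / ambiguous / pathogenic."""
    if not 0.0 <= score <= 1.0:
        raise ValueError("pathogenicity score must lie in [0, 1]")
    r = round(score, 3)
    if r <= 0.33:
        return BENIGN
    if r < 0.34:  # micro-gap between the printed bin edges
        return BENIGN if (r - 0.33) < (0.34 - r) else AMBIGUOUS
    if r <= 0.564:
        return AMBIGUOUS
    return PATHOGENIC


def classify_stability(ddg: float, tool: str) -> str:
    """Classify a ddG after unifying the tool's sign convention.

    The unified convention is positive = destabilising; thresholds are
    +/-2 kcal/mol.  Unknown tools raise with the supported list, so a
    value can never be silently double-flipped.
    """
    key = tool.strip().lower()
    if key in _POSITIVE_DESTABILIZING:
        unified = ddg
    elif key in _NEGATIVE_DESTABILIZING:
        unified = -ddg
    else:
        raise ValueError(
            f"unknown ddG tool {tool!r}; supported conventions: "
            f"positive-destabilising {sorted(_POSITIVE_DESTABILIZING)}, "
            f"negative-destabilising {sorted(_NEGATIVE_DESTABILIZING)}"
        )
    if unified > DDG_THRESHOLD:
        return DESTABILIZING
    if unified < -DDG_THRESHOLD:
        return STABILIZING
    return NEUTRAL


def load_variants(path) -> list[VariantRecord]:
    """Read a variant table: CSV with header protein,position,ref,alt,score[,tool,ddg]."""
    df = pd.read_csv(path)
    required = {"protein", "position", "ref", "alt", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    records: list[VariantRecord] = []
    for _, row in df.iterrows():
        ddg = []
        if "tool" in df.columns and "ddg" in df.columns and pd.notna(row.get("tool")):
            ddg.append((str(row["tool"]), float(row["ddg"])))
        rec = VariantRecord(
            protein=str(row["protein"]),
            position=int(row["position"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            score=float(row["score"]),
            ddg=ddg,
        )
        rec.pathogenicity_class = classify_pathogenicity(rec.score)
        if ddg:
            rec.stability_class = classify_stability(ddg[0][1], ddg[0][0])
        records.append(rec)
    return records


def flag_interface(
    variants: list[VariantRecord],
    cmap: ContactFrequencyMap,
    tau: float,
    axis: str = "receptor",
) -> list[VariantRecord]:
    """Flag variants whose residue keeps a contact above the map threshold.

    ``axis`` names which map axis the variants' protein corresponds to.
    Residues absent from that axis are flagged False with a warning (they
    may simply lie outside the modelled construct).
    """
    kept = threshold_map(cmap, tau).frequencies
    if axis == "receptor":
        residues, peak = cmap.receptor_residues, kept.max(axis=1, initial=0.0)
    elif axis == "ligand":
        residues, peak = cmap.ligand_residues, kept.max(axis=0, initial=0.0)
    else:
        raise ValueError("axis must be 'receptor' or 'ligand'")
    peak_by_res = dict(zip(residues.tolist(), peak.tolist()))
    for v in variants:
        if v.position not in peak_by_res:
            warnings.warn(
                f"variant {v.protein} {v.ref}{v.position}{v.alt}: residue not on "
                "the contact-map axis; interface flag set to False"
            )
            v.interface = False
        else:
            v.interface = peak_by_res[v.position] > 0.0
    return variants


@dataclass
class ResidueNetworkStats:
    """Contact-network centralities keyed by (chain_id, residue_index)."""

    degree: dict
    betweenness: dict
    closeness: dict

    def row(self, key) -> tuple[int, float, float]:
        return self.degree[key], self.betweenness[key], self.closeness[key]


def residue_network(
    traj: Trajectory, frame: int = 0, cutoff: float = 0.5
) -> ResidueNetworkStats:
    """Residue contact graph of one structure frame, with centralities.

    Nodes are residues; an edge joins two residues when any inter-particle
    distance is strictly below ``cutoff`` (nm).  Residues adjacent in
    sequence on the same chain (|delta index| < 2) are not joined, so
    centralities reflect tertiary contacts.  Betweenness and closeness are
    computed per connected component (normalised within the component);
    isolated residues get closeness 0.
    """
    top = traj.topology
    coords = traj.coordinates[frame]
    keys = list(zip(top.chain_ids.tolist(), top.residue_indices.tolist()))
    unique_keys = sorted(set(keys))
    groups = {k: np.flatnonzero([kk == k for kk in keys]) for k in unique_keys}
    G = nx.Graph()
    G.add_nodes_from(unique_keys)
    for a_i in range(len(unique_keys)):
        for b_i in range(a_i + 1, len(unique_keys)):
            a, b = unique_keys[a_i], unique_keys[b_i]
            if a[0] == b[0] and abs(a[1] - b[1]) < 2:
                continue  # sequence-adjacent: excluded from the graph
            if cdist(coords[groups[a]], coords[groups[b]]).min() < cutoff:
                G.add_edge(a, b)
    if G.number_of_edges() == 0:
        warnings.warn("empty contact graph: all centralities are zero")
    degree = dict(G.degree())
    betweenness: dict = {}
    for comp in nx.connected_components(G):
        sub = G.subgraph(comp)
        betweenness.update(nx.betweenness_centrality(sub, normalized=True))
    # wf_improved=False gives the within-component closeness in [0, 1]
    closeness = nx.closeness_centrality(G, wf_improved=False)
    return ResidueNetworkStats(degree, betweenness, closeness)
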