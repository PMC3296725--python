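"""Cryptic-intermediate / metastable-state prediction from structure.

Candidate amides are H-bond donors within regular secondary structure that
carry a residue-specific dG_HX (loop and surface H-bonded NHs exchange
through local fluctuations and are excluded). Candidates are clustered by
the 7 A contact-order matrix over backbone nitrogen distances: two
residues are in contact when their N atoms are within the cutoff
(inclusive), and a cluster is a connected component of the contact graph.
Each cluster of two or more residues is a candidate cryptic unfolding
intermediate; its free-energy coverage is the [min, max] of member dG_HX,
and clusters with matching coverage are cooperative units. When the
clustering returns a single cluster the protein shows no distinct cryptic
intermediates and the search falls back to metastable states: residues
with dG_HX strictly above the threshold dG_X, re-clustered the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .constants import CONTACT_CUTOFF, ENERGY_TOLERANCE
from .energetics import EnergyLedger
from .structure import (HydrogenBond, ProteinStructure, ResidueKey,
                        SecondaryStructureAssignment, StructureError,
                        backbone_N_distance, write_pdb)


class PredictionError(ValueError):
    """Raised when prediction inputs are unusable."""


@dataclass
class ContactOrderMatrix:
    """Binary symmetric contact matrix over backbone-N distances."""

    residues: list[ResidueKey]
    matrix: np.ndarray          # 0/1, zero diagonal
    distances: np.ndarray       # angstrom
    cutoff: float = CONTACT_CUTOFF

    def contacts(self) -> list[tuple[ResidueKey, ResidueKey]]:
        n = len(self.residues)
        return [(self.residues[i], self.residues[j])
                for i in range(n) for j in range(i + 1, n)
                if self.matrix[i, j]]


@dataclass
class Cluster:
    """One contact-connected group of candidate residues."""

    members: list[ResidueKey]
    coverage: tuple[float, float] | None = None   # (min, max) dG_HX, kcal/mol
    pdb_text: str | None = None

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class IntermediatePrediction:
    """Stage-IV outcome: either cryptic intermediates or a metastable search."""

    mode: str                                  # "cryptic_intermediates" | "metastable_state"
    clusters: list[Cluster]
    unclustered: list[ResidueKey]
    cooperative_pairs: list[tuple[int, int]] = field(default_factory=list)
    dg_x: float | None = None
    selected: list[ResidueKey] = field(default_factory=list)


def select_candidate_residues(s: ProteinStructure,
                              ss: SecondaryStructureAssignment,
                              hbonds: list[HydrogenBond],
                              dg_map: dict[ResidueKey, float],
                              require_secondary_structure: bool = True,
                              ) -> list[ResidueKey]:
    """Residues whose NH donates an H-bond, sits in regular secondary
    structure, and has a measured dG_HX.

    ``require_secondary_structure=False`` relaxes to all H-bonded donors
    (for proteins whose slow NHs include ordered-loop positions).
    """
    donors = {hb.donor for hb in hbonds}
    selected = []
    for r in s.residues:
        if r.key not in donors or r.key not in dg_map:
            continue
        if require_secondary_structure and ss.label(r.key) == "none":
            continue
        selected.append(r.key)
    if not selected:
        raise PredictionError(
            "no candidate residues: check that the exchange table covers "
            "H-bonded residues in regular secondary structure and that the "
            "structure file matches the residue numbering")
    return selected


def contact_order_matrix(s: ProteinStructure, residues: list[ResidueKey],
                         cutoff: float = CONTACT_CUTOFF) -> ContactOrderMatrix:
    """Pairwise backbone-N contact matrix; 1 iff distance <= cutoff, i != j."""
    coords = []
    for key in residues:
        r = s.get(key)
        if not r.has("N"):
            raise StructureError(f"residue {r!r} lacks a backbone N atom")
        coords.append(r.atoms["N"])
    xyz = np.asarray(coords, float)
    if len(xyz) == 0:
        return ContactOrderMatrix(list(residues), np.zeros((0, 0), int),
                                  np.zeros((0, 0)), cutoff)
    diff = xyz[:, None, :] - xyz[None, :, :]
    distances = np.sqrt((diff ** 2).sum(axis=-1))
    matrix = (distances <= cutoff).astype(int)
    np.fill_diagonal(matrix, 0)
    return ContactOrderMatrix(list(residues), matrix, distances, cutoff)


def cluster_contacts(matrix: ContactOrderMatrix
                     ) -> tuple[list[Cluster], list[ResidueKey]]:
    """Connected components of the contact graph.

    Returns (clusters, singletons): components of size >= 2 sorted by
    descending size then smallest member residue number; contact-free
    residues are reported separately, not as clusters.
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.residues)
    g.add_edges_from(matrix.contacts())
    clusters = []
    singletons = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda k: (k[0], k[1], k[2]))
        if len(members) >= 2:
            clusters.append(Cluster(members))
        else:
            singletons.extend(members)
    clusters.sort(key=lambda c: (-len(c.members),
                                 min(k[1] for k in c.members)))
    singletons.sort(key=lambda k: (k[0], k[1], k[2]))
    return clusters, singletons


def coverage(cluster: Cluster, dg_map: dict[ResidueKey, float]
             ) -> tuple[float, float]:
    """Free-energy coverage of a cluster: (min, max) member dG_HX."""
    missing = [k for k in cluster.members if k not in dg_map]
    if missing:
        raise PredictionError(f"cluster member(s) without dG_HX: {missing}")
    values = [dg_map[k] for k in cluster.members]
    return (min(values), max(values))


def cooperative_units(clusters: list[Cluster],
                      tolerance: float = ENERGY_TOLERANCE
                      ) -> list[tuple[int, int]]:
    """Index pairs of clusters whose coverage endpoints each agree within
    the tolerance — groups expected to unfold together."""
    pairs = []
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            ci, cj = clusters[i].coverage, clusters[j].coverage
            if ci is None or cj is None:
                raise PredictionError("cluster coverage not computed")
            if abs(ci[0] - cj[0]) <= tolerance and abs(ci[1] - cj[1]) <= tolerance:
                pairs.append((i, j))
    return pairs


def _finalize(clusters: list[Cluster], s: ProteinStructure,
              dg_map: dict[ResidueKey, float]) -> None:
    for idx, c in enumerate(clusters, start=1):
        c.coverage = coverage(c, dg_map)
        c.pdb_text = write_pdb(s, c.members, title=f"cluster {idx}")


def metastable_search(dg_map: dict[ResidueKey, float], dg_x_value: float,
                      s: ProteinStructure,
                      cutoff: float = CONTACT_CUTOFF) -> IntermediatePrediction:
    """Cluster all residues with dG_HX strictly above the threshold dG_X."""
    selected = sorted((k for k, v in dg_map.items() if v > dg_x_value),
                      key=lambda k: (k[0], k[1], k[2]))
    if not selected:
        return IntermediatePrediction("metastable_state", [], [],
                                      dg_x=dg_x_value, selected=[])
    matrix = contact_order_matrix(s, selected, cutoff)
    clusters, singletons = cluster_contacts(matrix)
    _finalize(clusters, s, dg_map)
    pred = IntermediatePrediction("metastable_state", clusters, singletons,
                                  cooperative_units(clusters),
                                  dg_x=dg_x_value, selected=selected)
    return pred


def predict(s: ProteinStructure, ss: SecondaryStructureAssignment,
            hbonds: list[HydrogenBond], dg_map: dict[ResidueKey, float],
            ledger: EnergyLedger | None = None,
            cutoff: float = CONTACT_CUTOFF,
            tolerance: float = ENERGY_TOLERANCE,
            require_secondary_structure: bool = True,
            ) -> IntermediatePrediction:
    """Run the stage-IV decision: cryptic clustering, metastable fallback.

    Two or more clusters -> cryptic intermediates, with coverages and
    cooperative units. Exactly one cluster -> the metastable search over
    the ledger's dG_X threshold (which requires dG_U*, dG_HX, dG_HX*).
    """
    selected = select_candidate_residues(s, ss, hbonds, dg_map,
                                         require_secondary_structure)
    matrix = contact_order_matrix(s, selected, cutoff)
    clusters, singletons = cluster_contacts(matrix)
    if len(clusters) >= 2:
        _finalize(clusters, s, dg_map)
        return IntermediatePrediction(
            "cryptic_intermediates", clusters, singletons,
            cooperative_units(clusters, tolerance), selected=selected)
    if ledger is None:
        raise PredictionError(
            "single cluster found: the metastable search needs an energy "
            "ledger with dG_U*, dG_HX and dG_HX*")
    return metastable_search(dg_map, ledger.dg_x, s, cutoff)
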