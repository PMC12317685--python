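"""Peptide similarity networks and mechanistic subgroup alignments.

All-against-all pairwise similarities (alignment score over mean length,
min-max normalized to [0,1] like the benchmark score tables) define a graph
whose edges keep only pairs at or above a threshold - by default the cutoff
maximizing the MCC in the benchmark.  Clusters are the connected components
of the thresholded graph; each cluster is summarized by a center-star
multiple alignment built with the same trained matrix and gap penalties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import networkx as nx
import numpy as np

from .align import GapPenalties, encode_set, nw_align, _tss_sum
from .io import PeptideSet, SubstitutionMatrix
from .similarity import _normalize

EXPORT_FORMATS = ("sif", "graphml", "tsv")


@dataclass
class SimilarityNetwork:
    peptides: PeptideSet
    graph: nx.Graph  # nodes are record indices; edge attr "weight" = normalized similarity
    threshold: float

    @property
    def edges(self) -> list:
        """Undirected edges as (i, j, weight) with i < j."""
        return sorted(
            (min(i, j), max(i, j), d["weight"]) for i, j, d in self.graph.edges(data=True)
        )

    def node_name(self, index: int) -> str:
        rec = self.peptides[index]
        if rec.span is not None:
            return f"{rec.protein_id}:{rec.span[0]}-{rec.span[1]}"
        return f"{rec.protein_id}:{index}"


def pairwise_similarities(
    peptides: PeptideSet, matrix: SubstitutionMatrix, gaps: GapPenalties
) -> np.ndarray:
    """Length-normalized alignment scores for every unordered peptide pair."""
    seqs, lens = encode_set(peptides)
    n = len(peptides)
    sims = np.zeros((n, n))
    S = matrix.extended()
    for i in range(n):
        for j in range(i + 1, n):
            total, _ = _tss_sum(
                seqs[i : i + 1],
                lens[i : i + 1],
                seqs[j : j + 1],
                lens[j : j + 1],
                S,
                np.int64(gaps.open),
                np.int64(gaps.extend),
                False,
            )
            sims[i, j] = sims[j, i] = total
    return sims


def build_network(
    peptides: PeptideSet,
    matrix: SubstitutionMatrix,
    gaps: GapPenalties,
    threshold: float,
) -> SimilarityNetwork:
    """Thresholded all-against-all similarity network.

    Pair similarities are min-max normalized over all pairs (the same
    normalization the benchmark applies to score tables); an edge is kept iff
    its normalized similarity is >= threshold.
    """
    if len(peptides) < 2:
        raise ValueError("network needs at least 2 peptides")
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    sims = pairwise_similarities(peptides, matrix, gaps)
    n = len(peptides)
    iu = np.triu_indices(n, k=1)
    normalized = np.zeros_like(sims)
    normalized[iu] = _normalize(sims[iu])
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i, j in zip(*iu):
        w = float(normalized[i, j])
        if w >= threshold:
            graph.add_edge(int(i), int(j), weight=w)
    return SimilarityNetwork(peptides=peptides, graph=graph, threshold=threshold)


def extract_clusters(network: SimilarityNetwork) -> Tuple[list, list]:
    """Connected components of the thresholded graph.

    Returns ``(clusters, singletons)``: clusters are sorted index lists in
    decreasing size (ties by smallest member), singletons listed separately.
    """
    components = [sorted(c) for c in nx.connected_components(network.graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    clusters = [c for c in components if len(c) > 1]
    singletons = sorted(i for c in components if len(c) == 1 for i in c)
    return clusters, singletons


@dataclass
class ClusterAlignment:
    members: list  # PeptideRecords in output row order
    aligned: list  # gapped sequences, equal length
    center_index: int  # index into members of the center sequence

    @property
    def n_columns(self) -> int:
        return len(self.aligned[0]) if self.aligned else 0


def _merge_into_center(center_gapped: str, other_gapped: str, master: List[str]) -> List[str]:
    """Thread a pairwise alignment onto the master center gapping
    (once a gap, always a gap)."""
    merged_center: List[str] = []
    merged_other: List[str] = []
    mi = 0  # position in master center string
    pi = 0  # position in pairwise center string
    while mi < len(master[0]) or pi < len(center_gapped):
        m_char = master[0][mi] if mi < len(master[0]) else None
        p_char = center_gapped[pi] if pi < len(center_gapped) else None
        if m_char == "-" and (p_char != "-" or p_char is None):
            # master has a gap the pairwise alignment lacks
            merged_center.append("-")
            merged_other.append("-")
            mi += 1
        elif p_char == "-" and (m_char != "-" or m_char is None):
            # pairwise alignment inserts a new gap into the center
            for row_idx in range(len(master)):
                master[row_idx] = master[row_idx][:mi] + "-" + master[row_idx][mi:]
            merged_center.append("-")
            merged_other.append(other_gapped[pi])
            mi += 1
            pi += 1
        else:
            merged_center.append(m_char)
            merged_other.append(other_gapped[pi])
            mi += 1
            pi += 1
    master.append("".join(merged_other))
    return master


def center_star_msa(
    cluster: PeptideSet, matrix: SubstitutionMatrix, gaps: GapPenalties
) -> ClusterAlignment:
    """Center-star multiple alignment of a cluster.

    The center is the member with the highest summed pairwise similarity
    (ties to the first); all other members are globally aligned to the
    center and merged by the once-a-gap-always-a-gap rule.
    """
    members = list(cluster.records)
    if len(members) == 1:
        return ClusterAlignment(members=members, aligned=[members[0].sequence], center_index=0)
    sims = pairwise_similarities(cluster, matrix, gaps)
    center = int(np.argmax(sims.sum(axis=1)))
    master = [members[center].sequence]
    order = [center]
    for idx in range(len(members)):
        if idx == center:
            continue
        pair = nw_align(members[center].sequence, members[idx].sequence, matrix, gaps)
        master = _merge_into_center(pair.aligned_query, pair.aligned_target, master)
        order.append(idx)
    return ClusterAlignment(
        members=[members[i] for i in order], aligned=master, center_index=0
    )


def export_network(network: SimilarityNetwork, path, format: str = "tsv") -> None:
    """Write the network as SIF, GraphML, or an edge-list TSV."""
    if format not in EXPORT_FORMATS:
        raise ValueError(f"unknown network format {format!r}; expected one of {EXPORT_FORMATS}")
    if format == "graphml":
        named = nx.relabel_nodes(network.graph, {i: network.node_name(i) for i in network.graph})
        nx.write_graphml(named, path)
        return
    with open(path, "w") as out:
        if format == "sif":
            for i, j, _ in network.edges:
                out.write(f"{network.node_name(i)}\tsim\t{network.node_name(j)}\n")
            isolated = [i for i in network.graph if network.graph.degree[i] == 0]
            for i in isolated:
                out.write(f"{network.node_name(i)}\n")
        else:
            out.write("source\ttarget\tweight\n")
            for i, j, w in network.edges:
                out.write(f"{network.node_name(i)}\t{network.node_name(j)}\t{w:.6g}\n")


def read_sif_edge_count(path) -> int:
    """Count edges in a SIF file (helper for round-trip checks)."""
    count = 0
    with open(path) as handle:
        for line in handle:
            if len(line.split("\t")) == 3:
                count += 1
    return count


def alignment_to_fasta(alignment: ClusterAlignment, path) -> None:
    with open(path, "w") as out:
        for rec, row in zip(alignment.members, alignment.aligned):
            span = f"|{rec.span[0]}-{rec.span[1]}" if rec.span else ""
            out.write(f">{rec.protein_id}{span}\n{row}\n")
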