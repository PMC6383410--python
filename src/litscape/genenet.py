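"""Gene–gene literature co-occurrence networks.

The co-occurrence matrix A counts, for each unordered gene pair, the number
of publications whose abstract mentions both genes.  A strict threshold
turns A into an unweighted graph: an edge is drawn where A[i, j] > theta.
The default theta of 10 (more than ten joint abstracts) is conservative:
the fraction of realized gene pairs reaching such counts in a large corpus
is well below 0.0005, which ``pair_exceedance_probability`` measures.
Communities of the thresholded graph default to its connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np

from .collab import ENTITY_TOTAL, CooccurrenceMatrix, build_cooccurrence
from .corpus import Corpus, classify_genetics

__all__ = ["ThresholdedGraph", "gene_matrix", "threshold_graph",
           "pair_exceedance_probability", "communities",
           "export_graph", "read_graph"]


@dataclass
class ThresholdedGraph:
    """Unweighted gene graph from strict thresholding of a count matrix.

    ``edges`` holds unordered pairs as sorted 2-tuples; ``weights`` retains
    the source joint-publication count of each kept edge.  Labels without
    any edge remain listed (isolated genes are part of the vocabulary).
    """

    labels: list[str]
    edges: set[tuple[str, str]]
    theta: int
    weights: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for (a, b) in sorted(self.edges):
            g.add_edge(a, b, count=self.weights.get((a, b), 1))
        return g


def gene_matrix(corpus: Corpus, genetics_only: bool = True) -> CooccurrenceMatrix:
    """Joint-publication count matrix over deduplicated per-abstract gene sets.

    The diagonal stores each gene's own publication count
    (``entity_publication_total``); thresholding ignores it.
    """
    records = corpus.records
    if genetics_only:
        records = [r for r in records if classify_genetics(r)]
    return build_cooccurrence((r.gene_set for r in records), ENTITY_TOTAL)


def threshold_graph(A: CooccurrenceMatrix, theta: int = 10) -> ThresholdedGraph:
    """Edge (i, j) iff the off-diagonal count strictly exceeds ``theta``."""
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    edges: set[tuple[str, str]] = set()
    weights: dict[tuple[str, str], int] = {}
    n = len(A.labels)
    for i in range(n):
        for j in range(i + 1, n):
            c = int(A.counts[i, j])
            if c > theta:
                pair = (A.labels[i], A.labels[j])
                edges.add(pair)
                weights[pair] = c
    return ThresholdedGraph(list(A.labels), edges, theta, weights)


def pair_exceedance_probability(A: CooccurrenceMatrix, theta: int) -> float:
    """Fraction of co-occurring gene pairs whose joint count exceeds ``theta``.

    The denominator is the set of realized pairs (count >= 1), the only
    pairs observable from the literature itself.
    """
    n = len(A.labels)
    iu = np.triu_indices(n, k=1)
    pair_counts = A.counts[iu]
    realized = pair_counts[pair_counts >= 1]
    if realized.size == 0:
        raise ValueError("no co-occurring gene pairs: exceedance probability undefined")
    return float((realized > theta).sum() / realized.size)


def communities(graph: ThresholdedGraph, method: str = "components") -> list[set[str]]:
    """Communities of the edge-bearing subgraph, largest first.

    ``components`` (default) returns connected components, excluding isolated
    genes; ``modularity`` uses greedy modularity maximisation instead.  Both
    are deterministic; ties in size break on sorted member names.
    """
    g = graph.to_networkx()
    g.remove_nodes_from([n for n in graph.labels if g.degree(n) == 0])
    if method == "components":
        comms = [set(c) for c in nx.connected_components(g)]
    elif method == "modularity":
        comms = [set(c) for c in
                 nx.algorithms.community.greedy_modularity_communities(g)]
    else:
        raise ValueError(f"unknown community method {method!r}")
    return sorted(comms, key=lambda c: (-len(c), sorted(c)))


def export_graph(graph: ThresholdedGraph, path: str | Path,
                 format: str = "edgelist") -> None:
    """Serialize the graph; the edge set round-trips through ``read_graph``."""
    path = Path(path)
    if format == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tcount\n")
            for a, b in sorted(graph.edges):
                fh.write(f"{a}\t{b}\t{graph.weights.get((a, b), 1)}\n")
    elif format == "graphml":
        g = graph.to_networkx()
        g.graph["theta"] = graph.theta
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported graph format {format!r}")


def read_graph(path: str | Path, format: str = "edgelist",
               theta: int = 0) -> ThresholdedGraph:
    path = Path(path)
    if format == "edgelist":
        edges: set[tuple[str, str]] = set()
        weights: dict[tuple[str, str], int] = {}
        labels: set[str] = set()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("gene_a"):
                raise ValueError(f"{path}: malformed edge-list header")
            for line in fh:
                a, b, c = line.rstrip("\n").split("\t")
                pair = tuple(sorted((a, b)))
                edges.add(pair)
                weights[pair] = int(c)
                labels |= {a, b}
        return ThresholdedGraph(sorted(labels), edges, theta, weights)
    if format == "graphml":
        g = nx.read_graphml(path)
        edges = {tuple(sorted((a, b))) for a, b in g.edges}
        weights = {tuple(sorted((a, b))): int(d.get("count", 1))
                   for a, b, d in g.edges(data=True)}
        return ThresholdedGraph(sorted(g.nodes), edges,
                                int(g.graph.get("theta", theta)), weights)
    raise ValueError(f"unsupported graph format {format!r}")
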