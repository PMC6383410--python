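"""Gene x city publication counts and hierarchical clustering of cities.

Cities are compared by their publication-count profiles over a fixed list
of top genes: M[i, j] is the number of publications mentioning gene i with
an author in city j (a multi-city publication counts once per city).  City
column vectors are clustered agglomeratively with Ward's minimum-variance
criterion on Euclidean distances (the Ward.D2-equivalent Lance-Williams
update), with no standardization of the raw counts.  Per-gene proportions
(row-normalized M) show which cities carry each gene's literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

from .corpus import Corpus

__all__ = ["GeneCityMatrix", "Dendrogram", "gene_city_matrix", "ward_cluster",
           "gene_city_proportions", "to_newick", "cut"]


@dataclass
class GeneCityMatrix:
    genes: list[str]
    cities: list[str]
    counts: np.ndarray    # shape (len(genes), len(cities)), nonnegative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cities)):
            raise ValueError("counts shape does not match gene/city labels")
        if len(set(self.genes)) != len(self.genes) or len(set(self.cities)) != len(self.cities):
            raise ValueError("gene and city labels must be unique")
        if not np.issubdtype(self.counts.dtype, np.integer) or (self.counts < 0).any():
            raise ValueError("counts must be nonnegative integers")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.cities)


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over city labels (scipy linkage format)."""

    labels: list[str]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def gene_city_matrix(corpus: Corpus, top_genes: list[str],
                     focal_country: str) -> GeneCityMatrix:
    """Count publications per (gene, city) over the focal country's records."""
    if not top_genes:
        raise ValueError("top_genes must be non-empty")
    records = [r for r in corpus.records
               if r.countries and focal_country in r.countries and r.cities]
    cities = sorted(set().union(*(r.cities for r in records)) if records else set())
    counts = np.zeros((len(top_genes), len(cities)), dtype=np.int64)
    city_idx = {c: j for j, c in enumerate(cities)}
    gene_idx = {g: i for i, g in enumerate(top_genes)}
    for r in records:
        for g in r.gene_set & gene_idx.keys():
            for c in r.cities:
                counts[gene_idx[g], city_idx[c]] += 1
    return GeneCityMatrix(list(top_genes), cities, counts)


def ward_cluster(M: GeneCityMatrix) -> Dendrogram:
    """Ward/Euclidean agglomerative clustering of city column vectors.

    Deterministic given the matrix; permuting city input order changes leaf
    identities but no merge heights.
    """
    if len(M.cities) < 2:
        raise ValueError(f"need >= 2 cities to cluster, got {len(M.cities)}")
    X = M.counts.T.astype(float)    # cities x genes
    Z = linkage(X, method="ward", metric="euclidean")
    return Dendrogram(list(M.cities), Z)


def cut(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Flat clustering into ``k`` groups; returns city -> cluster id."""
    assignment = fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    return dict(zip(dendrogram.labels, (int(a) for a in assignment)))


def gene_city_proportions(M: GeneCityMatrix) -> pd.DataFrame:
    """Row-normalized gene x city matrix; every kept row sums to 1.

    Genes with no publications in any city are excluded with a warning: a
    proportion over an empty row is undefined.
    """
    totals = M.counts.sum(axis=1)
    zero = [g for g, t in zip(M.genes, totals) if t == 0]
    if zero:
        warnings.warn(f"excluding genes with zero city publications: {zero}")
    keep = totals > 0
    props = M.counts[keep].astype(float) / totals[keep, None]
    return pd.DataFrame(props, index=[g for g, k in zip(M.genes, keep) if k],
                        columns=M.cities)


def to_newick(dendrogram: Dendrogram, path: str | Path | None = None) -> str:
    """Newick serialization with branch lengths from merge-height differences."""
    root = to_tree(dendrogram.linkage)
    labels = dendrogram.labels

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        inner = f"({render(node.left, node.dist)},{render(node.right, node.dist)})"
        return f"{inner}:{length:.10g}"

    newick = (f"({render(root.left, root.dist)},"
              f"{render(root.right, root.dist)});")
    if path is not None:
        Path(path).write_text(newick + "\n", encoding="utf-8")
    return newick
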