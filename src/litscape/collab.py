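"""Collaboration matrices at country and city level.

A collaboration matrix is a labelled symmetric nonnegative-integer matrix:
the off-diagonal entry (i, j) counts publications on which both entities
appear.  The diagonal can carry one of two meanings, recorded on the matrix:

* ``self_only_publications`` — entry (i, i) counts publications whose entity
  set is exactly {i} (a "self-collaboration": all resolved authors from one
  country or one city).  Used for country and city collaboration matrices.
* ``entity_publication_total`` — entry (i, i) is the number of publications
  mentioning entity i at all.  Used for gene co-occurrence matrices.

Per-entity publication totals (|{publications whose set contains i}|) are a
separate vector, since for multi-entity publications they are not row sums
of either diagonal convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .corpus import Corpus

__all__ = [
    "CooccurrenceMatrix",
    "build_cooccurrence",
    "country_matrix",
    "city_matrix",
    "publication_totals",
    "group_others",
    "chord_export",
    "self_collaboration_pct",
    "partner_counts",
]

SELF_ONLY = "self_only_publications"
ENTITY_TOTAL = "entity_publication_total"


@dataclass
class CooccurrenceMatrix:
    labels: list[str]
    counts: np.ndarray
    diagonal_semantics: str = SELF_ONLY

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n})")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("co-occurrence matrix must be symmetric")
        if self.diagonal_semantics not in (SELF_ONLY, ENTITY_TOTAL):
            raise ValueError(f"unknown diagonal semantics {self.diagonal_semantics!r}")

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def __getitem__(self, pair: tuple[str, str]) -> int:
        i, j = (self.index_of(p) for p in pair)
        return int(self.counts[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="")


def build_cooccurrence(entity_sets: Iterable[frozenset[str] | set[str]],
                       diagonal_semantics: str = SELF_ONLY,
                       labels: list[str] | None = None) -> CooccurrenceMatrix:
    """Accumulate per-publication entity sets into a symmetric count matrix.

    Every unordered pair within a set contributes +1 to both symmetric
    cells.  Diagonal handling follows ``diagonal_semantics`` (see module
    docstring).
    """
    sets = [frozenset(s) for s in entity_sets]
    if labels is None:
        labels = sorted(set().union(*sets)) if sets else []
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    counts = np.zeros((n, n), dtype=np.int64)
    for s in sets:
        members = sorted(m for m in s if m in index)
        if diagonal_semantics == SELF_ONLY:
            if len(s) == 1 and members:
                i = index[members[0]]
                counts[i, i] += 1
        else:
            for m in members:
                counts[index[m], index[m]] += 1
        for a, b in combinations(members, 2):
            counts[index[a], index[b]] += 1
            counts[index[b], index[a]] += 1
    return CooccurrenceMatrix(labels, counts, diagonal_semantics)


def _located(corpus: Corpus) -> list:
    recs = [r for r in corpus.records if r.countries]
    if any(r.countries is None for r in corpus.records):
        raise ValueError("country extraction has not run on this corpus")
    return recs


def country_matrix(corpus: Corpus) -> CooccurrenceMatrix:
    """Country collaboration matrix; diagonal counts single-country papers."""
    return build_cooccurrence((r.countries for r in _located(corpus)), SELF_ONLY)


def city_matrix(corpus: Corpus, focal_country: str) -> CooccurrenceMatrix:
    """City collaboration matrix within ``focal_country``.

    A publication with resolved cities {Helsinki, Tampere, Oulu} contributes
    one collaboration to each of the three unordered pairs; a publication
    with a singleton city set (possibly several institutions in one city)
    counts as one self-collaboration on that city's diagonal.
    """
    sets = [r.cities for r in corpus.records
            if r.countries and focal_country in r.countries and r.cities]
    return build_cooccurrence(sets, SELF_ONLY)


def publication_totals(corpus: Corpus, level: str = "country",
                       focal_country: str | None = None) -> pd.Series:
    """Publications per entity: |{pubs whose entity set contains i}|."""
    from collections import Counter
    counter: Counter = Counter()
    for r in _located(corpus) if level == "country" else corpus.records:
        if level == "country":
            entities = r.countries
        elif level == "city":
            if not (r.countries and focal_country in r.countries):
                continue
            entities = r.cities or set()
        else:
            raise ValueError(f"unknown level {level!r}")
        for e in entities:
            counter[e] += 1
    keys = sorted(counter)
    return pd.Series([counter[k] for k in keys], index=pd.Index(keys, name=level),
                     name="publications")


def group_others(matrix: CooccurrenceMatrix, totals: pd.Series,
                 min_pubs: int = 1000, label: str = "Others") -> CooccurrenceMatrix:
    """Merge all entities with fewer than ``min_pubs`` publications into one
    ``Others`` row/column by element-wise summation (symmetry and the grand
    total of entries are preserved)."""
    small = [lab for lab in matrix.labels if int(totals.get(lab, 0)) < min_pubs]
    if not small:
        return matrix
    keep = [lab for lab in matrix.labels if lab not in small]
    new_labels = keep + [label]
    idx = {lab: i for i, lab in enumerate(matrix.labels)}
    keep_idx = [idx[lab] for lab in keep]
    small_idx = [idx[lab] for lab in small]
    n = len(new_labels)
    counts = np.zeros((n, n), dtype=matrix.counts.dtype)
    counts[:-1, :-1] = matrix.counts[np.ix_(keep_idx, keep_idx)]
    counts[:-1, -1] = matrix.counts[np.ix_(keep_idx, small_idx)].sum(axis=1)
    counts[-1, :-1] = counts[:-1, -1]
    counts[-1, -1] = matrix.counts[np.ix_(small_idx, small_idx)].sum()
    return CooccurrenceMatrix(new_labels, counts, matrix.diagonal_semantics)


def chord_export(matrix: CooccurrenceMatrix, k: int,
                 totals: pd.Series | None = None) -> pd.DataFrame:
    """Three-column (source, target, value) table of the unordered pairs among
    the top-``k`` entities, for chord-diagram tooling.

    Ranking uses ``totals`` when given, otherwise matrix row sums.  Each pair
    with a positive co-occurrence count is emitted once, sorted by descending
    value then by labels.
    """
    if k > len(matrix.labels):
        raise ValueError(f"k={k} exceeds the number of entities ({len(matrix.labels)})")
    if totals is not None:
        rank = {lab: float(totals.get(lab, 0)) for lab in matrix.labels}
    else:
        sums = matrix.counts.sum(axis=1)
        rank = {lab: float(sums[i]) for i, lab in enumerate(matrix.labels)}
    top = sorted(matrix.labels, key=lambda lab: (-rank[lab], lab))[:k]
    rows = []
    for a, b in combinations(sorted(top), 2):
        v = matrix[a, b]
        if v > 0:
            rows.append((a, b, v))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return pd.DataFrame(rows, columns=["source", "target", "value"])


def self_collaboration_pct(corpus: Corpus, country: str) -> float:
    """Percentage of a country's publications authored only from that country.

    100 x |{pubs with country set == {country}}| / |{pubs containing country}|,
    kept at full precision (round only when reporting).
    """
    containing = [r for r in _located(corpus) if country in r.countries]
    if not containing:
        raise KeyError(f"country {country!r} has no located publications")
    self_only = sum(1 for r in containing if r.countries == {country})
    return 100.0 * self_only / len(containing)


def partner_counts(corpus: Corpus, country: str) -> pd.Series:
    """Joint-publication counts between ``country`` and each partner country;
    each partner on a multi-country paper counts once per publication."""
    from collections import Counter
    counter: Counter = Counter()
    for r in _located(corpus):
        if country in r.countries:
            for other in r.countries - {country}:
                counter[other] += 1
    keys = sorted(counter, key=lambda c: (-counter[c], c))
    return pd.Series([counter[k] for k in keys], index=pd.Index(keys, name="country"),
                     name="joint_publications")
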