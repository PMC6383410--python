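"""Exact enrichment test for literature attention of gene sets.

Are the genes a city works on the same genes the world studies most?  Each
gene studied worldwide gets two binary attributes: "HS" (highly studied —
worldwide publication count strictly above a threshold gamma) and "City"
(mentioned in at least one publication of the city).  The 2x2 contingency
table of these attributes

                City-in    City-out
    HS-yes        x          n12      | n1+
    HS-no         n21        n22      | n2+
    ------------------------------------------
                  n+1        n+2      | n

is tested against the null that highly-studied status is independent of the
city, using the exact hypergeometric sampling distribution

    P(k) = C(n+1, k) * C(n - n+1, n1+ - k) / C(n, n1+)

with the upper-tail p-value  p = P(K > x) = sum_{k = x+1}^{min(n1+, n+1)} P(k).
Note the tail *strictly excludes* the observed x; the conventional one-sided
exact test (which includes x) is available via ``include_observed=True``.

Because the correct gamma is unknown, the test is repeated over a sweep of
thresholds with Bonferroni control at alpha / (number of thresholds).  At
the degenerate extremes — no gene selected as highly studied, or all genes
selected — the table has a zero margin and the p-value is 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = ["ContingencyTable", "EnrichmentResult", "assign_attributes",
           "build_contingency", "exact_pvalue", "sweep", "results_to_frame"]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts x, n12, n21, n22 of the HS x City cross-classification."""

    x: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        for name in ("x", "n12", "n21", "n22"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")

    @property
    def n_plus1(self) -> int:   # genes studied in the city
        return self.x + self.n21

    @property
    def n_plus2(self) -> int:   # genes not studied in the city
        return self.n12 + self.n22

    @property
    def n_1plus(self) -> int:   # highly studied genes
        return self.x + self.n12

    @property
    def n_2plus(self) -> int:   # not highly studied genes
        return self.n21 + self.n22

    @property
    def n(self) -> int:         # all genes studied worldwide
        return self.n_1plus + self.n_2plus

    def check_margins(self) -> None:
        assert self.n == self.n_plus1 + self.n_plus2 == self.n_1plus + self.n_2plus


@dataclass
class EnrichmentResult:
    gamma: int
    table: ContingencyTable
    p_value: float
    significant: bool


def assign_attributes(world_counts: Mapping[str, int], city_genes: Iterable[str],
                      gamma: int) -> pd.DataFrame:
    """Per-gene (HS, City) labels over the worldwide gene list.

    HS-yes iff the worldwide count strictly exceeds ``gamma``; City-in iff
    the gene appears in the city's gene set.  A city gene absent from the
    worldwide list is impossible by construction and raises.
    """
    world = dict(world_counts.items())
    city = set(city_genes)
    missing = city - world.keys()
    if missing:
        raise ValueError(f"city genes absent from worldwide counts: {sorted(missing)}")
    genes = sorted(world)
    return pd.DataFrame(
        {"hs": [world[g] > gamma for g in genes],
         "in_city": [g in city for g in genes]},
        index=pd.Index(genes, name="gene"))


def build_contingency(labels: pd.DataFrame) -> ContingencyTable:
    """Cross-tabulate the per-gene attribute labels into a 2x2 table."""
    hs = labels["hs"].to_numpy(dtype=bool)
    city = labels["in_city"].to_numpy(dtype=bool)
    t = ContingencyTable(
        x=int((hs & city).sum()),
        n12=int((hs & ~city).sum()),
        n21=int((~hs & city).sum()),
        n22=int((~hs & ~city).sum()),
    )
    t.check_margins()
    return t


def _log_choose(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def log_pmf(k: int, table: ContingencyTable) -> float:
    """log P(k) of the sampling distribution; -inf outside the support."""
    n, n_plus1, n_1plus = table.n, table.n_plus1, table.n_1plus
    if k < 0 or k > n_plus1 or n_1plus - k < 0 or n_1plus - k > n - n_plus1:
        return -np.inf
    return (_log_choose(n_plus1, k)
            + _log_choose(n - n_plus1, n_1plus - k)
            - _log_choose(n, n_1plus))


def exact_pvalue(table: ContingencyTable, include_observed: bool = False) -> float:
    """Upper-tail exact p-value, computed in log-space via log-gamma.

    Strictly excludes the observed x from the tail unless
    ``include_observed`` is set.  Degenerate tables (any zero margin) return
    1.0: with no gene selected, or every gene selected, nothing can be
    enriched.
    """
    table.check_margins()
    if min(table.n_plus1, table.n_plus2, table.n_1plus, table.n_2plus) == 0:
        return 1.0
    lo = table.x if include_observed else table.x + 1
    hi = min(table.n_1plus, table.n_plus1)
    if lo > hi:
        return 0.0
    logs = [log_pmf(k, table) for k in range(lo, hi + 1)]
    return float(min(1.0, np.exp(logsumexp(logs))))


def sweep(world_counts: Mapping[str, int], city_genes: Iterable[str],
          gammas: list[int], alpha: float = 0.05,
          include_observed: bool = False) -> list[EnrichmentResult]:
    """Run the exact test at every threshold with Bonferroni control.

    The significance cutoff is alpha / len(gammas); the threshold list is
    taken verbatim from the caller.
    """
    if not gammas:
        raise ValueError("gammas must be non-empty")
    city = set(city_genes)
    m = len(gammas)
    results = []
    for gamma in gammas:
        labels = assign_attributes(world_counts, city, gamma)
        table = build_contingency(labels)
        p = exact_pvalue(table, include_observed=include_observed)
        results.append(EnrichmentResult(gamma=int(gamma), table=table, p_value=p,
                                        significant=p < alpha / m))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gamma": r.gamma, "x": r.table.x, "n12": r.table.n12,
          "n21": r.table.n21, "n22": r.table.n22,
          "p_value": r.p_value, "significant": r.significant}
         for r in results])
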