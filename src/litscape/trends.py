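"""Time trends in the percentage of genetics research.

For an entity (one country, or all countries pooled) the yearly percentage
of genetics research is 100 x (genetics publications) / (all publications)
in that year, computed only for years with at least one publication.  Years
are grouped into three fixed intervals, A: 1987-1996, B: 1997-2006 and
C: 2007-2018, and for each adjacent interval pair an ordinary least squares
regression of the yearly percentages on a 0/1 interval indicator tests
whether the mean level shifted: the slope equals the difference of interval
means and its two-sided t-test is the reported hypothesis test.  Testing
many entities at once uses a Bonferroni correction at alpha / m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .corpus import Corpus, classify_genetics

__all__ = ["DEFAULT_INTERVALS", "TrendSeries", "RegressionResult",
           "genetics_percentage", "build_series", "interval_regression",
           "bonferroni"]

DEFAULT_INTERVALS: dict[str, tuple[int, int]] = {
    "A": (1987, 1996),
    "B": (1997, 2006),
    "C": (2007, 2018),
}

ALL_COUNTRIES = "All countries"


def genetics_percentage(n_genetics: int, n_total: int) -> float:
    """100 x n_genetics / n_total at full precision (round only to report)."""
    if n_total < 1:
        raise ValueError("percentage undefined for zero total publications")
    if n_genetics > n_total:
        raise ValueError(f"n_genetics={n_genetics} exceeds n_total={n_total}")
    return 100.0 * n_genetics / n_total


@dataclass
class TrendSeries:
    """Yearly genetics percentages for one entity."""

    entity: str
    points: dict[int, float]
    intervals: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_INTERVALS))

    def interval_of(self, year: int) -> str | None:
        hits = [lab for lab, (lo, hi) in self.intervals.items() if lo <= year <= hi]
        if len(hits) > 1:
            raise ValueError(f"year {year} falls in overlapping intervals {hits}")
        return hits[0] if hits else None

    def interval_points(self, label: str) -> list[float]:
        lo, hi = self.intervals[label]
        return [p for y, p in sorted(self.points.items()) if lo <= y <= hi]


@dataclass
class RegressionResult:
    entity: str
    pair: tuple[str, str]
    beta1: float
    p_value: float
    n_points: int


def build_series(corpus: Corpus, entity: str = ALL_COUNTRIES,
                 intervals: Mapping[str, tuple[int, int]] | None = None) -> TrendSeries:
    """Yearly percentage-of-genetics series for one country or all pooled.

    Restricts to publications whose country set contains the entity (or all
    located publications for the pooled series); years without publications
    are omitted, not imputed as zero.
    """
    if entity == ALL_COUNTRIES:
        records = [r for r in corpus.records]
    else:
        records = [r for r in corpus.records if r.countries and entity in r.countries]
        if not records:
            raise KeyError(f"entity {entity!r} has no publications in the corpus")
    totals: dict[int, int] = {}
    genetics: dict[int, int] = {}
    for r in records:
        totals[r.year] = totals.get(r.year, 0) + 1
        if classify_genetics(r):
            genetics[r.year] = genetics.get(r.year, 0) + 1
    points = {y: genetics_percentage(genetics.get(y, 0), n)
              for y, n in sorted(totals.items())}
    return TrendSeries(entity=entity, points=points,
                       intervals=dict(intervals or DEFAULT_INTERVALS))


def interval_regression(series: TrendSeries,
                        pair: tuple[str, str] = ("A", "B")) -> RegressionResult:
    """OLS of yearly percentages on a 0/1 interval indicator.

    With indicator coding the slope is exactly the difference of interval
    means; the p-value is the standard two-sided t-test of a zero slope.
    Each interval must contribute at least two yearly points.
    """
    first, second = pair
    y1 = series.interval_points(first)
    y2 = series.interval_points(second)
    for label, pts in ((first, y1), (second, y2)):
        if len(pts) < 2:
            raise ValueError(
                f"interval {label!r} has {len(pts)} yearly point(s); need >= 2")
    y = np.asarray(y1 + y2, dtype=float)
    indicator = np.concatenate([np.zeros(len(y1)), np.ones(len(y2))])
    model = sm.OLS(y, sm.add_constant(indicator)).fit()
    return RegressionResult(entity=series.entity, pair=(first, second),
                            beta1=float(model.params[1]),
                            p_value=float(model.pvalues[1]),
                            n_points=len(y))


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Significance flags at the Bonferroni-adjusted level alpha / m."""
    if len(p_values) == 0:
        raise ValueError("p_values must be non-empty")
    cutoff = alpha / len(p_values)
    return [p < cutoff for p in p_values]


def regression_table(results: Sequence[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"entity": r.entity, "pair": "-".join(r.pair), "beta1": r.beta1,
          "p_value": r.p_value, "n_points": r.n_points} for r in results])
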