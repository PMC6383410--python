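"""Synthetic annotated corpora with planted statistical structure.

The generator emulates the gross statistical shape of a large disease-
focused literature corpus so that every pipeline stage can be exercised and
validated without any download:

* gene popularity follows a Zipf law over a fixed vocabulary (the leading
  symbols are well-known prostate-cancer genes, the rest synthetic);
* one dominant country plus a long tail of smaller contributors, with a
  configurable fraction of international (multi-country) papers;
* the fraction of genetics papers (papers mentioning >= 1 gene) is set per
  time interval and rises between the early and late intervals;
* papers with an author in the focal country receive cities drawn from a
  weight table patterned on real per-city publication counts.

Affiliation strings are synthesized as "Institute, City, Country" so the
text-matching geocoder is exercised end-to-end.  All randomness flows from
a single seed, split into independent per-stage streams, so adding a stage
never perturbs the draws of earlier stages; the same seed and spec yield a
byte-identical corpus.  Alongside the corpus a ``GroundTruth`` records the
planted quantities that recovery tests check against.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corpus import Corpus, PublicationRecord, classify_genetics

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "plant_gene_pair",
           "default_country_weights", "default_city_weights", "gene_vocabulary"]

_WEIGHT_TOL = 1e-9

# Leading vocabulary symbols: genes prominent in the prostate-cancer
# literature, in planted popularity order.
_KNOWN_GENES = [
    "KLK3", "NPEPPS", "AR", "KLK2", "TMPRSS2", "ERG", "MAPK1", "MAPK3",
    "CDKN2A", "PTEN", "KCNH2", "HTRA1", "ELANE", "KLK6", "TGM4", "HK2",
    "KCNA5", "HOOK2", "ATP2A2", "MYLIP", "MARCH8", "MSMP", "ACPP", "SLC20A2",
]


def gene_vocabulary(n_genes: int) -> list[str]:
    """Vocabulary in planted popularity order (rank 1 most popular)."""
    if n_genes <= len(_KNOWN_GENES):
        return _KNOWN_GENES[:n_genes]
    return _KNOWN_GENES + [f"GS{i:04d}" for i in range(1, n_genes - len(_KNOWN_GENES) + 1)]


def default_country_weights() -> dict[str, float]:
    """Dominant-country + long-tail contribution shares."""
    raw = {
        "United States": 44.0, "China": 6.0, "Japan": 5.0, "United Kingdom": 5.0,
        "Germany": 4.5, "Italy": 4.0, "Canada": 3.5, "France": 3.0,
        "Netherlands": 2.5, "Australia": 2.5, "Spain": 2.0, "Finland": 1.2,
        "Sweden": 1.5, "South Korea": 1.5, "India": 1.3, "Brazil": 1.2,
        "Switzerland": 1.1, "Austria": 0.9, "Belgium": 0.9, "Denmark": 0.8,
        "Norway": 0.8, "Poland": 0.8, "Greece": 0.7, "Turkey": 0.7,
        "Israel": 0.7, "Taiwan": 0.7, "Portugal": 0.6, "Ireland": 0.6,
        "Czech Republic": 0.5, "Hungary": 0.5, "Mexico": 0.5, "Argentina": 0.5,
    }
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def default_city_weights() -> dict[str, float]:
    """Finnish city shares patterned on real per-city publication counts."""
    raw = {"Helsinki": 180, "Tampere": 165, "Turku": 116, "Oulu": 64,
           "Kuopio": 58, "Espoo": 12, "Jyväskylä": 1}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def _default_fractions() -> dict[str, float]:
    return {"A": 0.40, "B": 0.58, "C": 0.57}


def _default_intervals() -> dict[str, tuple[int, int]]:
    return {"A": (1987, 1996), "B": (1997, 2006), "C": (2007, 2018)}


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults emulate the study conditions at a
    5,000-publication scale (~300 genes keeps the corpus's publications-per-
    gene ratio; Zipf exponent 1.1 reproduces a top-gene share near 20%;
    five genes per genetics abstract reflects family-expanded annotations)."""

    n_pubs: int = 5000
    year_range: tuple[int, int] = (1987, 2018)
    country_weights: dict[str, float] = field(default_factory=default_country_weights)
    p_international: float = 0.2
    n_genes: int = 300
    zipf_exponent: float = 1.1
    genes_per_pub: float = 5.0
    genetics_fraction_by_interval: dict[str, float] = field(default_factory=_default_fractions)
    intervals: dict[str, tuple[int, int]] = field(default_factory=_default_intervals)
    focal_country: str = "Finland"
    city_weights: dict[str, float] = field(default_factory=default_city_weights)
    p_multi_city: float = 0.3
    p_unlocatable: float = 0.0
    planted_enriched_city_genes: frozenset[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_pubs < 0:
            bad.append("n_pubs")
        if self.year_range[0] > self.year_range[1]:
            bad.append("year_range")
        for name in ("p_international", "p_multi_city", "p_unlocatable"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                bad.append(name)
        for name in ("country_weights", "city_weights"):
            w = getattr(self, name)
            if not w or any(v < 0 for v in w.values()) or \
                    abs(sum(w.values()) - 1.0) > _WEIGHT_TOL:
                bad.append(name)
        if self.n_genes < 1:
            bad.append("n_genes")
        if self.zipf_exponent <= 0:
            bad.append("zipf_exponent")
        if self.genes_per_pub < 1:
            bad.append("genes_per_pub")
        for label, p in self.genetics_fraction_by_interval.items():
            if not 0.0 <= p <= 1.0:
                bad.append(f"genetics_fraction_by_interval[{label}]")
        for y in range(self.year_range[0], self.year_range[1] + 1):
            if not any(lo <= y <= hi for lo, hi in self.intervals.values()):
                bad.append("intervals")
                break
        if bad:
            raise ValueError(f"invalid synthetic spec fields: {sorted(set(bad))}")

    def interval_of(self, year: int) -> str:
        for label, (lo, hi) in self.intervals.items():
            if lo <= year <= hi:
                return label
        raise ValueError(f"year {year} outside all intervals")


@dataclass
class GroundTruth:
    """Planted quantities, plus realized counts tallied during generation."""

    genetics_fraction_by_interval: dict[str, float]
    realized_genetics_by_interval: dict[str, tuple[int, int]]   # (genetics, total)
    gene_rank: list[str]                                        # planted popularity order
    planted_enriched_genes: list[str]
    unlocatable_ids: list[str]
    international_ids: list[str]
    first_mentions: dict[str, int]                              # gene -> earliest year

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True),
                              encoding="utf-8")


_STAGES = ["years", "genetics", "gene_counts", "gene_choice",
           "countries", "cities", "unlocatable"]


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def _affiliation(city: str, country: str, i: int) -> str:
    return f"Department of Oncology, Research Institute {i % 97}, {city}, {country}"


def generate(spec: SyntheticSpec) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus of exactly ``spec.n_pubs`` annotated records."""
    spec.validate()
    rngs = _stage_rngs(spec.seed)
    n = spec.n_pubs
    lo, hi = spec.year_range

    years = rngs["years"].integers(lo, hi + 1, size=n)
    frac = np.array([spec.genetics_fraction_by_interval[spec.interval_of(int(y))]
                     for y in years])
    is_genetics = rngs["genetics"].random(n) < frac
    n_gene_draws = 1 + rngs["gene_counts"].poisson(spec.genes_per_pub - 1.0, size=n)

    vocab = gene_vocabulary(spec.n_genes)
    zipf = np.arange(1, spec.n_genes + 1, dtype=float) ** (-spec.zipf_exponent)
    zipf /= zipf.sum()

    country_names = list(spec.country_weights)
    country_probs = np.array([spec.country_weights[c] for c in country_names])
    city_names = list(spec.city_weights)
    city_probs = np.array([spec.city_weights[c] for c in city_names])
    planted = sorted(spec.planted_enriched_city_genes or ())

    rng_genes = rngs["gene_choice"]
    rng_country = rngs["countries"]
    rng_city = rngs["cities"]
    unlocatable = rngs["unlocatable"].random(n) < spec.p_unlocatable

    records: list[PublicationRecord] = []
    gt_realized: dict[str, list[int]] = {k: [0, 0] for k in spec.intervals}
    international_ids: list[str] = []
    unlocatable_ids: list[str] = []
    first_seen: dict[str, int] = {}

    for i in range(n):
        pub_id = f"SYN{i:07d}"
        year = int(years[i])
        interval = spec.interval_of(year)
        gt_realized[interval][1] += 1

        # countries: one primary draw, extra draws without replacement for
        # international papers, with a geometric tail beyond two
        countries = [country_names[rng_country.choice(len(country_names), p=country_probs)]]
        if rng_country.random() < spec.p_international:
            while len(countries) < len(country_names):
                remaining = [c for c in country_names if c not in countries]
                probs = np.array([spec.country_weights[c] for c in remaining])
                probs /= probs.sum()
                countries.append(remaining[rng_country.choice(len(remaining), p=probs)])
                if len(countries) >= 2 and rng_country.random() >= 0.3:
                    break
            international_ids.append(pub_id)

        # genes
        genes: list[str] = []
        if is_genetics[i]:
            gt_realized[interval][0] += 1
            k = min(int(n_gene_draws[i]), spec.n_genes)
            if planted and spec.focal_country in countries and rng_genes.random() < 0.9:
                kk = min(k, len(planted))
                picks = rng_genes.choice(len(planted), size=kk, replace=False)
                genes = [planted[j] for j in picks]
            else:
                picks = rng_genes.choice(spec.n_genes, size=k, replace=False, p=zipf)
                genes = [vocab[j] for j in picks]
            for g in genes:
                if g not in first_seen or year < first_seen[g]:
                    first_seen[g] = year

        # cities within the focal country
        cities: list[str] = []
        if spec.focal_country in countries:
            cities = [city_names[rng_city.choice(len(city_names), p=city_probs)]]
            if rng_city.random() < spec.p_multi_city:
                while len(cities) < len(city_names):
                    remaining = [c for c in city_names if c not in cities]
                    probs = np.array([spec.city_weights[c] for c in remaining])
                    probs /= probs.sum()
                    cities.append(remaining[rng_city.choice(len(remaining), p=probs)])
                    if rng_city.random() >= 0.3:
                        break

        # affiliations
        if unlocatable[i]:
            affiliations = [f"Department of Oncology, Independent Research Organisation {i % 97}"]
            unlocatable_ids.append(pub_id)
        else:
            affiliations = []
            for country in countries:
                if country == spec.focal_country and cities:
                    for c in cities:
                        affiliations.append(_affiliation(c, country, i))
                else:
                    affiliations.append(_affiliation(f"{country} City", country, i))

        records.append(PublicationRecord(pub_id=pub_id, year=year,
                                         affiliations=affiliations, genes=genes))

    corpus = Corpus(records, provenance={"source": f"synthetic(seed={spec.seed})"})
    truth = GroundTruth(
        genetics_fraction_by_interval=dict(spec.genetics_fraction_by_interval),
        realized_genetics_by_interval={k: (v[0], v[1]) for k, v in gt_realized.items()},
        gene_rank=list(vocab),
        planted_enriched_genes=list(planted),
        unlocatable_ids=unlocatable_ids,
        international_ids=international_ids,
        first_mentions=dict(sorted(first_seen.items())),
    )
    return corpus, truth


def plant_gene_pair(corpus: Corpus, gene_a: str, gene_b: str, n_joint: int,
                    seed: int = 0) -> Corpus:
    """Return a copy of the corpus in which *exactly* ``n_joint`` records
    contain both genes, inserted into randomly chosen genetics records.

    Any pre-existing joint occurrence elsewhere is broken by removing
    ``gene_b`` from those records, so the planted joint count is exact.
    """
    out = copy.deepcopy(corpus)
    genetics_idx = [i for i, r in enumerate(out.records) if classify_genetics(r)]
    if n_joint > len(genetics_idx):
        raise ValueError(f"n_joint={n_joint} exceeds the {len(genetics_idx)} "
                         "genetics records available")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(genetics_idx, size=n_joint, replace=False).tolist()) \
        if n_joint else set()
    for i, r in enumerate(out.records):
        if i in chosen:
            for g in (gene_a, gene_b):
                if g not in r.gene_set:
                    r.genes.append(g)
        elif gene_a in r.gene_set and gene_b in r.gene_set:
            r.genes = [g for g in r.genes if g != gene_b]
    out.provenance.setdefault("planted", []).append(
        {"pair": [gene_a, gene_b], "n_joint": int(n_joint), "seed": int(seed)})
    return out
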