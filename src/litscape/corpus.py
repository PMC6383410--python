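"""Annotated publication records and corpus-level counting.

The unit of analysis is one abstract-bearing publication carrying a list of
raw author affiliations and the gene symbols recognised in its abstract.
All counting operations work on the *deduplicated* per-publication gene set:
a publication mentioning a gene five times still contributes one count,
because every downstream network and enrichment construction is
publication-based.  Raw mention counting is available as an option.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PublicationRecord",
    "Corpus",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "classify_genetics",
    "gene_publication_counts",
    "first_mention",
    "top_genes",
    "write_counts_tsv",
]


class CorpusError(ValueError):
    """Raised for invalid corpora (duplicate ids, malformed records)."""


@dataclass
class PublicationRecord:
    """One annotated publication.

    ``countries`` is ``None`` before geographic extraction has run; after
    extraction it is a set of canonical country names, empty when no
    affiliation could be located (the "NA" outcome).  ``cities`` follows the
    same convention for cities within a focal country.
    """

    pub_id: str
    year: int
    affiliations: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    countries: set[str] | None = None
    cities: set[str] | None = None

    @property
    def gene_set(self) -> frozenset[str]:
        """Deduplicated gene symbols — the unit used by all counting."""
        return frozenset(self.genes)

    def validate(self) -> None:
        if not self.pub_id:
            raise CorpusError("record with empty pub_id")
        if not isinstance(self.year, int):
            raise CorpusError(f"record {self.pub_id!r}: year must be an integer")
        for g in self.genes:
            if not isinstance(g, str) or not g:
                raise CorpusError(f"record {self.pub_id!r}: empty gene symbol")


@dataclass
class Corpus:
    """A list of publication records plus free-form provenance metadata.

    ``provenance['filters']`` accumulates ``{"step": name, "dropped": n}``
    entries, one per filtering step applied, so the accounting of removed
    records is always reconstructible.
    """

    records: list[PublicationRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.provenance.setdefault("filters", [])
        seen: set[str] = set()
        for r in self.records:
            if r.pub_id in seen:
                raise CorpusError(f"duplicate pub_id {r.pub_id!r}")
            seen.add(r.pub_id)

    def __len__(self) -> int:
        return len(self.records)

    def add_filter_step(self, step: str, dropped: int) -> None:
        self.provenance["filters"].append({"step": step, "dropped": int(dropped)})

    def total_dropped(self) -> int:
        return sum(f["dropped"] for f in self.provenance["filters"])


def _parse_year(value) -> int | None:
    try:
        return int(str(value).strip())
    except (TypeError, ValueError):
        return None


def _record_from_mapping(raw: Mapping) -> PublicationRecord | None:
    if "pub_id" not in raw or raw["pub_id"] in (None, ""):
        raise CorpusError(f"record missing pub_id: {dict(raw)!r}")
    year = _parse_year(raw.get("year"))
    if year is None:
        return None
    rec = PublicationRecord(
        pub_id=str(raw["pub_id"]),
        year=year,
        affiliations=list(raw.get("affiliations") or []),
        genes=[str(g) for g in (raw.get("genes") or [])],
    )
    rec.validate()
    return rec


def read_corpus(path: str | Path, format: str | None = None,
                year_range: tuple[int, int] | None = None) -> Corpus:
    """Read a corpus from JSONL (canonical) or CSV.

    Records with a missing or unparseable year are dropped and counted in
    provenance; with ``year_range`` given, out-of-range years are dropped
    and counted as a separate filter step.  A duplicate ``pub_id`` raises
    :class:`CorpusError` naming the id.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unsupported corpus format {format!r}")

    raws: list[Mapping] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    raws.append(json.loads(line))
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                row = dict(row)
                row["affiliations"] = [a for a in (row.get("affiliations") or "").split(";") if a]
                row["genes"] = [g for g in (row.get("genes") or "").split(";") if g]
                raws.append(row)

    records, dropped_year = [], 0
    for raw in raws:
        rec = _record_from_mapping(raw)
        if rec is None:
            dropped_year += 1
        else:
            records.append(rec)
    corpus = Corpus(records, provenance={"source": str(path)})
    corpus.add_filter_step("unparseable_year", dropped_year)
    if year_range is not None:
        lo, hi = year_range
        kept = [r for r in corpus.records if lo <= r.year <= hi]
        corpus.add_filter_step("year_out_of_range", len(corpus.records) - len(kept))
        corpus.records = kept
    return corpus


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus; ``read_corpus(write_corpus(c))`` is the identity on records."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in corpus.records:
                fh.write(json.dumps(
                    {"pub_id": r.pub_id, "year": r.year,
                     "affiliations": r.affiliations, "genes": r.genes},
                    ensure_ascii=False) + "\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pub_id", "year", "affiliations", "genes"])
            for r in corpus.records:
                w.writerow([r.pub_id, r.year, ";".join(r.affiliations), ";".join(r.genes)])
    else:
        raise ValueError(f"unsupported corpus format {format!r}")


def classify_genetics(record: PublicationRecord) -> bool:
    """A publication is genetics research iff its abstract mentions >=1 gene."""
    return len(record.gene_set) > 0


def gene_publication_counts(corpus: Corpus, by_year: bool = False,
                            unit: str = "publications") -> pd.Series:
    """Count publications (default) or raw mentions per gene.

    Returns a Series indexed by gene symbol, or by (gene, year) when
    ``by_year`` is true; the by-year table sums over years to the aggregate.
    """
    if len(corpus) == 0:
        raise CorpusError("gene_publication_counts requires a non-empty corpus")
    if unit not in ("publications", "mentions"):
        raise ValueError(f"unknown counting unit {unit!r}")
    counter: Counter = Counter()
    for r in corpus.records:
        symbols = r.gene_set if unit == "publications" else r.genes
        for g in symbols:
            counter[(g, r.year) if by_year else g] += 1
    if by_year:
        idx = pd.MultiIndex.from_tuples(sorted(counter), names=["gene", "year"])
        return pd.Series([counter[k] for k in idx], index=idx, name="count")
    keys = sorted(counter)
    return pd.Series([counter[k] for k in keys], index=pd.Index(keys, name="gene"),
                     name="count")


def first_mention(corpus: Corpus, gene: str) -> tuple[int, set[str]]:
    """Year of the earliest publication mentioning ``gene`` and the union of
    country sets of all its earliest-year publications."""
    hits = [r for r in corpus.records if gene in r.gene_set]
    if not hits:
        raise KeyError(f"gene {gene!r} not found in corpus")
    year = min(r.year for r in hits)
    countries: set[str] = set()
    for r in hits:
        if r.year == year and r.countries:
            countries |= r.countries
    return year, countries


def top_genes(counts: Mapping[str, int] | pd.Series, k: int) -> list[str]:
    """The ``k`` most frequent genes, ties broken lexicographically by symbol."""
    items = counts.items() if hasattr(counts, "items") else counts
    ranked = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds the number of genes ({len(ranked)})")
    if k < 0:
        raise ValueError("k must be nonnegative")
    return [g for g, _ in ranked[:k]]


def write_counts_tsv(counts: pd.Series, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", header=True)


def iter_gene_sets(records: Iterable[PublicationRecord]) -> Iterable[frozenset[str]]:
    for r in records:
        yield r.gene_set
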