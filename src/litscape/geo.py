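"""Affiliation-string geocoding by gazetteer text matching.

Resolving an author affiliation to a country uses no external geocoding
service: each affiliation string is split into ";"-separated subgroups, each
subgroup into comma tokens, and the *last* token — cleaned of whitespace,
trailing periods, digits/postal codes and e-mail fragments — is matched
against a gazetteer of country names, country aliases and US states (a bare
state such as "NY" resolves to "United States").  If the last token fails,
earlier tokens are tried right-to-left, so trailing e-mail addresses or
postal codes do not hide an otherwise well-formed ", City, Country" ending.
An affiliation like "John Hopkins University" carrying no place name yields
no match; a record whose affiliations all fail is marked unlocated (an empty
country set) and can be dropped with provenance accounting.

City extraction is supported for one focal country only, against the
gazetteer's city table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .corpus import Corpus

__all__ = ["Gazetteer", "load_gazetteer", "default_gazetteer",
           "extract_countries", "extract_cities", "annotate_corpus",
           "drop_unlocated"]

_EMAIL_RE = re.compile(r"\S*@\S*")
_DIGIT_RE = re.compile(r"\d+")
_PUNCT_RE = re.compile(r"[^\w\s'\-]", re.UNICODE)


def _norm(text: str) -> str:
    """Case- and punctuation-insensitive normal form used for lookups."""
    text = _EMAIL_RE.sub(" ", text)
    text = _DIGIT_RE.sub(" ", text)
    text = _PUNCT_RE.sub(" ", text)
    return " ".join(text.split()).casefold()


@dataclass
class Gazetteer:
    """Lookup tables for countries, aliases, US states and focal-country cities."""

    countries: set[str] = field(default_factory=set)
    aliases: dict[str, str] = field(default_factory=dict)       # alias -> canonical country
    us_states: dict[str, str] = field(default_factory=dict)     # state/abbrev -> "United States"
    cities: dict[str, str] = field(default_factory=dict)        # city/alias -> canonical city

    def __post_init__(self) -> None:
        for alias, target in self.aliases.items():
            if target not in self.countries:
                raise ValueError(f"alias {alias!r} targets unknown country {target!r}")
        self._country_index = {_norm(c): c for c in self.countries}
        self._country_index.update({_norm(a): t for a, t in self.aliases.items()})
        self._state_index = {_norm(s): t for s, t in self.us_states.items()}
        self._city_index = {_norm(c): t for c, t in self.cities.items()}

    def lookup_country(self, token: str) -> str | None:
        """Resolve one raw token to a canonical country name, or None."""
        key = _norm(token)
        if not key:
            return None
        return self._country_index.get(key) or self._state_index.get(key)

    def lookup_city(self, token: str) -> str | None:
        return self._city_index.get(_norm(token))


def load_gazetteer(path: str | Path) -> Gazetteer:
    """Load a gazetteer from a UTF-8 TSV with columns (name, type, canonical)."""
    gaz = Gazetteer()
    rows: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("name"):
            raise ValueError(f"{path}: expected header 'name\\ttype\\tcanonical'")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            rows.append(tuple(parts))
    for name, kind, canonical in rows:
        if kind == "country":
            gaz.countries.add(canonical)
        elif kind == "us_state":
            gaz.us_states[name] = canonical
        elif kind == "city":
            gaz.cities[name] = canonical
        elif kind != "alias":
            raise ValueError(f"unknown gazetteer entry type {kind!r}")
    for name, kind, canonical in rows:   # aliases after countries so targets exist
        if kind == "alias":
            gaz.aliases[name] = canonical
    gaz.__post_init__()
    return gaz


def default_gazetteer() -> Gazetteer:
    """The gazetteer shipped with the package (world countries, US states,
    Finnish cities)."""
    ref = resources.files("litscape").joinpath("data/gazetteer.tsv")
    with resources.as_file(ref) as path:
        return load_gazetteer(path)


def _subgroup_tokens(affiliation: str) -> list[list[str]]:
    return [[t for t in sub.split(",")] for sub in affiliation.split(";") if sub.strip()]


def extract_countries(affiliations: list[str], gazetteer: Gazetteer) -> set[str]:
    """Countries resolved from a list of raw affiliation strings.

    Returns the union over all strings; an empty set means no affiliation
    could be located ("NA" — a value, not an error).
    """
    found: set[str] = set()
    for aff in affiliations:
        for tokens in _subgroup_tokens(aff):
            for token in reversed(tokens):
                country = gazetteer.lookup_country(token)
                if country is not None:
                    found.add(country)
                    break
    return found


def extract_cities(affiliations: list[str], gazetteer: Gazetteer,
                   focal_country: str) -> set[str]:
    """Cities of ``focal_country`` mentioned in the affiliations whose
    country resolved to the focal country.  The empty set is allowed."""
    cities: set[str] = set()
    for aff in affiliations:
        for tokens in _subgroup_tokens(aff):
            resolved = None
            for token in reversed(tokens):
                resolved = gazetteer.lookup_country(token)
                if resolved is not None:
                    break
            if resolved != focal_country:
                continue
            for token in tokens:
                city = gazetteer.lookup_city(token)
                if city is not None:
                    cities.add(city)
    return cities


def annotate_corpus(corpus: Corpus, gazetteer: Gazetteer,
                    focal_country: str | None = None) -> Corpus:
    """Fill ``countries`` (and, for the focal country, ``cities``) in place."""
    for r in corpus.records:
        r.countries = extract_countries(r.affiliations, gazetteer)
        if focal_country is not None and focal_country in r.countries:
            r.cities = extract_cities(r.affiliations, gazetteer, focal_country)
        elif focal_country is not None:
            r.cities = set()
    return corpus


def drop_unlocated(corpus: Corpus) -> Corpus:
    """Remove records whose extraction yielded no country; count in provenance."""
    for r in corpus.records:
        if r.countries is None:
            raise ValueError("drop_unlocated requires extract_countries to have run "
                             f"(record {r.pub_id!r} has no extraction result)")
    kept = [r for r in corpus.records if r.countries]
    out = Corpus(kept, provenance=dict(corpus.provenance))
    out.provenance["filters"] = list(corpus.provenance.get("filters", []))
    out.add_filter_step("unlocated_affiliation", len(corpus.records) - len(kept))
    return out
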