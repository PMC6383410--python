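"""Country/city collaboration matrices, Others grouping and chord export."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from litscape.collab import (CooccurrenceMatrix, chord_export, city_matrix,
                             country_matrix, group_others, partner_counts,
                             publication_totals, self_collaboration_pct)
from litscape.geo import annotate_corpus, default_gazetteer
from litscape.synthetic import SyntheticSpec, generate

from conftest import make_corpus, make_record


def brute_force_pairs(entity_sets):
    """Independent pair enumeration: off-diagonal counts and singleton diag."""
    labels = sorted(set().union(*entity_sets)) if entity_sets else []
    pairs = {}
    diag = dict.fromkeys(labels, 0)
    for s in entity_sets:
        if len(s) == 1:
            diag[next(iter(s))] += 1
        for a, b in combinations(sorted(s), 2):
            pairs[(a, b)] = pairs.get((a, b), 0) + 1
    return labels, pairs, diag


@pytest.fixture(scope="module")
def located_corpus():
    spec = SyntheticSpec(n_pubs=50, p_international=0.4, seed=13)
    corpus, _ = generate(spec)
    return annotate_corpus(corpus, default_gazetteer(), focal_country="Finland")


class TestCountryMatrix:
    def test_single_country_paper_hits_diagonal(self):
        corpus = make_corpus([make_record("P1", countries={"Finland"})])
        m = country_matrix(corpus)
        assert m["Finland", "Finland"] == 1

    def test_pure_pair_paper_off_diagonal_only(self):
        corpus = make_corpus([make_record("P1", countries={"Finland", "United States"})])
        m = country_matrix(corpus)
        assert m["Finland", "United States"] == 1
        assert m["Finland", "Finland"] == 0 and m["United States", "United States"] == 0

    def test_matches_brute_force_enumeration(self, located_corpus):
        m = country_matrix(located_corpus)
        sets = [r.countries for r in located_corpus.records if r.countries]
        labels, pairs, diag = brute_force_pairs(sets)
        assert m.labels == labels
        for a, b in combinations(labels, 2):
            assert m[a, b] == pairs.get((a, b), 0)
        for a in labels:
            assert m[a, a] == diag[a]

    def test_symmetric_nonnegative_integer_invariants(self, located_corpus):
        m = country_matrix(located_corpus)
        assert np.array_equal(m.counts, m.counts.T)
        assert (m.counts >= 0).all()
        assert np.issubdtype(m.counts.dtype, np.integer)


class TestGroupOthers:
    FIXTURE = CooccurrenceMatrix(
        ["A", "B", "C", "D"],
        np.array([[5, 2, 1, 0],
                  [2, 7, 0, 1],
                  [1, 0, 2, 3],
                  [0, 1, 3, 1]]))

    def test_all_above_threshold_unchanged(self):
        totals = pd.Series({"A": 10, "B": 12, "C": 11, "D": 15})
        assert group_others(self.FIXTURE, totals, min_pubs=10) is self.FIXTURE

    def test_vacuous_threshold_unchanged(self):
        totals = pd.Series({"A": 1, "B": 1, "C": 1, "D": 1})
        assert group_others(self.FIXTURE, totals, min_pubs=0) is self.FIXTURE

    def test_merged_cells_are_elementwise_sums(self):
        # C and D fall below threshold; hand enumeration of the merged cells:
        totals = pd.Series({"A": 10, "B": 12, "C": 3, "D": 4})
        g = group_others(self.FIXTURE, totals, min_pubs=10)
        assert g.labels == ["A", "B", "Others"]
        assert g["A", "Others"] == 1 + 0        # A-C + A-D
        assert g["B", "Others"] == 0 + 1        # B-C + B-D
        assert g["Others", "Others"] == 2 + 1 + 3 + 3   # C-C + D-D + C-D both cells

    def test_total_count_is_conserved(self):
        totals = pd.Series({"A": 10, "B": 2, "C": 3, "D": 4})
        g = group_others(self.FIXTURE, totals, min_pubs=10)
        assert g.counts.sum() == self.FIXTURE.counts.sum()
        assert np.array_equal(g.counts, g.counts.T)


class TestChordExport:
    def test_zero_matrix_gives_empty_table(self):
        m = CooccurrenceMatrix(["A", "B"], np.zeros((2, 2), dtype=int))
        assert len(chord_export(m, 2)) == 0

    def test_two_entities_one_row(self):
        m = CooccurrenceMatrix(["A", "B"], np.array([[0, 5], [5, 0]]))
        table = chord_export(m, 2)
        assert table.values.tolist() == [["A", "B", 5]]

    def test_top_k_matches_filter_and_sort_oracle(self, located_corpus):
        m = country_matrix(located_corpus)
        totals = publication_totals(located_corpus, "country")
        table = chord_export(m, 3, totals=totals)
        top3 = set(sorted(m.labels, key=lambda c: (-totals.get(c, 0), c))[:3])
        expected = {(a, b): m[a, b] for a, b in combinations(sorted(top3), 2)
                    if m[a, b] > 0}
        got = {(r.source, r.target): r.value for r in table.itertuples()}
        assert got == expected
        assert len(table) <= 3 * 2 // 2

    def test_k_exceeding_labels_raises(self):
        m = CooccurrenceMatrix(["A"], np.zeros((1, 1), dtype=int))
        with pytest.raises(ValueError):
            chord_export(m, 2)


class TestSelfCollaborationPct:
    def test_worked_example_general_research(self):
        # 736 publications with the country, 343 of them country-only -> 46.6%
        recs = [make_record(f"S{i}", countries={"Finland"}) for i in range(343)]
        recs += [make_record(f"I{i}", countries={"Finland", "United States"})
                 for i in range(736 - 343)]
        pct = self_collaboration_pct(make_corpus(recs), "Finland")
        assert round(pct, 1) == 46.6

    def test_worked_example_genetics_research(self):
        recs = [make_record(f"S{i}", countries={"Finland"}) for i in range(402)]
        recs += [make_record(f"I{i}", countries={"Finland", "Sweden"})
                 for i in range(530 - 402)]
        pct = self_collaboration_pct(make_corpus(recs), "Finland")
        assert round(pct, 2) == 75.85

    def test_all_single_country_is_100(self):
        recs = [make_record(f"P{i}", countries={"Japan"}) for i in range(5)]
        assert self_collaboration_pct(make_corpus(recs), "Japan") == 100.0

    def test_absent_country_raises(self):
        corpus = make_corpus([make_record("P1", countries={"Japan"})])
        with pytest.raises(KeyError):
            self_collaboration_pct(corpus, "Finland")

    def test_bounds(self, located_corpus):
        for country in publication_totals(located_corpus, "country").index:
            assert 0.0 <= self_collaboration_pct(located_corpus, country) <= 100.0


class TestCityMatrix:
    def test_three_city_paper_increments_each_pair_once(self):
        corpus = make_corpus([make_record(
            "P1", countries={"Finland"}, cities={"Helsinki", "Tampere", "Oulu"})])
        m = city_matrix(corpus, "Finland")
        for a, b in [("Helsinki", "Tampere"), ("Helsinki", "Oulu"), ("Tampere", "Oulu")]:
            assert m[a, b] == 1
        assert all(m[c, c] == 0 for c in m.labels)

    def test_single_city_multiple_institutions_is_self_collaboration(self):
        corpus = make_corpus([make_record(
            "P1", countries={"Finland"}, cities={"Helsinki"})])
        m = city_matrix(corpus, "Finland")
        assert m["Helsinki", "Helsinki"] == 1

    def test_matches_brute_force_enumeration(self, located_corpus):
        m = city_matrix(located_corpus, "Finland")
        sets = [r.cities for r in located_corpus.records
                if r.countries and "Finland" in r.countries and r.cities]
        labels, pairs, diag = brute_force_pairs(sets)
        assert m.labels == labels
        for a, b in combinations(labels, 2):
            assert m[a, b] == pairs.get((a, b), 0)
        for a in labels:
            assert m[a, a] == diag[a]


def test_partner_counts_each_partner_once_per_publication():
    recs = [make_record("P1", countries={"Finland", "Sweden", "Norway"}),
            make_record("P2", countries={"Finland", "Sweden"}),
            make_record("P3", countries={"Finland"})]
    counts = partner_counts(make_corpus(recs), "Finland")
    assert counts.to_dict() == {"Sweden": 2, "Norway": 1}
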