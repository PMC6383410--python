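"""Exact enrichment test: contingency construction and hypergeometric tail."""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import hypergeom

from litscape.enrichment import (ContingencyTable, assign_attributes,
                                 build_contingency, exact_pvalue, log_pmf,
                                 results_to_frame, sweep)


def enumeration_pvalue(n, n_plus1, n_1plus, x, include_observed=False):
    """Brute-force oracle: enumerate all n_1plus-subsets of n genes, of which
    n_plus1 are city genes, and count subsets whose city overlap exceeds x."""
    city = set(range(n_plus1))
    total = hits = 0
    for subset in combinations(range(n), n_1plus):
        total += 1
        overlap = len(city.intersection(subset))
        if overlap > x or (include_observed and overlap == x):
            hits += 1
    return hits / total


def table_from_margins(n, n_plus1, n_1plus, x):
    return ContingencyTable(x=x, n12=n_1plus - x, n21=n_plus1 - x,
                            n22=n - n_plus1 - n_1plus + x)


class TestContingencyTable:
    def test_margin_identities(self):
        t = ContingencyTable(x=3, n12=4, n21=2, n22=5)
        t.check_margins()
        assert (t.n_plus1, t.n_plus2, t.n_1plus, t.n_2plus, t.n) == (5, 9, 7, 7, 14)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(x=-1, n12=0, n21=0, n22=0)


class TestAssignAttributes:
    def test_count_equal_to_gamma_is_not_highly_studied(self):
        labels = assign_attributes({"A": 5, "B": 6}, {"A"}, gamma=5)
        assert labels.loc["A", "hs"] == False  # noqa: E712 — strict boundary
        assert labels.loc["B", "hs"] == True   # noqa: E712

    def test_gamma_zero_any_count_is_highly_studied(self):
        labels = assign_attributes({"A": 1}, set(), gamma=0)
        assert labels.loc["A", "hs"] == True   # noqa: E712

    def test_gamma_at_max_count_selects_nothing(self):
        counts = {"A": 5, "B": 9}
        labels = assign_attributes(counts, {"A"}, gamma=max(counts.values()))
        assert not labels["hs"].any()

    def test_city_gene_missing_worldwide_is_an_error(self):
        with pytest.raises(ValueError, match="GHOST"):
            assign_attributes({"A": 1}, {"GHOST"}, gamma=0)


class TestBuildContingency:
    def test_empty_gene_list_gives_zero_table(self):
        labels = assign_attributes({}, set(), gamma=0)
        t = build_contingency(labels)
        assert (t.x, t.n12, t.n21, t.n22) == (0, 0, 0, 0)

    def test_hand_counted_four_gene_fixture(self):
        counts = {"A": 10, "B": 10, "C": 1, "D": 1}
        labels = assign_attributes(counts, {"A", "C"}, gamma=5)
        t = build_contingency(labels)
        assert (t.x, t.n12, t.n21, t.n22) == (1, 1, 1, 1)

    def test_row_order_invariance(self):
        counts = {"A": 10, "B": 2, "C": 7}
        labels = assign_attributes(counts, {"B", "C"}, gamma=5)
        permuted = labels.sample(frac=1, random_state=1)
        assert build_contingency(labels) == build_contingency(permuted)


class TestExactPvalue:
    def test_maximal_overlap_gives_zero(self):
        # x = min(n1+, n+1) with nondegenerate margins: empty summation range
        t = table_from_margins(n=10, n_plus1=4, n_1plus=6, x=4)
        assert exact_pvalue(t) == 0.0

    def test_single_term_tail_worked_example(self):
        # n=10, n+1=5, n1+=4, x=3: tail = P(4) = C(5,4)C(5,0)/C(10,4) = 5/210
        t = table_from_margins(10, 5, 4, 3)
        assert exact_pvalue(t) == pytest.approx(5 / 210, abs=1e-12)
        assert enumeration_pvalue(10, 5, 4, 3) == pytest.approx(5 / 210, abs=1e-12)

    def test_two_term_tail_worked_example(self):
        # n=6, n+1=3, n1+=3, x=1: P(2)+P(3) = (9+1)/20 = 0.5
        t = table_from_margins(6, 3, 3, 1)
        assert exact_pvalue(t) == pytest.approx(0.5, abs=1e-12)
        assert enumeration_pvalue(6, 3, 3, 1) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_margins_return_one(self):
        assert exact_pvalue(ContingencyTable(0, 0, 3, 7)) == 1.0     # no HS-yes gene
        assert exact_pvalue(ContingencyTable(3, 7, 0, 0)) == 1.0     # all HS-yes
        assert exact_pvalue(ContingencyTable(0, 5, 0, 5)) == 1.0     # empty city

    def test_agrees_with_enumeration_oracle_small_margins(self):
        for n in range(2, 9):
            for n_plus1 in range(1, n):
                for n_1plus in range(1, n):
                    for x in range(max(0, n_plus1 + n_1plus - n),
                                   min(n_plus1, n_1plus) + 1):
                        t = table_from_margins(n, n_plus1, n_1plus, x)
                        expected = enumeration_pvalue(n, n_plus1, n_1plus, x)
                        assert exact_pvalue(t) == pytest.approx(expected, abs=1e-12)

    def test_include_observed_matches_conventional_tail(self):
        t = table_from_margins(10, 5, 4, 3)
        conventional = hypergeom.sf(t.x - 1, t.n, t.n_plus1, t.n_1plus)
        assert exact_pvalue(t, include_observed=True) == \
               pytest.approx(conventional, abs=1e-12)

    def test_agrees_with_scipy_survival_function(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(4, 400))
            n_plus1 = int(rng.integers(1, n))
            n_1plus = int(rng.integers(1, n))
            lo, hi = max(0, n_plus1 + n_1plus - n), min(n_plus1, n_1plus)
            x = int(rng.integers(lo, hi + 1))
            t = table_from_margins(n, n_plus1, n_1plus, x)
            assert exact_pvalue(t) == pytest.approx(
                hypergeom.sf(x, n, n_plus1, n_1plus), abs=1e-10)

    def test_pmf_sums_to_one_over_full_support(self):
        for n, n_plus1, n_1plus in [(10, 5, 4), (12, 3, 9), (50, 20, 30), (7, 6, 1)]:
            t = table_from_margins(n, n_plus1, n_1plus,
                                   max(0, n_plus1 + n_1plus - n))
            total = sum(np.exp(log_pmf(k, t))
                        for k in range(min(n_plus1, n_1plus) + 1))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_non_increasing_in_x_for_fixed_margins(self):
        n, n_plus1, n_1plus = 30, 12, 10
        ps = [exact_pvalue(table_from_margins(n, n_plus1, n_1plus, x))
              for x in range(min(n_plus1, n_1plus) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_large_margins_are_finite_and_in_range(self):
        # magnitudes comparable to a 7,519-gene worldwide list
        t = table_from_margins(7519, 900, 1200, 400)
        p = exact_pvalue(t)
        assert 0.0 <= p <= 1.0 and np.isfinite(p)


class TestSweep:
    COUNTS = {"A": 100, "B": 50, "C": 20, "D": 5, "E": 2, "F": 1}

    def test_single_gamma_uses_unadjusted_alpha(self):
        results = sweep(self.COUNTS, {"A", "B"}, gammas=[10], alpha=0.05)
        assert len(results) == 1
        assert results[0].significant == (results[0].p_value < 0.05)

    def test_extreme_gammas_give_p_one(self):
        results = sweep(self.COUNTS, {"A", "B"}, gammas=[0, 100])
        by_gamma = {r.gamma: r.p_value for r in results}
        assert by_gamma[100] == 1.0      # no gene selected as highly studied
        assert by_gamma[0] == 1.0        # every gene selected (all counts > 0)

    def test_empty_gamma_list_rejected(self):
        with pytest.raises(ValueError):
            sweep(self.COUNTS, set(), gammas=[])

    def test_results_frame_schema(self):
        frame = results_to_frame(sweep(self.COUNTS, {"A"}, gammas=[10, 30]))
        assert list(frame.columns) == ["gamma", "x", "n12", "n21", "n22",
                                       "p_value", "significant"]
        assert len(frame) == 2
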