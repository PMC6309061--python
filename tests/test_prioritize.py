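"""Hypergeometric tail scoring and disease ranking."""

import datetime as dt
import math
import random
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from helpers import tail_by_enumeration
from meshrank.linktable import build_link_table
from meshrank.medline import PublicationRecord
from meshrank.prioritize import (
    ContingencyError,
    QueryContingency,
    hypergeom_tail,
    log_hypergeom_tail,
    prioritize,
    score_disease,
)
from meshrank.vocabulary import MeshDescriptor

LN10 = math.log(10)


class TestTailProbability:
    @pytest.mark.parametrize(
        "m, n, j, k, expected",
        [
            (10, 4, 5, 3, Fraction(55, 210)),
            (5, 2, 2, 2, Fraction(1, 10)),
            (6, 6, 4, 4, Fraction(1)),
            (8, 3, 5, 0, Fraction(1)),
        ],
    )
    def test_matches_enumeration_oracle_examples(self, m, n, j, k, expected):
        assert tail_by_enumeration(m, n, j, k) == expected  # freeze the oracle
        assert hypergeom_tail(QueryContingency(m, n, j, k)) == pytest.approx(
            float(expected), rel=1e-12
        )

    @pytest.mark.parametrize(
        "m, n, j, k",
        [(500, 60, 120, 25), (1000, 10, 400, 9), (10_000, 200, 30, 5)],
    )
    def test_agrees_with_scipy_survival_function(self, m, n, j, k):
        ours = log_hypergeom_tail(m, n, j, k)
        theirs = hypergeom.logsf(k - 1, m, j, n)
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_below_support_floor_tail_is_one(self):
        # n + j − m = 4 forces at least 4 marked draws; k=2 still means ≥2.
        assert hypergeom_tail(QueryContingency(m=10, n=7, j=7, k=2)) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "m, n, j, k, message",
        [
            (10, 11, 5, 3, "n ≤ m"),
            (10, 4, 11, 3, "j ≤ m"),
            (10, 4, 5, 5, "min"),
            (10, 4, 5, -1, "min"),
        ],
    )
    def test_invariant_violations_name_the_inequality(self, m, n, j, k, message):
        with pytest.raises(ContingencyError, match=message):
            QueryContingency(m, n, j, k)


class TestScore:
    def test_worked_examples(self):
        assert score_disease(QueryContingency(10, 4, 5, 3)) == pytest.approx(
            -math.log10(55 / 210), rel=1e-12
        )
        assert score_disease(QueryContingency(5, 2, 2, 2)) == pytest.approx(1.0, rel=1e-12)
        assert score_disease(QueryContingency(10, 4, 5, 0)) == 0.0

    def test_extreme_contingency_is_finite_and_order_stable(self):
        forward = score_disease(QueryContingency(10**7, 10**3, 10**5, 800))
        reverse = score_disease(QueryContingency(10**7, 10**3, 10**5, 800), order="reverse")
        assert math.isfinite(forward) and forward > 0
        assert forward == pytest.approx(reverse, rel=1e-6)

    def test_score_far_beyond_float_underflow(self):
        # f ≈ 10^−1800 territory: linear-space tail underflows to 0.0
        # while the log-space score stays finite and large.
        c = QueryContingency(13_000_000, 2000, 5000, 900)
        assert hypergeom_tail(c) == 0.0
        assert 1000 < score_disease(c) < 5000

    @given(
        st.integers(min_value=2, max_value=40).flatmap(
            lambda m: st.tuples(
                st.just(m),
                st.integers(min_value=1, max_value=m),
                st.integers(min_value=1, max_value=m),
            )
        ),
        st.data(),
    )
    def test_monotone_in_k_and_j(self, mnj, data):
        m, n, j = mnj
        k = data.draw(st.integers(min_value=0, max_value=min(n, j)))
        score = score_disease(QueryContingency(m, n, j, k))
        if k < min(n, j):
            assert score_disease(QueryContingency(m, n, j, k + 1)) >= score - 1e-12
        if j < m and k <= min(n, j + 1):
            assert score_disease(QueryContingency(m, n, j + 1, k)) <= score + 1e-12


def _table(pub_diseases: dict[int, tuple[str, ...]], year=2000):
    """Build a table whose pmid→disease sets are given directly."""
    names = sorted({d for ds in pub_diseases.values() for d in ds})
    vocab = [
        MeshDescriptor(nm, f"D{i:06d}", (f"C{(i % 26) + 1:02d}.{i}",))
        for i, nm in enumerate(names)
    ]
    records = [
        PublicationRecord(pmid=p, date=dt.date(year, 1, 1) + dt.timedelta(days=p), mesh_headings=ds)
        for p, ds in pub_diseases.items()
    ]
    return build_link_table(records, vocab)


class TestPrioritize:
    def test_toy_example_scores_and_order(self):
        table = _table({1: ("D_A",), 2: ("D_A",), 3: ("D_A", "D_B"), 4: ("D_B",)})
        scores = prioritize(table, [1, 2, 3])
        assert [s.disease for s in scores] == ["D_A", "D_B"]
        a, b = scores
        assert a.score == pytest.approx(-math.log10(1 / 4), rel=1e-12)
        assert (a.contingency.k, a.contingency.j) == (3, 3)
        assert b.score == 0.0
        assert (b.contingency.k, b.contingency.j) == (1, 2)
        assert [s.rank for s in scores] == [1, 2]

    def test_symmetric_tie_broken_by_name_ascending(self):
        table = _table({1: ("D_B",), 2: ("D_A",), 3: ("D_A", "D_B")})
        scores = prioritize(table, [1, 2, 3])
        assert [s.score for s in scores] == pytest.approx(
            [scores[0].score] * 2
        )
        assert [s.disease for s in scores] == ["D_A", "D_B"]

    def test_tie_on_score_broken_by_j_descending(self):
        # Querying the whole table forces f = 1 (score 0) for both
        # diseases; D_rare has the smaller j.
        table = _table(
            {1: ("D_common", "D_rare"), 2: ("D_common", "D_rare"), 3: ("D_common",)}
        )
        scores = prioritize(table, [1, 2, 3])
        assert [s.disease for s in scores] == ["D_common", "D_rare"]

    def test_disjoint_query_returns_empty_list(self):
        table = _table({1: ("D_A",)})
        assert prioritize(table, [99, 100]) == []

    def test_query_pmid_order_is_irrelevant(self):
        table = _table({p: ("D_A",) if p % 2 else ("D_B", "D_A") for p in range(1, 12)})
        query = list(range(1, 9))
        baseline = prioritize(table, query)
        for seed in range(3):
            shuffled = query[:]
            random.Random(seed).shuffle(shuffled)
            assert prioritize(table, shuffled) == baseline

    def test_every_disease_has_k_at_least_one_and_k_sum_identity(self):
        table = _table({1: ("D_A", "D_B"), 2: ("D_B",), 3: ("D_C",), 4: ("D_A",)})
        query = [1, 2, 4, 77]
        scores = prioritize(table, query)
        assert all(s.contingency.k >= 1 for s in scores)
        expected = sum(
            len(table.publications[p][1]) for p in query if p in table.publications
        )
        assert sum(s.contingency.k for s in scores) == expected

    def test_supporting_pmids_most_recent_first(self):
        table = _table({1: ("D_A",), 5: ("D_A",), 3: ("D_A",)})
        (top,) = prioritize(table, [1, 3, 5])
        assert top.supporting_pmids == (5, 3, 1)
        assert len(top.supporting_pmids) == top.contingency.k
        (oldest,) = prioritize(table, [1, 3, 5], newest_first=False)
        assert oldest.supporting_pmids == (1, 3, 5)

    def test_max_diseases_truncates_after_ranking(self):
        table = _table({1: ("D_A", "D_B", "D_C"), 2: ("D_A",)})
        scores = prioritize(table, [1, 2], max_diseases=2)
        assert len(scores) == 2
        assert [s.rank for s in scores] == [1, 2]

    def test_empty_table_rejected(self, toy_vocabulary):
        table = build_link_table([], toy_vocabulary)
        with pytest.raises(ValueError):
            prioritize(table, [1])
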