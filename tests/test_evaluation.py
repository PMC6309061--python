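"""Gold-standard construction and ranked-retrieval metrics."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from meshrank.evaluation import (
    CuratedAssociation,
    GoldStandard,
    average_precision,
    build_gold_standard,
    gold_rank_counts,
    map_score,
    pr_curve,
    precision_at_k,
    precision_recall_f,
    rank_of_gold,
    read_associations_tsv,
    therapeutic_gold_standard,
    write_associations_tsv,
)


def assoc(term, disease, source, count=3, evidence=""):
    return CuratedAssociation(term, disease, source, count, evidence)


class TestGoldStandardCriteria:
    def test_union_vs_intersection_toy(self):
        assocs = [assoc("g", "D1", "GAD"), assoc("g", "D2", "CTD_curated", 5)]
        assert build_gold_standard(assocs, 1).relevant == {"g": {"D1", "D2"}}
        # empty intersection → term dropped entirely
        assert build_gold_standard(assocs, 3).relevant == {}

    def test_single_publication_pair_in_c3_but_not_c4(self):
        assocs = [assoc("g", "D1", "GAD", count=1), assoc("g", "D1", "CTD_curated", count=7)]
        assert build_gold_standard(assocs, 3).relevant == {"g": {"D1"}}
        assert build_gold_standard(assocs, 4).relevant == {}

    def test_criterion_2_requires_support_in_each_source_it_appears_in(self):
        assocs = [
            assoc("g", "D1", "GAD", count=4),  # one source only, well supported
            assoc("g", "D2", "GAD", count=1),  # one source only, weak
            assoc("g", "D3", "GAD", count=2),
            assoc("g", "D3", "CTD_curated", count=1),  # weak in the other source
        ]
        assert build_gold_standard(assocs, 2).relevant == {"g": {"D1"}}

    def test_empty_associations_give_empty_gold(self):
        assert build_gold_standard([], 1).relevant == {}

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError, match="criterion"):
            build_gold_standard([], 5)

    def test_criteria_nest_on_a_noisy_table(self):
        import numpy as np

        rng = np.random.default_rng(17)
        assocs = []
        for t in range(12):
            for d in range(6):
                for source in ("GAD", "CTD_curated"):
                    if rng.random() < 0.7:
                        assocs.append(
                            assoc(f"t{t}", f"D{d}", source, count=int(rng.integers(1, 6)))
                        )
        gold = {c: build_gold_standard(assocs, c) for c in (1, 2, 3, 4)}
        terms = set(gold[1].relevant)
        for term in terms:
            c1 = gold[1].relevant.get(term, set())
            assert gold[4].relevant.get(term, set()) <= gold[3].relevant.get(term, set()) <= c1
            assert gold[2].relevant.get(term, set()) <= c1


class TestTherapeuticGold:
    def test_keeps_only_therapeutic_ctd_rows(self):
        assocs = [
            assoc("drugx", "D1", "CTD_curated", evidence="therapeutic"),
            assoc("drugx", "D2", "CTD_curated", evidence="marker/mechanism"),
            assoc("drugx", "D3", "GAD", evidence="therapeutic"),
        ]
        assert therapeutic_gold_standard(assocs).relevant == {"drugx": {"D1"}}

    def test_no_therapeutic_rows_gives_empty_gold(self):
        assert therapeutic_gold_standard([assoc("d", "D", "CTD_curated")]).relevant == {}

    def test_evidence_match_is_case_sensitive(self):
        assocs = [assoc("d", "D1", "CTD_curated", evidence="Therapeutic")]
        assert therapeutic_gold_standard(assocs).relevant == {}


class TestSetMetrics:
    def test_hand_example_two_thirds(self):
        m = precision_recall_f(["A", "B", "C"], {"B", "C", "D"})
        assert (m.precision, m.recall) == (pytest.approx(2 / 3), pytest.approx(2 / 3))
        assert m.f_measure == pytest.approx(2 / 3)

    def test_identity_and_disjoint(self):
        perfect = precision_recall_f(["A", "B"], {"A", "B"})
        assert (perfect.precision, perfect.recall, perfect.f_measure) == (1, 1, 1)
        zero = precision_recall_f(["A"], {"B"})
        assert (zero.precision, zero.recall, zero.f_measure) == (0, 0, 0)

    def test_empty_retrieved_convention(self):
        m = precision_recall_f([], {"A"})
        assert (m.precision, m.recall, m.f_measure) == (0.0, 0.0, 0.0)

    @given(
        retrieved=st.lists(st.sampled_from("ABCDEFGH"), unique=True, min_size=1),
        relevant=st.sets(st.sampled_from("ABCDEFGH"), min_size=1),
    )
    def test_f_is_the_harmonic_mean(self, retrieved, relevant):
        m = precision_recall_f(retrieved, relevant)
        if m.precision > 0 and m.recall > 0:
            assert 1 / m.f_measure == pytest.approx(
                (1 / m.precision + 1 / m.recall) / 2
            )


class TestAveragePrecision:
    def test_hand_example_five_sixths(self):
        assert average_precision(["D1", "x", "D2", "y"], {"D1", "D2"}) == pytest.approx(5 / 6)

    def test_single_relevant_at_rank_one(self):
        assert average_precision(["D1", "x"], {"D1"}) == 1.0

    def test_unretrieved_relevant_contributes_zero(self):
        assert average_precision(["D1"], {"D1", "D2"}) == pytest.approx(0.5)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            average_precision(["D1", "D1"], {"D1"})

    @given(
        ranked=st.lists(st.sampled_from("ABCDEFGHIJ"), unique=True, min_size=1),
        relevant=st.sets(st.sampled_from("ABCDE"), min_size=1),
    )
    def test_bounded_and_one_iff_top_ranks_filled(self, ranked, relevant):
        ap = average_precision(ranked, relevant)
        assert 0 <= ap <= 1
        retrieved_relevant = set(ranked) & relevant
        tops_filled = (
            retrieved_relevant == relevant
            and set(ranked[: len(relevant)]) == relevant
        )
        assert (ap == 1.0) == tops_filled

    def test_invariant_to_order_of_trailing_irrelevant_items(self):
        ranked = ["x", "D1", "y", "z", "w"]
        swapped = ["x", "D1", "w", "z", "y"]
        relevant = {"D1"}
        assert average_precision(ranked, relevant) == average_precision(swapped, relevant)


class TestMapAndPrecisionAtK:
    def test_map_examples(self):
        assert map_score([1.0, 0.5]) == 0.75
        assert map_score([0, 0, 0]) == 0
        assert map_score([0.77] * 100) == pytest.approx(0.77)
        with pytest.raises(ValueError):
            map_score([])

    def test_precision_at_k_examples(self):
        ranked = [f"D{i}" for i in range(10)]
        relevant = {f"D{i}" for i in range(5)}
        assert precision_at_k(ranked, relevant, 10) == 0.5
        assert precision_at_k(ranked, relevant, 1) == 1.0

    def test_short_list_keeps_fixed_denominator(self):
        assert precision_at_k(["D1", "x", "D2"], {"D1", "D2"}, 10) == pytest.approx(0.2)

    def test_p_at_list_length_equals_set_precision(self):
        ranked = ["A", "B", "C", "D"]
        relevant = {"B", "D", "E"}
        assert precision_at_k(ranked, relevant, len(ranked)) == pytest.approx(
            precision_recall_f(ranked, relevant).precision
        )


class TestCurvesAndRanks:
    def test_pr_curve_examples(self):
        assert pr_curve(["D1"], {"D1"}) == [(1.0, 1.0)]
        assert pr_curve(["x", "D1"], {"D1"}) == [(0.0, 0.0), (1.0, 0.5)]
        assert [p for _, p in pr_curve(["x", "y"], {"D1"})] == [0.0, 0.0]

    @given(
        ranked=st.lists(st.sampled_from("ABCDEFGHIJ"), unique=True, min_size=1),
        relevant=st.sets(st.sampled_from("ABCDE"), min_size=1),
    )
    def test_recall_is_non_decreasing_along_curve(self, ranked, relevant):
        recalls = [r for r, _ in pr_curve(ranked, relevant)]
        assert recalls == sorted(recalls)

    def test_rank_of_gold(self):
        assert rank_of_gold(["Dg", "x"], {"Dg"}) == 1
        assert rank_of_gold(["x", "y", "Dg"], {"Dg"}) == 3
        assert rank_of_gold(["x", "y"], {"Dg"}) is None

    def test_batch_rank_counts(self):
        gold = GoldStandard(relevant={"a": {"D1"}, "b": {"D2"}, "c": {"D3"}}, criterion="1")
        ranked = {"a": ["D1"], "b": ["x", "D2"], "c": ["x", "y", "z"]}
        assert gold_rank_counts(ranked, gold) == {1: 1, 2: 2, 5: 2}


class TestAssociationTsv:
    def test_round_trip(self, tmp_path):
        assocs = [
            assoc("g1", "D1", "GAD", 3, "curated"),
            assoc("g1", "D2", "CTD_curated", 1, "therapeutic"),
        ]
        path = tmp_path / "gold.tsv"
        write_associations_tsv(assocs, path)
        assert read_associations_tsv(path) == assocs

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("term\tdisease\ng\tD1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_associations_tsv(path)
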