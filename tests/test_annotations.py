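"""Hypergeometric enrichment, feature selection, PPI conversion."""

import itertools
import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lysvote import (
    AnnotationTable,
    FeatureSpace,
    build_feature_space,
    enrich_terms,
    hypergeometric_test,
    ppi_to_annotation,
    read_ppi_tsv,
    select_features,
)


def enumeration_tails(N: int, K: int, n: int, k: int) -> tuple[float, float]:
    """Independent oracle: walk every n-subset of an N-element universe whose
    first K elements carry the term, and count tail events directly."""
    total = over = under = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        carried = sum(1 for i in subset if i < K)
        if carried >= k:
            over += 1
        if carried <= k:
            under += 1
    return over / total, under / total


class TestHypergeometricTest:
    def test_fully_enriched_small_case(self):
        # all 4 sampled proteins annotated, 5 of 10 in background: 5/210
        p_over, _ = hypergeometric_test(k=4, n=4, K=5, N=10)
        assert p_over == pytest.approx(5 / 210, abs=1e-12)

    def test_saturated_background_gives_one(self):
        p_over, _ = hypergeometric_test(k=3, n=3, K=5, N=5)
        assert p_over == 1.0

    def test_depleted_case_mirrors_enriched(self):
        _, p_under = hypergeometric_test(k=0, n=4, K=5, N=10)
        assert p_under == pytest.approx(5 / 210, abs=1e-12)

    def test_matches_enumeration_on_a_grid(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(1, N + 1):
                    for k in range(min(n, K) + 1):
                        expect = enumeration_tails(N, K, n, k)
                        got = hypergeometric_test(k, n, K, N)
                        assert got[0] == pytest.approx(expect[0], abs=1e-12)
                        assert got[1] == pytest.approx(expect[1], abs=1e-12)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_tails_share_the_point_mass(self, data):
        N = data.draw(st.integers(1, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(n, K)))
        p_over, p_under = hypergeometric_test(k, n, K, N)
        assert 0.0 <= p_over <= 1.0 and 0.0 <= p_under <= 1.0
        assert p_over + p_under >= 1.0 - 1e-12

    def test_bounds_are_enforced(self):
        with pytest.raises(ValueError):
            hypergeometric_test(k=5, n=4, K=5, N=10)
        with pytest.raises(ValueError):
            hypergeometric_test(k=1, n=2, K=11, N=10)


def _table(mapping):
    return AnnotationTable("BP", {p: frozenset(t) for p, t in mapping.items()})


class TestEnrichTerms:
    def test_exclusive_term_has_closed_form_p(self):
        positives = {f"S{i}" for i in range(5)}
        background = positives | {f"B{i}" for i in range(95)}
        table = _table({p: {"t_only"} for p in positives})
        rec = enrich_terms(positives, background, table)
        row = rec[rec["term"] == "t_only"].iloc[0]
        assert row["direction"] == "over"
        assert row["p_raw"] == pytest.approx(1 / math.comb(100, 5), rel=1e-9)

    def test_universal_term_is_never_significant(self):
        positives = {"S1", "S2"}
        background = positives | {"B1", "B2", "B3"}
        table = _table({p: {"everywhere"} for p in background})
        rec = enrich_terms(positives, background, table)
        assert rec.iloc[0]["p_corrected"] == 1.0

    def test_bonferroni_multiplies_by_terms_tested_in_source(self):
        positives = {"S1", "S2", "S3"}
        background = positives | {f"B{i}" for i in range(27)}
        table = _table(
            {"S1": {"t1", "t2"}, "S2": {"t1"}, "S3": {"t1"}, "B0": {"t3"}}
        )
        rec = enrich_terms(positives, background, table)
        assert len(rec) == 3  # m = 3 terms tested
        for _, row in rec.iterrows():
            assert row["p_corrected"] == pytest.approx(
                min(1.0, row["p_raw"] * 3), rel=1e-12
            )

    def test_invariant_to_iteration_order(self):
        positives = {"S1", "S2"}
        background = positives | {"B1", "B2", "B3", "B4"}
        mapping = {"S1": {"a", "b"}, "S2": {"a"}, "B1": {"b"}, "B3": {"a"}}
        fwd = enrich_terms(positives, background, _table(mapping))
        rev = enrich_terms(
            positives, background, _table(dict(reversed(list(mapping.items()))))
        )
        pd.testing.assert_frame_equal(fwd, rev)

    def test_empty_positives_is_error(self):
        with pytest.raises(ValueError):
            enrich_terms(set(), {"B1"}, _table({}))

    def test_positives_must_be_inside_background(self):
        with pytest.raises(ValueError, match="not contained"):
            enrich_terms({"S1"}, {"B1"}, _table({}))


def _records(pairs):
    rows = [
        {"source": "BP", "term": t, "k": 1, "n": 2, "K": 2, "N": 10,
         "direction": "over", "p_raw": p, "p_corrected": p}
        for t, p in pairs
    ]
    return pd.DataFrame(rows)


class TestSelectFeatures:
    def test_threshold_is_strict(self):
        sel = select_features(_records([("t1", 0.003), ("t2", 0.012)]), alpha=1e-2)
        assert list(sel["term"]) == ["t1"]

    def test_nothing_significant_gives_empty_selection(self):
        sel = select_features(_records([("t1", 0.5)]), alpha=1e-2)
        assert sel.empty

    def test_cap_with_ties_prefers_lexicographic_terms(self):
        records = _records([(f"t{i:03d}", 1e-5) for i in range(150)])
        sel = select_features(records, alpha=1e-2, cap=100)
        assert len(sel) == 100
        assert list(sel["term"]) == sorted(f"t{i:03d}" for i in range(100))

    @given(st.lists(st.floats(0, 1), min_size=0, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_selection_respects_alpha_and_cap(self, ps):
        records = _records([(f"t{i}", p) for i, p in enumerate(ps)])
        sel = select_features(records, alpha=1e-2, cap=10)
        assert len(sel) <= 10
        if not sel.empty:
            assert (sel["p_corrected"] < 1e-2).all()


class TestPPI:
    def test_link_becomes_symmetric_terms(self):
        links = pd.DataFrame(
            [("P1", "P2", 900)], columns=["protein_a", "protein_b", "score"]
        )
        tab = ppi_to_annotation(links, min_score=400)
        assert tab.terms_of("P1") == {"P2"}
        assert tab.terms_of("P2") == {"P1"}

    def test_low_score_links_are_dropped(self):
        links = pd.DataFrame(
            [("P1", "P2", 150)], columns=["protein_a", "protein_b", "score"]
        )
        assert ppi_to_annotation(links, min_score=400).protein_to_terms == {}

    def test_reversed_duplicates_collapse(self):
        links = pd.DataFrame(
            [("P1", "P2", 900), ("P2", "P1", 900)],
            columns=["protein_a", "protein_b", "score"],
        )
        once = ppi_to_annotation(links.head(1))
        twice = ppi_to_annotation(links)
        assert once.protein_to_terms == twice.protein_to_terms

    def test_malformed_score_reports_line_number(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("protein_a\tprotein_b\tscore\nP1\tP2\t900\nP3\tP4\toops\n")
        with pytest.raises(ValueError, match="line 3"):
            read_ppi_tsv(path)


class TestFeatureSpace:
    def test_dimension_is_20L_plus_selected(self):
        fs = FeatureSpace(L=21, selected=[("BP", "t1"), ("PPI", "P5")])
        assert fs.dimension == 20 * 21 + 2

    def test_save_load_is_bit_exact(self, tmp_path):
        fs = FeatureSpace(L=15, selected=[("BP", "t1"), ("MF", "m x")])
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        fs.save(p1)
        reloaded = FeatureSpace.load(p1)
        assert reloaded == fs
        reloaded.save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FeatureSpace(L=21, selected=[("BP", "t1"), ("BP", "t1")])

    def test_build_orders_sources_canonically(self):
        sel = {
            "PPI": pd.DataFrame({"term": ["P9"]}),
            "BP": pd.DataFrame({"term": ["t1", "t2"]}),
        }
        fs = build_feature_space(21, sel)
        assert fs.selected == [("BP", "t1"), ("BP", "t2"), ("PPI", "P9")]
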