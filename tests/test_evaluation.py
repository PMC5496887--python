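"""Metrics, protein-level splitting, the harness, and proportion tests."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from lysvote import (
    EvalCounts,
    SiteSet,
    SiteWindow,
    compute_metrics,
    predict_and_summarize,
    proportion_enrichment_test,
    protein_level_split,
    run_harness,
)
from lysvote.evaluation import round_half_up


def direct_metrics(tp, tn, fp, fn):
    """Independent textbook-formula oracle for Sn/Sp/MCC."""
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    denom = math.sqrt((tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fn * fp) / denom
    return sn, sp, mcc


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(EvalCounts(TP=10, TN=10, FP=0, FN=0))
        assert (m.Sn, m.Sp, m.MCC) == (1.0, 1.0, 1.0)

    def test_worked_confusion_table(self):
        m = compute_metrics(EvalCounts(TP=71, TN=92, FP=8, FN=29))
        assert m.Sn == pytest.approx(0.71)
        assert m.Sp == pytest.approx(0.92)
        # numerator 71*92 - 29*8 = 6300; denominator sqrt(100*100*79*121)
        assert m.MCC == pytest.approx(6300 / math.sqrt(100 * 100 * 79 * 121))
        assert m.MCC == pytest.approx(0.6444, abs=1e-4)

    def test_zero_denominator_mcc_is_zero(self):
        m = compute_metrics(EvalCounts(TP=0, TN=10, FP=0, FN=10))
        assert m.MCC == 0.0

    def test_empty_margins_raise_naming_the_margin(self):
        with pytest.raises(ValueError, match="Sn undefined"):
            compute_metrics(EvalCounts(TP=0, TN=5, FP=5, FN=0))
        with pytest.raises(ValueError, match="Sp undefined"):
            compute_metrics(EvalCounts(TP=5, TN=0, FP=0, FN=5))

    def test_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            tp, tn, fp, fn = rng.integers(0, 200, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = compute_metrics(EvalCounts(int(tp), int(tn), int(fp), int(fn)))
            sn, sp, mcc = direct_metrics(tp, tn, fp, fn)
            assert m.Sn == pytest.approx(sn, abs=1e-12)
            assert m.Sp == pytest.approx(sp, abs=1e-12)
            assert m.MCC == pytest.approx(mcc, abs=1e-12)
            assert 0 <= m.Sn <= 1 and 0 <= m.Sp <= 1 and -1 <= m.MCC <= 1


def _sites(protein_sites):
    windows = []
    for pid, positions in protein_sites.items():
        for pos in positions:
            windows.append(SiteWindow(pid, pos, "A" * 10 + "K" + "A" * 10))
    return SiteSet(windows, 21)


class TestProteinLevelSplit:
    ten = _sites({f"P{i}": [20 + i, 40 + i] for i in range(10)})

    def test_ten_proteins_split_eight_two(self):
        train, test = protein_level_split(self.ten, fraction=0.8, seed=1)
        assert len(train.protein_ids()) == 8
        assert len(test.protein_ids()) == 2

    def test_same_seed_reproduces_the_split(self):
        a = protein_level_split(self.ten, seed=5)
        b = protein_level_split(self.ten, seed=5)
        assert [w.site for w in a[0]] == [w.site for w in b[0]]

    def test_no_protein_spans_both_folds(self):
        train, test = protein_level_split(self.ten, seed=2)
        assert train.protein_ids() & test.protein_ids() == set()
        assert len(train) + len(test) == len(self.ten)

    def test_fewer_than_two_proteins_is_error(self):
        with pytest.raises(ValueError, match="2 distinct"):
            protein_level_split(_sites({"P": [20, 40]}))

    def test_both_folds_always_nonempty(self):
        two = _sites({"A": [20], "B": [20]})
        train, test = protein_level_split(two, fraction=0.9, seed=0)
        assert len(train.protein_ids()) == 1
        assert len(test.protein_ids()) == 1


class TestProportionTest:
    def test_identical_proportions_clip_to_zero(self):
        stat, p = proportion_enrichment_test(10, 100, 10, 100)
        assert stat == 0.0
        assert p == 1.0

    def test_hand_evaluated_yates_table(self):
        # table (20, 10; 10, 20): chi2 = 60*(|400-100|-30)^2 / 30^4 = 5.4
        stat, p = proportion_enrichment_test(20, 30, 10, 30)
        assert stat == pytest.approx(5.4)
        assert p == pytest.approx(0.0201, abs=2e-4)

    def test_published_screen_counts_are_overwhelming(self):
        _, p = proportion_enrichment_test(5412, 17572, 3112, 19949)
        assert p < 2.2e-16

    def test_matches_scipy_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 500, size=4)
            stat, p = proportion_enrichment_test(int(a), int(a + b), int(c), int(c + d))
            ref = chi2_contingency([[a, b], [c, d]], correction=True)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError, match="margin"):
            proportion_enrichment_test(0, 10, 0, 10)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (100 * 5412 / 17572, 30.80),
            (100 * 3112 / 19949, 15.60),
            (0.125, 0.13),  # half rounds up, not to even
            (0.005, 0.01),
        ],
    )
    def test_half_up_two_decimals(self, x, expected):
        assert round_half_up(x, 2) == expected


class TestHarness:
    def test_single_repeat_has_no_standard_error(self, small_model):
        res = small_model.evaluate(R=1, seed=0)
        assert res.R == 1
        assert all(v is None for v in res.se().values())

    def test_standard_error_is_sd_over_sqrt_R(self, small_model):
        res = small_model.evaluate(R=4, seed=0)
        sd = res.repeats["MCC"].std(ddof=1)
        assert res.se()["MCC"] == pytest.approx(sd / 2)

    def test_config_echo_carries_reproducibility_fields(self, small_model):
        res = small_model.evaluate(R=1, seed=9)
        for key in ("L", "feature_groups", "K", "cutoff", "seed"):
            assert key in res.config

    def test_leaky_feature_selection_inflates_null_performance(self):
        """Selecting features on all positives (test fold included) scores
        better than the leakage-safe per-fold protocol on data with no real
        signal — the reason the harness re-selects inside each fold. Shown
        with functional features alone on a densely annotated null fixture,
        where chance enrichment has the most room to leak."""
        from dataclasses import replace

        from lysvote import SubstrateVotingModel, SynthConfig, generate_fixture

        cfg = replace(
            SynthConfig(seed=42), p_background_term=0.3, n_terms_per_source=60
        ).null()
        model = SubstrateVotingModel.from_fixture(
            generate_fixture(cfg), alpha=1.0, cap=25
        )
        groups = ("BP", "CC", "MF", "DOMAIN", "PPI")
        safe = model.evaluate(R=8, seed=4, feature_groups=groups)
        leaky = model.evaluate(R=8, seed=4, feature_groups=groups, leak_features=True)
        assert leaky.mean()["MCC"] > safe.mean()["MCC"] + 0.1


class TestPredictAndSummarize:
    def test_percent_formatting_and_counts(self, small_results, small_model):
        pos = small_model.positives.relabel("unlabeled")
        from lysvote.ensemble import sample_negatives

        bg = sample_negatives(small_model.background, 50, 7).relabel("unlabeled")
        summary = predict_and_summarize(
            small_results.ensemble, pos, small_model.tables, bg
        )
        frame = summary.frame
        assert list(frame["set"]) == ["candidate", "comparison"]
        for _, row in frame.iterrows():
            assert row["percent"] == round_half_up(
                100 * row["predicted"] / row["total"], 2
            )
        assert "prediction summary" in summary.text()

    def test_no_positive_calls_reports_test_error(self, small_results, small_model):
        from lysvote.ensemble import sample_negatives

        bg = sample_negatives(small_model.background, 30, 8).relabel("unlabeled")
        summary = predict_and_summarize(
            small_results.ensemble, bg, small_model.tables, bg,
            cutoff=small_results.ensemble.K + 1,
        )
        assert (summary.frame["predicted"] == 0).all()
        assert (summary.frame["percent"] == 0.0).all()
        assert summary.test_error is not None
        assert math.isnan(summary.chi2)
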