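"""Evaluation harness: presence, P/R/F1, calibration, ledger, paired tests."""

import math

import numpy as np
import pytest
from scipy import stats

from _oracles import ece_oracle
from notegate.corpus import Extraction, FeatureSpec, GateDecision, GoldAnnotation
from notegate.evaluation import (
    CalibrationBin,
    PresenceDecision,
    brier,
    confusion_counts,
    ece,
    error_ledger,
    mcnemar_p,
    paired_comparison,
    per_feature_error_rates,
    presence_binary_overlap,
    presence_semantic,
    prf,
    reliability_table,
    review_queue,
    round1,
)
from notegate.similarity import BagOfWordsEmbedder


def _gold(text, note="n1", fid="f1"):
    return GoldAnnotation(note, fid, (text,), (((0, len(text)),),))


def _ext(text, note="n1", fid="f1", gate=None, conf=None):
    return Extraction(note, fid, text, confidence=conf, gate=gate)


class TestPresenceBinaryOverlap:
    def test_exact_match_present(self):
        d = presence_binary_overlap(_ext("fever"), _gold("fever"))
        assert d.present_pred and d.present_gold

    def test_missing_extraction_is_false_negative(self):
        d = presence_binary_overlap(_ext(""), _gold("fever"))
        assert not d.present_pred and d.present_gold

    def test_word_order_irrelevant_above_half(self):
        d = presence_binary_overlap(_ext("breath shortness"), _gold("shortness of breath"))
        assert d.present_pred
        assert d.similarity == pytest.approx(2 / 3)

    def test_gate_rejected_prediction_not_counted(self):
        rej = GateDecision("rejected", "none")
        d = presence_binary_overlap(_ext("fever", gate=rej), _gold("fever"))
        assert not d.present_pred

    def test_prediction_without_gold_is_false_positive(self):
        d = presence_binary_overlap(_ext("fever"), GoldAnnotation("n1", "f1"))
        assert d.present_pred and not d.present_gold


class TestPresenceSemantic:
    feature = FeatureSpec("f1", "c1", "chest pain")
    embedder = BagOfWordsEmbedder()

    def test_identical_text_present_not_borderline(self):
        d = presence_semantic(_ext("chest pain"), self.feature, self.embedder, _gold("chest pain"))
        assert d.present_pred and d.similarity == pytest.approx(1.0) and not d.borderline

    def test_gate_rejection_takes_precedence(self):
        rej = GateDecision("rejected", "none")
        d = presence_semantic(_ext("chest pain", gate=rej), self.feature, self.embedder)
        assert not d.present_pred

    def test_borderline_window(self):
        d = presence_semantic(
            _ext("chest pain mild aching today"), self.feature, self.embedder
        )
        # cosine = 2 / (sqrt(5) * sqrt(2)) ~ 0.632 -> present and borderline
        assert d.present_pred
        assert d.similarity == pytest.approx(2 / math.sqrt(10))
        assert d.borderline


class TestPrf:
    def _decisions(self, tp, fp, fn, tn=0):
        out = []
        i = 0
        for _ in range(tp):
            out.append(PresenceDecision(f"n{i}", "f", True, True, "binary_overlap")); i += 1
        for _ in range(fp):
            out.append(PresenceDecision(f"n{i}", "f", True, False, "binary_overlap")); i += 1
        for _ in range(fn):
            out.append(PresenceDecision(f"n{i}", "f", False, True, "binary_overlap")); i += 1
        for _ in range(tn):
            out.append(PresenceDecision(f"n{i}", "f", False, False, "binary_overlap")); i += 1
        return out

    def test_direct_formula(self):
        p, r, f1 = prf(self._decisions(9, 1, 3))
        assert (p, r) == (0.9, 0.75)
        assert f1 == pytest.approx(2 * 0.9 * 0.75 / 1.65)

    def test_all_correct(self):
        assert prf(self._decisions(5, 0, 0)) == (1.0, 1.0, 1.0)

    def test_no_predictions_with_gold(self):
        assert prf(self._decisions(0, 0, 5)) == (0.0, 0.0, 0.0)

    def test_no_gold_no_predictions(self):
        assert prf(self._decisions(0, 0, 0, tn=4)) == (1.0, 1.0, 1.0)

    def test_mixed_modes_rejected(self):
        ds = self._decisions(1, 0, 0)
        ds.append(PresenceDecision("nx", "f", True, True, "semantic", 0.9))
        with pytest.raises(ValueError):
            prf(ds)

    def test_accounting_conservation(self):
        ds = self._decisions(7, 3, 2, 5)
        tp, fp, fn, tn = confusion_counts(ds)
        assert tp + fp == sum(d.present_pred for d in ds)
        assert tp + fn == sum(d.present_gold for d in ds)
        assert tp + fp + fn + tn == len(ds)


class TestCalibration:
    def test_matched_bins_zero_ece(self):
        c = [0.65, 0.75, 0.85, 0.95]
        assert ece(c, c) == pytest.approx(0.0)

    def test_single_bin_gap(self):
        assert ece([0.9, 0.92, 0.95], [0.6, 0.62, 0.65]) == pytest.approx(0.3)

    def test_weighted_two_bin_hand_computation(self):
        confs = [0.65, 0.66, 0.67, 0.95]
        scores = [0.6, 0.6, 0.6, 0.5]
        gap1 = abs(np.mean(confs[:3]) - 0.6)
        gap2 = abs(0.95 - 0.5)
        assert ece(confs, scores) == pytest.approx(0.75 * gap1 + 0.25 * gap2)

    def test_ece_agrees_with_bruteforce_binning(self):
        rng = np.random.default_rng(9)
        bins = [(0.0, 0.6), (0.6, 0.7), (0.7, 0.8), (0.8, 0.9), (0.9, 1.0)]
        for _ in range(50):
            n = int(rng.integers(1, 60))
            confs = rng.uniform(0, 1, n).tolist()
            scores = rng.uniform(0, 1, n).tolist()
            assert ece(confs, scores) == pytest.approx(
                ece_oracle(confs, scores, bins), abs=1e-12
            )

    def test_ece_bounded_by_max_bin_gap(self):
        rng = np.random.default_rng(2)
        confs = rng.uniform(0, 1, 100).tolist()
        scores = rng.uniform(0, 1, 100).tolist()
        table = reliability_table(confs, scores)
        assert ece(confs, scores) <= max(abs(b.gap) for b in table if b.count) + 1e-12

    def test_empty_input_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert ece([], []) == 0.0

    @pytest.mark.parametrize(
        "confs, scores, expected",
        [([0.8, 0.8], [0.8, 0.8], 0.0), ([1.0], [0.0], 1.0), ([0.8, 0.9], [0.6, 0.9], 0.02)],
    )
    def test_brier_examples(self, confs, scores, expected):
        assert brier(confs, scores) == pytest.approx(expected)

    def test_brier_order_invariant_and_bounded(self):
        rng = np.random.default_rng(1)
        c = rng.uniform(0, 1, 50)
        s = rng.uniform(0, 1, 50)
        perm = rng.permutation(50)
        assert brier(c.tolist(), s.tolist()) == pytest.approx(
            brier(c[perm].tolist(), s[perm].tolist())
        )
        assert 0.0 <= brier(c.tolist(), s.tolist()) <= 1.0

    def test_reliability_gap_to_optimum_micro_example(self):
        """An underperforming low bin: mean F1 0.692 sits 0.308 below optimum."""
        confs = [0.65, 0.65, 0.65]
        scores = [0.692, 0.692, 0.692]
        table = reliability_table(confs, scores)
        bin_ = next(b for b in table if b.lower == 0.6)
        assert bin_.gap_to_optimum == pytest.approx(0.692 - 1)

    def test_perfectly_calibrated_bin_zero_gap(self):
        table = reliability_table([0.75], [0.75])
        bin_ = next(b for b in table if b.count)
        assert bin_.gap == 0.0

    def test_bin_means_match_bruteforce(self):
        confs = [0.62, 0.68, 0.91, 0.97]
        scores = [0.5, 0.7, 0.9, 1.0]
        table = reliability_table(confs, scores)
        lo = next(b for b in table if b.lower == 0.6)
        hi = next(b for b in table if b.lower == 0.9)
        assert lo.count == 2 and lo.mean_confidence == pytest.approx(0.65)
        assert hi.count == 2 and hi.mean_score == pytest.approx(0.95)


class TestErrorLedger:
    def _dec(self, pred, gold, i):
        return PresenceDecision(f"n{i}", "f", pred, gold, "binary_overlap")

    def test_reduction_and_rate_arithmetic(self):
        from notegate.evaluation import ErrorLedger, VariantErrors

        # printed-count arithmetic: 3081 -> 311 is an 89.9% reduction;
        # 599 missing of 2861 is a 20.9% rate
        assert ErrorLedger.reduction(3081, 311) == 89.9
        v = VariantErrors("vanilla", 335, 599, 2861)
        assert v.miss_rate == 20.9
        assert v.hallucination_rate == 11.7
        assert ErrorLedger.reduction(100, 100) == 0.0
        assert ErrorLedger.reduction(0, 5) is None

    def test_half_up_rounding(self):
        assert round1(0.25 * 100 / 100) == 0.3  # 0.25 -> 0.3, not banker's 0.2
        assert round1(89.85) == 89.9

    def test_counts_from_decisions(self):
        decisions = [
            self._dec(True, True, 0),
            self._dec(True, False, 1),  # hallucination
            self._dec(False, True, 2),  # miss
            self._dec(False, False, 3),
        ]
        ledger = error_ledger({"m": decisions})
        v = ledger["m"]
        assert v.hallucinated_count == 1 and v.missing_count == 1
        assert v.total_features == 4

    def test_gate_rejected_assertions_counted_as_hallucinations(self):
        decisions = [self._dec(False, False, 0)]
        rejected = Extraction("n0", "f", "made up", gate=GateDecision("rejected", "none"))
        ledger = error_ledger({"m": decisions}, {"m": [rejected]})
        assert ledger["m"].hallucinated_count == 1
        ledger_off = error_ledger(
            {"m": decisions}, {"m": [rejected]}, count_rejected_as_hallucination=False
        )
        assert ledger_off["m"].hallucinated_count == 0

    def test_per_feature_rates(self):
        decisions = [
            PresenceDecision("n1", "fa", True, True, "binary_overlap"),
            PresenceDecision("n2", "fa", True, False, "binary_overlap"),
            PresenceDecision("n1", "fb", False, True, "binary_overlap"),
        ]
        rates = per_feature_error_rates(decisions)
        assert rates["fa"] == (50.0, 0.0)
        assert rates["fb"] == (0.0, 100.0)


class TestPairedComparison:
    def _make(self, correct_flags, mode="binary_overlap"):
        return [
            PresenceDecision(f"n{i % 5}", f"f{i}", flag, True, mode)
            for i, flag in enumerate(correct_flags)
        ]

    def test_identical_models(self):
        a = self._make([True] * 10 + [False] * 2)
        diff, ci, p = paired_comparison(a, a, n_boot=200, seed=0)
        assert diff == 0.0
        assert ci[0] <= 0.0 <= ci[1]
        assert p == 1.0

    def test_mcnemar_exact_binomial_tail(self):
        # 20 discordant pairs, all favoring B: p = 2 * 0.5^20
        assert mcnemar_p(0, 20) == pytest.approx(2 * 0.5**20)
        assert mcnemar_p(10, 10) == 1.0
        assert mcnemar_p(0, 0) == 1.0
        # large-sample branch uses continuity-corrected chi-square
        expected = stats.chi2.sf((abs(30 - 10) - 1) ** 2 / 40, 1)
        assert mcnemar_p(30, 10) == pytest.approx(expected)

    def test_discordant_table_matches_construction(self):
        a = self._make([True] * 6 + [False] * 4)
        b = self._make([True] * 8 + [False] * 2)
        # items 6,7: A wrong, B correct (c=2); none where A correct B wrong
        _, _, p = paired_comparison(a, b, n_boot=50, seed=0)
        assert p == pytest.approx(2 * 0.5**2 if False else mcnemar_p(0, 2))

    def test_symmetric_up_to_sign(self):
        a = self._make([True] * 7 + [False] * 3)
        b = self._make([True] * 9 + [False] * 1)
        d_ab, _, p_ab = paired_comparison(a, b, n_boot=100, seed=3)
        d_ba, _, p_ba = paired_comparison(b, a, n_boot=100, seed=3)
        assert d_ab == pytest.approx(-d_ba)
        assert p_ab == p_ba

    def test_misaligned_keys_rejected(self):
        a = self._make([True] * 3)
        b = self._make([True] * 4)
        with pytest.raises(ValueError):
            paired_comparison(a, b, n_boot=10, seed=0)

    def test_deterministic_under_seed(self):
        a = self._make([True] * 8 + [False] * 2)
        b = self._make([False] * 3 + [True] * 7)
        assert paired_comparison(a, b, 300, seed=11) == paired_comparison(a, b, 300, seed=11)


class TestReviewQueue:
    def _sem(self, i, pred, gold, sim=None, borderline=False):
        return PresenceDecision(f"n{i}", "f", pred, gold, "semantic", sim, borderline)

    def test_empty_queue(self):
        assert review_queue([self._sem(0, True, True, 0.9)]) == []

    def test_borderline_then_misses(self):
        items = [
            self._sem(0, True, True, 0.55, True),
            self._sem(1, False, True, 0.2),
            self._sem(2, True, True, 0.9),
        ]
        queue = review_queue(items)
        assert [q.note_id for q in queue] == ["n0", "n1"]

    def test_borderline_sorted_ascending(self):
        items = [
            self._sem(0, True, True, 0.68, True),
            self._sem(1, True, True, 0.52, True),
            self._sem(2, True, True, 0.60, True),
        ]
        sims = [q.similarity for q in review_queue(items)]
        assert sims == sorted(sims)

    def test_non_semantic_rejected(self):
        with pytest.raises(ValueError):
            review_queue([PresenceDecision("n", "f", True, True, "binary_overlap")])
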