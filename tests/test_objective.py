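"""Confidence-regularized objective: penalty composition, loss, epoch loop."""

import numpy as np
import pytest

from notegate.confidence import ConfidenceConfig, EpochState
from notegate.corpus import Extraction, GoldAnnotation
from notegate.objective import (
    PenaltyConfig,
    note_penalties,
    overconfidence_penalty,
    run_epoch,
    total_loss,
)
from notegate.synthetic import MockGenerator, MockProfile


class TestOverconfidencePenalty:
    @pytest.mark.parametrize("c", [0.0, 0.3, 0.6])
    def test_zero_at_or_below_threshold(self, c):
        assert overconfidence_penalty(0.9, c, 0.6) == 0.0

    def test_zero_for_perfect_match(self):
        assert overconfidence_penalty(0.0, 0.99, 0.6) == 0.0

    def test_hand_composition(self):
        assert overconfidence_penalty(0.8, 0.8, 0.6, 2.0) == pytest.approx(0.704)

    def test_monotone_increasing_in_confidence(self):
        vals = [overconfidence_penalty(0.5, c, 0.6) for c in np.linspace(0.601, 1.0, 30)]
        assert vals == sorted(vals)

    def test_continuous_just_above_threshold(self):
        eps = 1e-9
        assert overconfidence_penalty(0.5, 0.6 + eps, 0.6) == pytest.approx(0.3, abs=1e-6)

    def test_raising_tau_never_increases_penalty(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            base, c = rng.uniform(0, 1, 2)
            t1, t2 = sorted(rng.uniform(0, 1, 2))
            assert overconfidence_penalty(base, c, t2) <= overconfidence_penalty(
                base, c, t1
            ) + 1e-12


class TestTotalLoss:
    def test_pure_language_modeling_step(self):
        lb = total_loss(0.7, 0.0, 0.0)
        assert lb.total == 0.7
        assert lb.no_penalty_gradient

    def test_weighted_combination(self):
        lb = total_loss(1.0, 0.5, 0.2)
        assert lb.total == pytest.approx(1.2)
        assert not lb.no_penalty_gradient

    def test_zero_weights_degenerate(self):
        cfg = PenaltyConfig(w_hallucination=0.0, w_missing=0.0)
        assert total_loss(0.4, 9.0, 9.0, cfg).total == pytest.approx(0.4)

    def test_exact_linear_identity_random_coefficients(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            ce, hall, miss = rng.uniform(0, 3, 3)
            wh, wm = rng.uniform(0, 2, 2)
            cfg = PenaltyConfig(w_hallucination=wh, w_missing=wm)
            lb = total_loss(ce, hall, miss, cfg)
            assert lb.total == ce + wh * hall + wm * miss  # exact, not approx

    def test_negative_components_rejected(self):
        with pytest.raises(ValueError):
            total_loss(-0.1, 0.0, 0.0)


def _gold(fid, text):
    return GoldAnnotation("n1", fid, (text,), (((0, len(text)),),))


class TestNotePenalties:
    def test_perfect_extractor_no_penalties(self):
        gold = [_gold("f1", "fever"), _gold("f2", "chest pain")]
        ext = [
            Extraction("n1", "f1", "fever", confidence=0.99),
            Extraction("n1", "f2", "chest pain", confidence=0.99),
        ]
        hall, miss, _ = note_penalties(ext, gold, tau=0.6)
        assert hall == 0.0 and miss == 0.0

    def test_fabrication_hand_trace(self):
        # one fabricated prediction, confidence 0.9, no gold at all:
        # base 1 -> penalty 0.9 + 2 * 0.3^2 = 1.08
        ext = [Extraction("n1", "f1", "zzzqqq", confidence=0.9)]
        hall, miss, _ = note_penalties(ext, [], tau=0.6)
        assert hall == pytest.approx(1.08)
        assert miss == 0.0

    def test_silent_extractor_maximal_missing(self):
        gold = [_gold(f"f{i}", t) for i, t in enumerate(["fever", "chills", "cough"])]
        ext = [Extraction("n1", g.feature_id, "") for g in gold]
        hall, miss, _ = note_penalties(ext, gold, tau=0.6)
        assert hall == 0.0
        assert miss == pytest.approx(1.0)

    def test_confidence_derived_from_token_probs_when_unset(self):
        # constant probs 0.9 over 1 token -> c = 0.9^(1 + 1/20) ~ 0.8953 > tau
        ext = [Extraction("n1", "f1", "zzzqqq", token_probs=(0.9,))]
        hall, _, _ = note_penalties(ext, [], tau=0.6)
        c = 0.9 ** (1 + 1 / 20)
        assert hall == pytest.approx(c + 2 * (c - 0.6) ** 2)


class TestRunEpoch:
    def _setup(self, small_corpus, profile, seed=3):
        _, notes, features, gold = small_corpus
        gen = MockGenerator(notes, features, gold, profile, seed=seed)
        return gen, notes, features, gold

    def test_error_free_generator_all_penalties_zero(self, small_corpus):
        prof = MockProfile(hallucination_rate=0, miss_rate=0, paraphrase_noise=0)
        gen, notes, features, gold = self._setup(small_corpus, prof)
        res = run_epoch(gen, notes, features, gold, EpochState(0, 5))
        assert all(v == 0.0 for v in res.case_hallucination_mean.values())
        assert all(v == 0.0 for v in res.case_missing_mean.values())
        assert all(lb.no_penalty_gradient for lb in res.losses.values())
        assert res.epoch_f1 == pytest.approx(1.0)

    def test_hand_built_single_note_breakdown(self):
        from notegate.corpus import FeatureSpec, PatientNote

        note = PatientNote("n1", "c1", "has fever. also zzz.")
        features = [FeatureSpec("f1", "c1", "fever"), FeatureSpec("f2", "c1", "cough")]
        gold = [
            GoldAnnotation("n1", "f1", ("fever",), (((4, 9),),)),
            GoldAnnotation("n1", "f2"),
        ]

        def generator(n, feats):
            return [("fever", [0.95]), ("", [])][: len(feats)]

        res = run_epoch(
            generator, [note], features, gold, EpochState(0, 5), ce_loss=0.5
        )
        lb = res.losses["n1"]
        assert lb.ce_loss == 0.5
        assert lb.hallucination_penalty == 0.0
        assert lb.missing_penalty == 0.0
        assert lb.total == 0.5

    def test_generator_contract_violation_names_note(self, small_corpus):
        _, notes, features, gold = small_corpus

        def bad_generator(note, feats):
            return []

        with pytest.raises(ValueError, match=notes[0].note_id):
            run_epoch(bad_generator, notes, features, gold, EpochState(0, 5))

    def test_decaying_error_schedule_penalties_trend_down(self, small_corpus):
        """Mean penalties over a decay-0.5 epoch series fall and end low."""
        prof = MockProfile(epoch_decay=0.5)
        firsts, lasts = [], []
        for seed in range(5):
            gen, notes, features, gold = self._setup(small_corpus, prof, seed=seed)
            state = EpochState(0, 5)
            series = []
            for e in range(5):
                gen.set_epoch(e)
                res = run_epoch(gen, notes, features, gold, state)
                state = res.state
                series.append(
                    np.mean(list(res.case_hallucination_mean.values()))
                    + np.mean(list(res.case_missing_mean.values()))
                )
            firsts.append(series[0])
            lasts.append(series[-1])
        assert np.mean(lasts) < np.mean(firsts)
        assert np.mean(lasts) < 0.2
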