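"""Referral detection and the three-principle arbitration logic."""

from itertools import product

import numpy as np
import pytest

import emosig
from emosig.classifiers import decision_from_values
from emosig.team import (
    MarginSummary,
    ReferralConfig,
    classify_batch,
    is_referral,
    margin_predicate,
    margin_summary,
    team_decide,
)
from oracles import straight_line_team

CLASSES = ("anger", "joy", "pleasure", "sadness")  # sorted label order


def unanimous_decision(scale_top=1.0, scale_rest=1.0):
    """Decision where the first class wins every one of its pairs."""
    # pairs: (an,jo) (an,pl) (an,sa) (jo,pl) (jo,sa) (pl,sa)
    vals = [1.0 * scale_top, 1.2 * scale_top, 2.0 * scale_top,
            0.5 * scale_rest, 0.4 * scale_rest, 0.3 * scale_rest]
    return decision_from_values(CLASSES, vals)


class TestMarginSummary:
    def test_min_max_over_top_class_models(self):
        pd = unanimous_decision()
        m = margin_summary(pd)
        assert m.u_min == pytest.approx(1.0)
        assert m.h_max == pytest.approx(2.0)

    def test_degenerate_equal_magnitudes(self):
        pd = decision_from_values(CLASSES, [1.0] * 6)
        m = margin_summary(pd)
        assert m.u_min == m.h_max == m.v_min == m.s_max == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_ordering_invariants_on_random_decisions(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            pd = decision_from_values(CLASSES, rng.uniform(-3, 3, 6))
            m = margin_summary(pd)
            assert 0.0 <= m.u_min <= m.h_max
            assert 0.0 <= m.v_min <= m.s_max


class TestReferral:
    def test_tied_top_votes_always_refer(self):
        # A beats B,C; D beats A; B beats C,D -> A and B tie at 2 votes
        pd = decision_from_values("ABCD", [0.5, 0.5, -0.5, 0.5, 0.5, 0.1])
        assert pd.votes[pd.top] == pd.votes[pd.second] == 2
        assert is_referral(pd, ReferralConfig())

    def test_confident_winner_outside_conditions_is_not_referred(self):
        # margin predicate fails at t1 < h_max * v_min
        m = MarginSummary(u_min=2.0, h_max=3.0, v_min=0.1, s_max=0.2)
        assert not margin_predicate(m, ReferralConfig(t1=1.5, t2=3.0))

    def test_borderline_margins_trigger_referral(self):
        m = MarginSummary(u_min=1.0, h_max=2.0, v_min=0.9, s_max=1.1)
        assert margin_predicate(m, ReferralConfig(t1=1.5, t2=3.0))

    def test_full_pipeline_referral_uses_margins(self):
        # same margins as the borderline case, realized as decision values:
        # top class values {1.0, 2.0, 1.5}; second class shares none below 0.9
        vals = [1.0, 2.0, 1.5, 0.9, 1.1, 0.2]
        pd = decision_from_values(CLASSES, vals)
        assert pd.top == "anger"
        m = margin_summary(pd)
        assert is_referral(pd) == margin_predicate(m)

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ReferralConfig(t1=0.0)


class TestTeamDecide:
    def test_principle_one_trusts_svm(self):
        pd = unanimous_decision(scale_top=3.0, scale_rest=0.05)
        assert not is_referral(pd)
        v = team_decide(pd, "joy", "sadness")
        assert (v.label, v.principle, v.referred) == ("anger", "I", False)

    def test_principle_two_majority_with_auxiliary(self):
        pd = decision_from_values("ABCD", [0.5, 0.5, -0.5, 0.5, 0.5, 0.1])
        assert is_referral(pd)
        v = team_decide(pd, pd.top, "D")
        assert (v.label, v.principle) == (pd.top, "II")

    def test_principle_three_switches_to_second(self):
        pd = decision_from_values("ABCD", [0.5, 0.5, -0.5, 0.5, 0.5, 0.1])
        top, second = pd.top, pd.second
        other = next(c for c in "ABCD" if c not in (top, second))
        v = team_decide(pd, second, other)
        assert (v.label, v.principle) == (second, "III")

    def test_fallback_keeps_svm_top(self):
        pd = decision_from_values("ABCD", [0.5, 0.5, -0.5, 0.5, 0.5, 0.1])
        others = [c for c in "ABCD" if c not in (pd.top, pd.second)]
        v = team_decide(pd, others[0], others[1])
        assert (v.label, v.principle) == (pd.top, "FALLBACK")

    def test_unknown_auxiliary_label_rejected(self):
        pd = unanimous_decision()
        with pytest.raises(ValueError, match="ELM"):
            team_decide(pd, "joy", "fear")

    @pytest.mark.parametrize("referred", [False, True])
    def test_exhaustive_64_case_oracle(self, referred):
        """All combinations of (dt, elm) labels against every possible top
        class match a straight-line transcription of the principles."""
        for top_idx, dt, elm in product(range(4), CLASSES, CLASSES):
            # build a decision whose top class is CLASSES[top_idx]
            vals = []
            for i, j in zip(*np.triu_indices(4, k=1)):
                if i == top_idx:
                    vals.append(1.0 + 0.1 * j)
                elif j == top_idx:
                    vals.append(-(1.0 + 0.1 * i))
                else:
                    vals.append(0.2 if i < j else -0.2)
            pd = decision_from_values(CLASSES, vals)
            assert pd.top == CLASSES[top_idx]
            cfg = (
                ReferralConfig(t1=1e-9, t2=1e9)   # predicate fires
                if referred
                else ReferralConfig(t1=1e9, t2=1e-9)  # predicate never fires
            )
            v = team_decide(pd, dt, elm, cfg)
            want_label, want_principle = straight_line_team(
                is_referral(pd, cfg), pd.top, pd.second, dt, elm
            )
            assert (v.label, v.principle) == (want_label, want_principle)


class TestClassifyBatch:
    def test_no_referral_matches_svm_exactly(self, trained_models):
        svm, dt, elm = (trained_models[k] for k in ("svm", "dt", "elm"))
        Xte = trained_models["Xte"]
        # a config under which the margin predicate can never fire
        cfg = ReferralConfig(t1=1e9, t2=1e-9)
        verdicts = classify_batch(svm, dt, elm, Xte, cfg)
        svm_pred = svm.estimator.predict(Xte)
        for v, s in zip(verdicts, svm_pred):
            if not v.referred:  # only vote ties can still refer
                assert v.label == s and v.principle == "I"
        assert sum(v.referred for v in verdicts) <= 2  # ties are rare

    def test_forced_referral_uses_arbitration_only(self, trained_models):
        svm, dt, elm = (trained_models[k] for k in ("svm", "dt", "elm"))
        Xte = trained_models["Xte"]
        cfg = ReferralConfig(t1=1e-9, t2=1e9)
        verdicts = classify_batch(svm, dt, elm, Xte, cfg)
        dt_pred, elm_pred = dt.predict(Xte), elm.predict(Xte)
        for v, d, e in zip(verdicts, dt_pred, elm_pred):
            if v.referred:
                want = straight_line_team(True, v.svm_top, v.svm_second, d, e)
                assert (v.label, v.principle) == want

    def test_principle_counts_sum_to_batch(self, trained_models):
        svm, dt, elm = (trained_models[k] for k in ("svm", "dt", "elm"))
        verdicts = classify_batch(svm, dt, elm, trained_models["Xte"])
        counts = {}
        for v in verdicts:
            counts[v.principle] = counts.get(v.principle, 0) + 1
        assert sum(counts.values()) == len(trained_models["Xte"])

    def test_feature_mismatch_rejected(self, trained_models):
        svm, dt, elm = (trained_models[k] for k in ("svm", "dt", "elm"))
        with pytest.raises(ValueError, match="dimension"):
            classify_batch(svm, dt, elm, np.zeros((3, 5)))
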