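"""Matching rates, filtering, Boschloo's test, and the Bayesian A/B model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, fisher_exact

from cardalign import analysis
from cardalign.analysis import (
    UndefinedOptimumError,
    add_match_indicators,
    aggregate_counts,
    boschloo_test,
    filter_participants,
    fit_ab_model,
    hypothesis_evidence,
    optimal_guess,
    score_participant,
    stratified_matching,
)


def boschloo_oracle(sa, na, sb, nb, grid=200):
    """Enumeration oracle: supremum over the nuisance success probability of
    P(one-sided Fisher p <= observed p), computed over the full outcome grid."""
    def fisher_greater(xa, xb):
        return fisher_exact([[xa, na - xa], [xb, nb - xb]],
                            alternative="greater")[1]

    obs = fisher_greater(sa, sb)
    xs_a = np.arange(na + 1)
    xs_b = np.arange(nb + 1)
    stat = np.array([[fisher_greater(xa, xb) for xb in xs_b] for xa in xs_a])
    extreme = stat <= obs + 1e-12
    best = 0.0
    for p in np.linspace(1e-6, 1 - 1e-6, grid):
        pa = binom.pmf(xs_a, na, p)
        pb = binom.pmf(xs_b, nb, p)
        best = max(best, float(pa @ extreme @ pb))
    return best


class TestMatching:
    def test_optimal_guess_thresholds_at_half(self):
        assert optimal_guess(33 / 65) == "red"
        assert optimal_guess(3 / 65) == "black"
        with pytest.raises(UndefinedOptimumError):
            optimal_guess(0.5)

    def test_hand_computed_indicator_table(self):
        recs = pd.DataFrame(
            {
                "r_num": [33, 33, 3, 3],
                "r_den": [65] * 4,
                "initial_guess": ["red", "black", "black", "red"],
                "final_guess": ["red", "red", "black", "black"],
            }
        )
        out = add_match_indicators(recs)
        assert out["Q"].tolist() == [1, 0, 1, 0]
        assert out["Qp"].tolist() == [1, 1, 1, 1]

    def test_scoring_rule_and_bonus_floor(self):
        def fake(n_correct, n_wrong):
            return pd.DataFrame(
                {
                    "final_guess": ["red"] * (n_correct + n_wrong),
                    "outcome_is_red": [1] * n_correct + [0] * n_wrong,
                }
            )

        assert score_participant(fake(24, 0)) == (24, 2.88)
        assert score_participant(fake(12, 12)) == (0, 0.0)
        assert score_participant(fake(0, 24)) == (-24, 0.0)

    def test_aggregate_counts_hand_example(self):
        rows = []
        for i in range(10):  # 10 games with Q=0, 7 of which end optimal
            rows.append((7, "toward", 33, 65, "black", "red" if i < 7 else "black"))
        for i in range(14):  # 14 games with Q=1, all stay optimal
            rows.append((7, "toward", 33, 65, "red", "red"))
        df = pd.DataFrame(
            rows,
            columns=["participant_id", "group", "r_num", "r_den",
                     "initial_guess", "final_guess"],
        )
        df["is_attention_check"] = 0
        counts = aggregate_counts(df)
        row0 = counts[counts.q == 0].iloc[0]
        row1 = counts[counts.q == 1].iloc[0]
        assert (row0.successes, row0.trials) == (7, 10)
        assert (row1.successes, row1.trials) == (14, 14)

    def test_empty_input_gives_empty_table(self):
        assert len(aggregate_counts(pd.DataFrame(columns=["is_attention_check"]))) == 0


class TestFiltering:
    def _attention(self, confs):
        rows = []
        for pid, per_check in enumerate(confs):
            for chk, c in enumerate(per_check):
                rows.append((pid, chk, c, 1))
        return pd.DataFrame(
            rows,
            columns=["participant_id", "round_index", "initial_confidence",
                     "is_attention_check"],
        )

    def test_exclusion_requires_more_than_one_flag(self):
        base = [[50, 50, 50]] * 20
        one_dev = [[99, 50, 50]]    # flagged once -> kept
        two_dev = [[99, 1, 50]]     # flagged twice -> excluded
        df = self._attention(base + one_dev + two_dev)
        kept, excluded, stats = filter_participants(df)
        assert 20 in kept
        assert excluded == [21]

    def test_identical_cohort_keeps_everyone(self):
        df = self._attention([[10, 80, 95]] * 15)
        kept, excluded, _ = filter_participants(df)
        assert excluded == []
        assert len(kept) == 15

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(0)
        df = self._attention(rng.integers(0, 101, size=(40, 3)).tolist())
        kept1, excl1, _ = filter_participants(df)
        shuffled = df.sample(frac=1.0, random_state=1)
        kept2, excl2, _ = filter_participants(shuffled)
        assert kept1 == kept2 and excl1 == excl2
        again = df[df.participant_id.isin(kept1)]
        kept3, excl3, _ = filter_participants(again)
        assert set(kept3) <= set(kept1)

    def test_missing_checks_rejected(self):
        df = self._attention([[50, 50, 50]] * 3)
        with pytest.raises(ValueError):
            filter_participants(df.iloc[:-1])


class TestBoschloo:
    def test_identical_proportions_carry_no_evidence(self):
        # the exact unconditional p at equal rates sits just below 1/2
        # (0.472 by enumeration); anything near or above it means no evidence
        assert boschloo_test(5, 10, 5, 10, "greater") > 0.4

    def test_extreme_separation_is_decisive(self):
        assert boschloo_test(10, 10, 0, 10, "greater") < 0.001

    def test_zero_trials_undefined(self):
        with pytest.raises(ValueError):
            boschloo_test(0, 0, 1, 5)

    @pytest.mark.parametrize(
        "sa,na,sb,nb", [(7, 9, 3, 8), (5, 6, 1, 7), (4, 10, 4, 10), (9, 12, 2, 5)]
    )
    def test_matches_enumeration_oracle(self, sa, na, sb, nb):
        p = boschloo_test(sa, na, sb, nb, "greater")
        ref = boschloo_oracle(sa, na, sb, nb)
        assert p == pytest.approx(ref, abs=2e-3)

    def test_never_exceeds_fisher_one_sided(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            na, nb = rng.integers(2, 13, 2)
            sa, sb = rng.integers(0, na + 1), rng.integers(0, nb + 1)
            pb = boschloo_test(int(sa), int(na), int(sb), int(nb), "greater")
            pf = fisher_exact(
                [[sa, na - sa], [sb, nb - sb]], alternative="greater"
            )[1]
            assert pb <= pf + 1e-9


@pytest.fixture(scope="module")
def symmetric_posterior():
    rng = np.random.default_rng(4)
    rows = []
    for pid in range(160):
        g = "a" if pid < 80 else "b"
        rows.append((pid, g, 0, int(rng.binomial(8, 0.6)), 8))
        rows.append((pid, g, 1, int(rng.binomial(16, 0.9)), 16))
    counts = pd.DataFrame(
        rows, columns=["participant_id", "group", "q", "successes", "trials"]
    )
    return fit_ab_model(counts, seed=21)


class TestABModel:
    def test_needs_two_groups(self):
        counts = pd.DataFrame(
            {"participant_id": [0], "group": ["a"], "q": [0],
             "successes": [1], "trials": [2]}
        )
        with pytest.raises(ValueError):
            fit_ab_model(counts, seed=0)

    def test_enough_draws_and_converged(self, symmetric_posterior):
        assert symmetric_posterior.n_draws >= 4000
        assert all(v < 1.01 for k, v in symmetric_posterior.rhat.items()
                   if k.startswith("beta"))

    def test_exchangeable_groups_center_difference_at_zero(self, symmetric_posterior):
        h = hypothesis_evidence(symmetric_posterior, 0, "a", "b")
        assert abs(h.estimate) < 3 * h.est_error
        assert 0.01 < h.post_prob < 0.99

    def test_evidence_ratio_is_posterior_odds(self, symmetric_posterior):
        h = hypothesis_evidence(symmetric_posterior, 1, "a", "b")
        if 0 < h.post_prob < 1:
            assert h.evidence_ratio == pytest.approx(
                h.post_prob / (1 - h.post_prob)
            )


class TestStratifiedMatching:
    def test_cells_with_at_most_min_count_records_are_omitted(self):
        rows = []
        for i in range(10):
            rows.append((i, "g", 33, 65, 92, "red", "red", 0))
        df = pd.DataFrame(
            rows,
            columns=["participant_id", "group", "r_num", "r_den", "a_shown",
                     "initial_guess", "final_guess", "is_attention_check"],
        )
        df["a_num"], df["a_den"] = 7, 13
        assert len(stratified_matching(df, min_count=10)) == 0
        df2 = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        out = stratified_matching(df2, min_count=10)
        assert len(out) == 1
        assert out.iloc[0].x == 1.0 and out.iloc[0].y == 1.0

    def test_obedient_agents_in_agreement_cells_match_perfectly(self):
        # participants who always follow a perfectly-pointing AI
        rows = []
        for i in range(30):
            rows.append((i, "g", 7, 13, 37, 65, 54, "red", "red", 0))
            rows.append((i, "g", 6, 13, 27, 65, 46, "black", "black", 0))
        df = pd.DataFrame(
            rows,
            columns=["participant_id", "group", "a_num", "a_den", "r_num",
                     "r_den", "a_shown", "initial_guess", "final_guess",
                     "is_attention_check"],
        )
        out = stratified_matching(df)
        assert (out.y == 1.0).all()
        assert (out.agrees_with_ai == 1).all()

    def test_ai_corrects_disagreeing_low_performers(self, small_cohorts):
        recs = small_cohorts["records"]["away"]
        out = stratified_matching(recs[recs.is_attention_check == 0], min_count=10)
        dis = out[(out.agrees_with_ai == 0) & (out.x < 0.3)]
        if len(dis):
            assert (dis.y >= dis.x).mean() > 0.8
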