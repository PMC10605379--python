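"""Fusion-core unit and property tests: both ensemble rules, weights, tie-breaks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionfuse import (
    BinaryDecision,
    ClassCatalog,
    ConfusionMatrix,
    PredictionMatrix,
    ScoreVector,
    StructuralError,
    WeightMatrix,
    argmax_with_tiebreak,
    branch_set_from_decisions,
    estimate_binary_weights,
    estimate_weights_from_confusion,
    fuse_model1,
    fuse_model2,
    harden,
    score_network_binary,
)

from conftest import MODELS, all_hard_vote_combos, one_hot_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_model1(P: PredictionMatrix, W: WeightMatrix) -> dict[str, float]:
    """Term-by-term evaluation of the per-class weighted sums."""
    totals = {}
    for c in P.catalog:
        ci = P.catalog.index(c)
        totals[c] = sum(
            P.rows[mi, ci] * W.weights[mi, ci] for mi in range(len(P.model_ids))
        )
    return totals


def plurality_vote(votes: tuple[str, ...], catalog: ClassCatalog) -> str:
    counts = {c: votes.count(c) for c in catalog}
    best = max(counts.values())
    return next(c for c in catalog if counts[c] == best)


# ---------------------------------------------------------------------------
# direct fusion (Ensemble Model 1)
# ---------------------------------------------------------------------------


class TestFuseModel1:
    def test_published_weight_worked_example(self, catalog, published_weights):
        """Hard votes (mel, bkl, mel) under the published F1 weights fuse to mel."""
        P = one_hot_matrix(catalog, ("mel", "bkl", "mel"))
        res = fuse_model1(P, published_weights)
        assert res.scores["mel"] == pytest.approx(1.67)
        assert res.scores["bkl"] == pytest.approx(0.74)
        assert res.scores["nv"] == 0.0 and res.scores["bcc"] == 0.0
        assert res.predicted == "mel" and not res.tie

    def test_unanimous_vote_wins_under_any_positive_weights(self, catalog):
        W = WeightMatrix(catalog, MODELS, np.full((3, 4), 0.31))
        res = fuse_model1(one_hot_matrix(catalog, ("nv", "nv", "nv")), W)
        assert res.predicted == "nv"

    def test_matches_brute_force_on_all_hard_combos(self, catalog, published_weights):
        """Exhaustive check: argmax equals the term-by-term oracle on all 64 combos."""
        for votes in all_hard_vote_combos(catalog):
            P = one_hot_matrix(catalog, votes)
            res = fuse_model1(P, published_weights)
            oracle = brute_force_model1(P, published_weights)
            expected, _ = argmax_with_tiebreak(oracle, catalog)
            assert res.predicted == expected
            for c in catalog:
                assert res.scores[c] == pytest.approx(oracle[c], abs=1e-12)

    def test_unit_weights_reduce_to_plurality_vote(self, catalog):
        W = WeightMatrix.unit(MODELS, catalog)
        for votes in all_hard_vote_combos(catalog):
            res = fuse_model1(one_hot_matrix(catalog, votes), W, mode="hard")
            assert res.predicted == plurality_vote(votes, catalog)

    def test_breakdown_records_each_product_term(self, catalog, published_weights):
        P = one_hot_matrix(catalog, ("mel", "bkl", "mel"))
        res = fuse_model1(P, published_weights)
        assert res.breakdown.loc["m1", "mel"] == pytest.approx(0.82)
        assert res.breakdown.loc["m2", "bkl"] == pytest.approx(0.74)
        assert res.breakdown.sum(axis=0).to_numpy() == pytest.approx(res.scores.as_array())

    def test_soft_mode_uses_score_mass_not_argmax(self, catalog):
        rows = np.array(
            [
                [0.4, 0.3, 0.2, 0.1],
                [0.4, 0.3, 0.2, 0.1],
                [0.0, 1.0, 0.0, 0.0],
            ]
        )
        P = PredictionMatrix(catalog, MODELS, rows)
        W = WeightMatrix.unit(MODELS, catalog)
        soft = fuse_model1(P, W, mode="soft")
        hard = fuse_model1(P, W, mode="hard")
        assert soft.scores["nv"] == pytest.approx(1.6)
        assert soft.predicted == "nv"  # mass 1.6 beats mel's 0.8
        assert hard.predicted == "mel"  # two hard mel votes beat one nv

    def test_shape_and_catalog_mismatch_rejected(self, catalog, published_weights):
        P = one_hot_matrix(catalog, ("mel", "mel"))  # only two models
        with pytest.raises(StructuralError):
            fuse_model1(P, published_weights)
        other = WeightMatrix.unit(MODELS, ClassCatalog(("nv", "mel", "bcc", "bkl")))
        with pytest.raises(StructuralError):
            fuse_model1(one_hot_matrix(catalog, ("mel", "mel", "mel")), other)


# ---------------------------------------------------------------------------
# pairwise branch scoring and Ensemble Model 2
# ---------------------------------------------------------------------------


def hard_branch_set(catalog, winners: dict[tuple[str, str], str], weights=None, model_id="model"):
    decisions = {}
    for pair in catalog.pairs():
        w = winners[pair]
        decisions[pair] = BinaryDecision(pair, 1.0 if w == pair[0] else 0.0, 1.0 if w == pair[1] else 0.0)
    return branch_set_from_decisions(decisions, weights, catalog, model_id)


class TestScoreNetworkBinary:
    def test_unit_weight_soft_sum(self, catalog):
        """mel mass 0.7 + 0.8 + 0.6 across its three branches totals 2.1."""
        decisions = {
            ("mel", "nv"): BinaryDecision(("mel", "nv"), 0.7, 0.3),
            ("mel", "bcc"): BinaryDecision(("mel", "bcc"), 0.8, 0.2),
            ("mel", "bkl"): BinaryDecision(("mel", "bkl"), 0.6, 0.4),
            ("nv", "bcc"): BinaryDecision(("nv", "bcc"), 0.5, 0.5),
            ("nv", "bkl"): BinaryDecision(("nv", "bkl"), 0.5, 0.5),
            ("bcc", "bkl"): BinaryDecision(("bcc", "bkl"), 0.5, 0.5),
        }
        vec = score_network_binary(branch_set_from_decisions(decisions, catalog=catalog))
        assert vec["mel"] == pytest.approx(2.1)

    def test_sweeping_own_branches_guarantees_win(self, catalog):
        """If every mel branch picks mel, no rival can exceed mel's total of 3."""
        for others in itertools.product([0, 1], repeat=3):
            winners = {}
            for pair in catalog.pairs():
                if "mel" in pair:
                    winners[pair] = "mel"
            rest = [p for p in catalog.pairs() if "mel" not in p]
            for bit, pair in zip(others, rest):
                winners[pair] = pair[bit]
            vec = score_network_binary(hard_branch_set(catalog, winners))
            assert vec["mel"] == 3.0
            assert all(vec[c] <= 2.0 for c in catalog if c != "mel")

    def test_missing_branch_rejected(self, catalog):
        decisions = {("mel", "nv"): BinaryDecision(("mel", "nv"), 1.0, 0.0)}
        with pytest.raises(StructuralError):
            branch_set_from_decisions(decisions, catalog=catalog)

    def test_negative_weight_rejected(self, catalog):
        weights = {p: (1.0, 1.0) for p in catalog.pairs()}
        weights[("mel", "nv")] = (-0.1, 1.0)
        winners = {p: p[0] for p in catalog.pairs()}
        with pytest.raises(StructuralError):
            hard_branch_set(catalog, winners, weights)


class TestFuseModel2:
    def test_single_model_equals_branch_scoring(self, catalog):
        winners = {p: p[0] for p in catalog.pairs()}
        bs = hard_branch_set(catalog, winners)
        res = fuse_model2([bs])
        direct = score_network_binary(bs)
        assert res.scores.as_array() == pytest.approx(direct.as_array())

    def test_three_identical_models_triple_the_totals(self, catalog):
        winners = {p: p[1] for p in catalog.pairs()}
        bs = hard_branch_set(catalog, winners)
        res = fuse_model2([bs, bs, bs])
        single = score_network_binary(bs).as_array()
        assert res.scores.as_array() == pytest.approx(3 * single, abs=1e-12)

    def test_two_mel_voters_outvote_one_nv_voter(self, catalog):
        """Two models sweeping mel's branches beat one sweeping nv's: 6 votes to 5.

        The mel-sweeping models each leak one nv vote through the
        nv_bcc branch (their mel_nv branch is already taken by mel), so
        nv totals 3 + 2 = 5 against mel's 2 x 3 = 6.  Hand-tallied over
        the 18 branches.
        """
        mel_sweeper = {
            ("mel", "nv"): "mel",
            ("mel", "bcc"): "mel",
            ("mel", "bkl"): "mel",
            ("nv", "bcc"): "nv",
            ("nv", "bkl"): "bkl",
            ("bcc", "bkl"): "bcc",
        }
        nv_sweeper = {
            ("mel", "nv"): "nv",
            ("mel", "bcc"): "bcc",
            ("mel", "bkl"): "bkl",
            ("nv", "bcc"): "nv",
            ("nv", "bkl"): "nv",
            ("bcc", "bkl"): "bkl",
        }
        res = fuse_model2(
            [
                hard_branch_set(catalog, mel_sweeper, model_id="m1"),
                hard_branch_set(catalog, mel_sweeper, model_id="m2"),
                hard_branch_set(catalog, nv_sweeper, model_id="m3"),
            ]
        )
        assert res.scores["mel"] == 6.0
        assert res.scores["nv"] == 5.0
        assert res.predicted == "mel"

    def test_one_vs_one_guarantee_exhaustive(self, catalog):
        """Whenever the three mel branches all pick mel, the fused argmax is mel.

        Exhaustive over the 2^6 outcome patterns of one model's branches,
        replicated across three equal-weight models.
        """
        pairs = catalog.pairs()
        for bits in itertools.product([0, 1], repeat=len(pairs)):
            winners = {pair: pair[bit] for pair, bit in zip(pairs, bits)}
            if any(winners[p] != "mel" for p in pairs if "mel" in p):
                continue
            bs = hard_branch_set(catalog, winners)
            res = fuse_model2([bs, bs, bs])
            assert res.predicted == "mel"

    def test_inconsistent_catalogs_rejected(self, catalog):
        winners = {p: p[0] for p in catalog.pairs()}
        other_cat = ClassCatalog(("nv", "mel", "bcc", "bkl"))
        other_winners = {p: p[0] for p in other_cat.pairs()}
        with pytest.raises(StructuralError):
            fuse_model2(
                [hard_branch_set(catalog, winners), hard_branch_set(other_cat, other_winners)]
            )

    def test_unit_weights_reduce_to_unweighted_vote_sums(self, catalog):
        """With all weights one, totals are plain per-class vote counts."""
        winners = {p: p[0] for p in catalog.pairs()}
        bs = hard_branch_set(catalog, winners)
        res = fuse_model2([bs])
        for c in catalog:
            expected = sum(1 for p in catalog.pairs() if winners.get(p) == c)
            assert res.scores[c] == expected


# ---------------------------------------------------------------------------
# weight estimation
# ---------------------------------------------------------------------------


class TestWeightEstimation:
    def test_perfect_confusion_gives_unit_weights(self, catalog):
        cm = ConfusionMatrix(np.diag([5, 5, 5, 5]), catalog)
        assert estimate_weights_from_confusion(cm) == {c: 1.0 for c in catalog}

    def test_single_off_diagonal_error(self, catalog):
        counts = np.diag([5, 5, 5, 5])
        counts[0, 1] = 1
        w = estimate_weights_from_confusion(ConfusionMatrix(counts, catalog))
        assert w["mel"] == pytest.approx(10 / 11)
        assert w["nv"] == pytest.approx(10 / 11)

    def test_zero_true_positive_class_gets_zero_weight(self, catalog):
        counts = np.diag([5, 5, 5, 0])
        counts[3, 0] = 4  # every bkl mistaken for mel
        w = estimate_weights_from_confusion(ConfusionMatrix(counts, catalog))
        assert w["bkl"] == 0.0

    def test_empty_matrix_rejected(self, catalog):
        with pytest.raises(StructuralError):
            estimate_weights_from_confusion(ConfusionMatrix(np.zeros((4, 4)), catalog))

    def _validation(self, catalog, tp=8, fp=2, fn=2, tn=8):
        """Labelled decisions realising a given 2x2 table on every branch."""
        out = {}
        for pair in catalog.pairs():
            a, b = pair
            samples = []
            samples += [(BinaryDecision(pair, 1.0, 0.0), a)] * tp
            samples += [(BinaryDecision(pair, 0.0, 1.0), a)] * fn
            samples += [(BinaryDecision(pair, 1.0, 0.0), b)] * fp
            samples += [(BinaryDecision(pair, 0.0, 1.0), b)] * tn
            out[pair] = samples
        return out

    def test_f1_policy_matches_hand_computed_table(self, catalog):
        weights = estimate_binary_weights(self._validation(catalog), catalog)
        for pair, (wa, wb) in weights.items():
            assert wa == pytest.approx(0.8)  # 2*8 / (16 + 2 + 2)
            assert wb == pytest.approx(0.8)

    def test_perfect_separation_gives_unit_weights(self, catalog):
        weights = estimate_binary_weights(self._validation(catalog, fp=0, fn=0), catalog)
        assert all(w == (1.0, 1.0) for w in weights.values())

    def test_unit_policy_ignores_validation_data(self, catalog):
        weights = estimate_binary_weights(
            self._validation(catalog, tp=1, fp=7, fn=7, tn=1), catalog, policy="unit"
        )
        assert all(w == (1.0, 1.0) for w in weights.values())

    def test_accuracy_policy_shares_branch_accuracy(self, catalog):
        weights = estimate_binary_weights(self._validation(catalog), catalog, policy="accuracy")
        assert all(w == (pytest.approx(0.8), pytest.approx(0.8)) for w in weights.values())

    def test_single_class_branch_warns_and_falls_back(self, catalog):
        val = self._validation(catalog)
        pair = ("mel", "nv")
        val[pair] = [(BinaryDecision(pair, 1.0, 0.0), "mel")] * 5
        with pytest.warns(UserWarning, match="only class"):
            weights = estimate_binary_weights(val, catalog)
        assert weights[pair] == (1.0, 1.0)


# ---------------------------------------------------------------------------
# argmax / harden plumbing
# ---------------------------------------------------------------------------


class TestArgmaxAndHarden:
    def test_clear_maximum(self, catalog):
        label, tie = argmax_with_tiebreak(
            {"mel": 1.67, "nv": 0.0, "bcc": 0.0, "bkl": 0.74}, catalog
        )
        assert (label, tie) == ("mel", False)

    def test_all_equal_breaks_to_first_catalog_class(self, catalog):
        label, tie = argmax_with_tiebreak({c: 1.0 for c in catalog}, catalog)
        assert (label, tie) == ("mel", True)

    def test_near_tie_within_tolerance_is_flagged(self, catalog):
        scores = {"mel": 0.5, "nv": 0.5 + 1e-15, "bcc": 0.0, "bkl": 0.0}
        label, tie = argmax_with_tiebreak(scores, catalog)
        assert (label, tie) == ("mel", True)

    def test_harden_one_hots_the_argmax(self, catalog):
        assert harden([0.7, 0.1, 0.1, 0.1], catalog).tolist() == [1, 0, 0, 0]

    def test_harden_is_idempotent(self, catalog):
        once = harden([0.2, 0.5, 0.2, 0.1], catalog)
        assert harden(once, catalog).tolist() == once.tolist()

    def test_harden_ties_break_to_first_class(self, catalog):
        assert harden([0.25, 0.25, 0.25, 0.25], catalog).tolist() == [1, 0, 0, 0]

    def test_empty_scores_rejected(self, catalog):
        with pytest.raises(StructuralError):
            harden([], catalog)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    rows=st.lists(
        st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4), min_size=3, max_size=3
    ),
    weights=st.lists(
        st.lists(st.floats(0.05, 1.0), min_size=4, max_size=4), min_size=3, max_size=3
    ),
)
def test_permutation_equivariance(rows, weights):
    """Permuting catalog order permutes fused scores identically.

    The set of maximal classes is unchanged; only tie resolution may
    differ, and these random draws are almost surely tie-free.
    """
    rows = np.array(rows)
    rows = rows / rows.sum(axis=1, keepdims=True)
    weights = np.array(weights)
    cat = ClassCatalog()
    perm = [2, 0, 3, 1]
    cat_p = ClassCatalog(tuple(cat.labels[i] for i in perm))
    res = fuse_model1(PredictionMatrix(cat, MODELS, rows), WeightMatrix(cat, MODELS, weights))
    res_p = fuse_model1(
        PredictionMatrix(cat_p, MODELS, rows[:, perm]),
        WeightMatrix(cat_p, MODELS, weights[:, perm]),
    )
    for c in cat:
        assert res_p.scores[c] == pytest.approx(res.scores[c], abs=1e-12)
    if not res.tie and not res_p.tie:
        assert res.predicted == res_p.predicted


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    masses=st.lists(st.floats(0.0, 1.0), min_size=18, max_size=18),
    w=st.lists(st.floats(0.0, 1.0), min_size=12, max_size=12),
)
def test_model2_linearity_over_models(masses, w):
    """fuse_model2 totals equal the sum of per-model branch-score vectors."""
    cat = ClassCatalog()
    pairs = cat.pairs()
    sets = []
    for m in range(3):
        decisions, weights = {}, {}
        for j, pair in enumerate(pairs):
            sa = masses[m * 6 + j]
            decisions[pair] = BinaryDecision(pair, sa, 1.0 - sa)
            weights[pair] = (w[m * 4 + j % 4], w[m * 4 + (j + 1) % 4])
        sets.append(branch_set_from_decisions(decisions, weights, cat, f"m{m}"))
    total = fuse_model2(sets).scores.as_array()
    summed = np.sum([score_network_binary(s).as_array() for s in sets], axis=0)
    assert total == pytest.approx(summed, abs=1e-12)


def test_score_vector_rejects_missing_or_negative_entries(catalog):
    with pytest.raises(StructuralError):
        ScoreVector(catalog, {"mel": 1.0})
    with pytest.raises(StructuralError):
        ScoreVector(catalog, {"mel": 1.0, "nv": -0.1, "bcc": 0.0, "bkl": 0.0})


def test_prediction_rows_must_sum_to_one(catalog):
    rows = np.array([[0.5, 0.2, 0.2, 0.2]] * 3)
    with pytest.raises(StructuralError):
        PredictionMatrix(catalog, MODELS, rows)


def test_weight_matrix_rejects_dead_class_column(catalog):
    w = np.ones((3, 4))
    w[:, 2] = 0.0
    with pytest.raises(StructuralError):
        WeightMatrix(catalog, MODELS, w)
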