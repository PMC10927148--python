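"""Fusion pipeline: validation, top-k penalties, FRS/CCFS/FDS, decisions."""

import numpy as np
import pytest

from rankfuse.fusion_core import (
    EnsembleScoreSet,
    complement_confidence_sum,
    decide,
    final_decision_score,
    fuse,
    fuzzy_rank_sum,
    ordinal_ranks,
    select_topk,
    validate_scores,
)
from rankfuse.rank_functions import mitscherlich_rank

from conftest import random_bank, scalar_fuse, scalar_rank


def make_set(scores, **kw):
    scores = np.asarray(scores, dtype=float)
    m, n, c = scores.shape
    return EnsembleScoreSet(
        scores=scores,
        sample_ids=kw.get("sample_ids", [f"s{j}" for j in range(n)]),
        class_labels=kw.get("class_labels", [f"c{j + 1}" for j in range(c)]),
    )


class TestValidateScores:
    def test_normalized_row_unchanged_strict(self):
        sset = make_set([[[0.2, 0.3, 0.5]]])
        out = validate_scores(sset, policy="strict")
        np.testing.assert_array_equal(out.scores, sset.scores)

    def test_renormalize_scales_rows(self):
        sset = make_set([[[2.0, 3.0, 5.0]]])
        out = validate_scores(sset, policy="renormalize")
        np.testing.assert_allclose(out.scores, [[[0.2, 0.3, 0.5]]])

    def test_strict_rejects_unnormalized(self):
        sset = make_set([[[2.0, 3.0, 5.0]]])
        with pytest.raises(ValueError, match="sums to"):
            validate_scores(sset, policy="strict")

    @pytest.mark.parametrize("policy", ["strict", "renormalize"])
    def test_zero_sum_row_error(self, policy):
        sset = make_set([[[0.0, 0.0, 0.0]]])
        with pytest.raises(ValueError, match="zero-sum"):
            validate_scores(sset, policy=policy)

    def test_negative_entry_error(self):
        sset = make_set([[[1.2, -0.1, -0.1]]])
        with pytest.raises(ValueError, match="negative"):
            validate_scores(sset)

    def test_misaligned_frames_rejected(self):
        import pandas as pd

        f1 = pd.DataFrame([[0.5, 0.5]], index=["a"], columns=["x", "y"])
        f2 = pd.DataFrame([[0.5, 0.5]], index=["a"], columns=["y", "x"])
        with pytest.raises(ValueError, match="class labels"):
            EnsembleScoreSet.from_dataframes([f1, f2])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            make_set(np.ones((1, 2, 1)))


class TestOrdinalRanksAndTopK:
    def test_sorted_ordinals(self):
        np.testing.assert_array_equal(
            ordinal_ranks(np.array([[0.37, 0.85, 0.93]])), [[1, 2, 3]]
        )

    def test_tie_broken_by_class_order(self):
        np.testing.assert_array_equal(
            ordinal_ranks(np.array([[0.93, 0.26, 0.93]])), [[2, 1, 3]]
        )

    def test_full_tie(self):
        np.testing.assert_array_equal(
            ordinal_ranks(np.array([[0.74, 0.74, 0.74]])), [[1, 2, 3]]
        )

    def test_topk_membership(self):
        sel = select_topk(np.array([[1, 2, 3]]), k=2)
        np.testing.assert_array_equal(sel.membership, [[True, True, False]])

    def test_k_equals_c_includes_all(self):
        sel = select_topk(np.array([[2, 1, 3]]), k=3)
        assert sel.membership.all()

    def test_k_one_is_argmax_confidence(self, rng):
        """With the decreasing transform, the top-1 class is the argmax class."""
        scores = rng.dirichlet(np.ones(4), size=(2, 30))
        from rankfuse.rank_functions import rank_transform

        ranks = np.stack([rank_transform(m) for m in scores])
        sel = select_topk(ordinal_ranks(ranks), k=1)
        np.testing.assert_array_equal(
            sel.membership.argmax(axis=-1), scores.argmax(axis=-1)
        )

    @pytest.mark.parametrize("k", [0, 4])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError, match="k must be"):
            select_topk(np.array([[1, 2, 3]]), k=k)


class TestAggregates:
    def test_frs_included_ranks(self):
        ranks = np.array([0.3755, 0.4843, 0.9282]).reshape(3, 1, 1)
        sel = select_topk(np.ones((3, 1, 1), dtype=int), k=1)
        assert fuzzy_rank_sum(ranks, sel)[0, 0] == pytest.approx(1.7880, abs=1e-4)

    def test_frs_fully_penalized_is_m(self):
        ranks = np.zeros((3, 1, 2))
        membership = np.zeros((3, 1, 2), dtype=bool)
        membership[..., 0] = True  # k=1, class 2 never included
        sel = select_topk(np.where(membership, 1, 2), k=1)
        assert fuzzy_rank_sum(ranks, sel)[0, 1] == 3.0

    def test_frs_single_model(self):
        ranks = np.array([[[0.42, 0.9]]])
        sel = select_topk(np.array([[[1, 2]]]), k=1)
        assert fuzzy_rank_sum(ranks, sel)[0, 0] == pytest.approx(0.42)

    def test_ccfs_variants(self):
        scores = np.array([0.7, 0.6, 0.1]).reshape(3, 1, 1)
        sel = select_topk(np.ones((3, 1, 1), dtype=int), k=1)
        comp = complement_confidence_sum(scores, sel, "complement")
        lit = complement_confidence_sum(scores, sel, "literal")
        assert comp[0, 0] == pytest.approx(1.0 - 1.4 / 3.0)
        assert lit[0, 0] == pytest.approx(1.4 / 3.0)

    def test_ccfs_absent_class_complement_is_one(self):
        scores = np.full((3, 1, 2), 0.5)
        membership = np.zeros((3, 1, 2), dtype=bool)
        membership[..., 0] = True
        sel = select_topk(np.where(membership, 1, 2), k=1)
        assert complement_confidence_sum(scores, sel)[0, 1] == 1.0

    def test_fds_product_and_decision(self):
        fds = final_decision_score(
            np.array([[1.7880, 1.8791, 3.0]]), np.array([[0.5333, 0.5667, 1.0]])
        )
        assert fds[0, 2] == 3.0
        idx, labels = decide(fds, ["c1", "c2", "c3"])
        assert labels[0] == "c1"

    def test_decide_tie_first_class(self):
        idx, labels = decide(np.array([[2.0, 2.0, 2.0]]), ["a", "b", "c"])
        assert labels[0] == "a"

    def test_fds_zero_frs(self):
        assert final_decision_score(np.array([[0.0]]), np.array([[0.7]]))[0, 0] == 0.0


class TestFuse:
    def test_worked_example(self, worked_bank):
        """Two of three models favour class 1; fused argmin-FDS picks it."""
        res = fuse(worked_bank, k=2)
        assert res.fused_label[0] == "c1"
        assert res.fds[0, 0] < res.fds[0, 1] < res.fds[0, 2]
        # class 3 misses every top-2 set: fully penalized
        assert res.frs[0, 2] == 3.0
        assert res.ccfs[0, 2] == 1.0
        assert res.fds[0, 2] == 3.0
        assert res.fds[0, 0] == pytest.approx(0.9536, abs=1e-4)
        assert res.fds[0, 1] == pytest.approx(1.0648, abs=1e-4)
        assert res.penalties == (1.0, 0.0)

    def test_unanimous_confident_models(self, rng):
        scores = np.tile(np.array([[0.05, 0.9, 0.05]]), (3, 8, 1))
        res = fuse(make_set(scores), k=2)
        assert (res.fused_label == "c2").all()

    def test_single_model_k_equals_c_is_argmax(self, rng):
        """FDS = R(x)(1-x) is strictly decreasing in x, so M=1, k=C
        reduces to that model's argmax-confidence decision."""
        bank = random_bank(rng, n=40, c=4, m=1)
        res = fuse(bank, k=4)
        np.testing.assert_array_equal(res.fused_index, bank.scores[0].argmax(axis=1))

    @pytest.mark.parametrize("variant", ["complement", "literal"])
    def test_oracle_equivalence(self, rng, variant):
        """Vectorized fuse matches the naive scalar transcription."""
        for _ in range(30):
            n = int(rng.integers(1, 51))
            c = int(rng.integers(2, 6))
            m = int(rng.integers(1, 5))
            k = int(rng.integers(1, c + 1))
            bank = random_bank(rng, n, c, m)
            res = fuse(bank, k=k, variant=variant)
            mats = [bank.scores[i].tolist() for i in range(m)]
            frs, ccfs, fds, fused = scalar_fuse(mats, k=k, variant=variant)
            np.testing.assert_allclose(res.frs, frs, atol=1e-12)
            np.testing.assert_allclose(res.ccfs, ccfs, atol=1e-12)
            np.testing.assert_allclose(res.fds, fds, atol=1e-12)
            np.testing.assert_array_equal(res.fused_index, fused)

    def test_classifier_order_invariance(self, rng):
        bank = random_bank(rng, n=25, c=4, m=3)
        res = fuse(bank, k=2)
        perm = [2, 0, 1]
        permuted = EnsembleScoreSet(
            scores=bank.scores[perm],
            sample_ids=bank.sample_ids,
            class_labels=bank.class_labels,
        )
        res_p = fuse(permuted, k=2)
        np.testing.assert_allclose(res.frs, res_p.frs, atol=1e-12)
        np.testing.assert_allclose(res.ccfs, res_p.ccfs, atol=1e-12)
        np.testing.assert_allclose(res.fds, res_p.fds, atol=1e-12)

    def test_class_relabel_equivariance(self, rng):
        bank = random_bank(rng, n=25, c=4, m=3)
        perm = np.array([3, 1, 0, 2])  # new column j holds old column perm[j]
        relabeled = EnsembleScoreSet(
            scores=bank.scores[:, :, perm],
            sample_ids=bank.sample_ids,
            class_labels=[bank.class_labels[j] for j in perm],
        )
        res = fuse(bank, k=2)
        res_p = fuse(relabeled, k=2)
        np.testing.assert_allclose(res.fds[:, perm], res_p.fds, atol=1e-12)
        np.testing.assert_array_equal(res.fused_label, res_p.fused_label)

    def test_bounds(self, rng):
        bank = random_bank(rng, n=50, c=5, m=4)
        res = fuse(bank, k=2)
        m = bank.n_models
        assert np.all((res.frs >= 0) & (res.frs <= m))
        assert np.all((res.ccfs >= 0) & (res.ccfs <= 1))
        assert np.all((res.fds >= 0) & (res.fds <= m))

    def test_unanimous_argmax_recovered(self, rng):
        """Across many random banks where every classifier shares one argmax
        class, the fused label always recovers it."""
        hits = trials = 0
        for _ in range(1000):
            c, m = 3, 3
            target = int(rng.integers(c))
            scores = rng.dirichlet(np.ones(c), size=(m, 1))
            # force a shared argmax by boosting the target column
            scores[:, :, target] += 1.0
            scores /= scores.sum(axis=-1, keepdims=True)
            res = fuse(make_set(scores), k=2)
            trials += 1
            hits += int(res.fused_index[0] == target)
        assert hits == trials

    def test_deterministic(self, rng):
        bank = random_bank(rng, n=20, c=3, m=3)
        a = fuse(bank, k=2)
        b = fuse(bank, k=2)
        np.testing.assert_array_equal(a.fds, b.fds)
        np.testing.assert_array_equal(a.fused_label, b.fused_label)

    def test_k_out_of_range(self, worked_bank):
        with pytest.raises(ValueError, match="k must be"):
            fuse(worked_bank, k=0)
        with pytest.raises(ValueError, match="k must be"):
            fuse(worked_bank, k=4)

    def test_predictions_frame(self, worked_bank):
        frame = fuse(worked_bank, k=2).to_frame()
        assert list(frame.columns) == ["sample_id", "fused_label", "fds_c1", "fds_c2", "fds_c3"]
        assert frame.loc[0, "fused_label"] == "c1"
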