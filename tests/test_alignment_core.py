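"""Alignment mathematics against closed forms and naive loop oracles.

The oracles re-derive every quantity with explicit Python loops (softmax by
hand, attention per word, Z per cross pair) and never call the vectorized
implementations they check.
"""

import numpy as np
import pytest

from glocalmm.alignment_core import (TemperatureSet, attention_over_regions,
                                     batched_local_nce, context_vectors,
                                     cosine_sim, global_nce_loss,
                                     local_match_score, local_nce_loss,
                                     pairwise_local_score, relevance_map,
                                     total_loss)
from glocalmm.nn import Tensor

RNG = np.random.default_rng(77)


def unit_columns(d, n, rng=RNG):
    x = rng.normal(size=(d, n))
    return x / np.linalg.norm(x, axis=0, keepdims=True)


def unit_rows(n, d, rng=RNG):
    return unit_columns(d, n, rng).T


# ---------------------------------------------------------------------------
# oracles

def oracle_global_nce(V, T, t1, direction):
    n = len(V)
    total = 0.0
    for i in range(n):
        num = np.exp(np.dot(V[i], T[i]) / t1)
        if direction == "v_given_t":
            den = sum(np.exp(np.dot(V[i], T[k]) / t1) for k in range(n))
        else:
            den = sum(np.exp(np.dot(V[k], T[i]) / t1) for k in range(n))
        total += -np.log(num / den)
    return total


def oracle_z(v_l, t_l, temps):
    """Z for one pair by explicit per-word attention loops."""
    D, M = v_l.shape
    _, W = t_l.shape
    word_sims = []
    for i in range(W):
        scores = [np.dot(v_l[:, j], t_l[:, i]) / temps.t2_attn for j in range(M)]
        e = np.exp(np.array(scores) - max(scores))
        a = e / e.sum()
        c = sum(a[j] * v_l[:, j] for j in range(M))
        word_sims.append(np.dot(c, t_l[:, i]))
    word_sims = np.array(word_sims) / temps.t3
    m = word_sims.max()
    return temps.t3 * (m + np.log(np.exp(word_sims - m).sum()))


def oracle_local_nce(pairs, temps, direction):
    n = len(pairs)
    Z = np.array([[oracle_z(pairs[i][0], pairs[k][1], temps) for k in range(n)]
                  for i in range(n)])
    total = 0.0
    for i in range(n):
        num = np.exp(Z[i, i] / temps.t2_local)
        if direction == "v_given_t":
            den = sum(np.exp(Z[i, k] / temps.t2_local) for k in range(n))
        else:
            den = sum(np.exp(Z[k, i] / temps.t2_local) for k in range(n))
        total += -np.log(num / den)
    return total


# ---------------------------------------------------------------------------

class TestCosine:
    def test_closed_forms(self):
        e1, e2 = np.eye(3)[0], np.eye(3)[1]
        assert cosine_sim(e1, e1) == pytest.approx(1.0)
        assert cosine_sim(e1, e2) == pytest.approx(0.0)
        assert cosine_sim([1, 1], [1, 0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            cosine_sim([0, 0], [1, 0])


class TestGlobalNCE:
    def test_single_pair_is_zero(self):
        V = unit_rows(1, 8)
        assert global_nce_loss(V, V, 0.07, "v_given_t") == pytest.approx(0.0)

    def test_identical_embeddings_give_2ln2(self):
        u = unit_rows(1, 8)[0]
        V = np.stack([u, u])
        for d in ("v_given_t", "t_given_v"):
            assert global_nce_loss(V, V, 0.07, d) == pytest.approx(2 * np.log(2))

    @pytest.mark.parametrize("direction", ["v_given_t", "t_given_v"])
    def test_matches_loop_oracle(self, direction):
        V, T = unit_rows(4, 8), unit_rows(4, 8)
        got = global_nce_loss(V, T, 0.07, direction)
        assert got == pytest.approx(oracle_global_nce(V, T, 0.07, direction),
                                    abs=1e-6)

    def test_direction_symmetry_under_modality_swap(self):
        V, T = unit_rows(5, 8), unit_rows(5, 8)
        assert global_nce_loss(V, T, 0.1, "v_given_t") == pytest.approx(
            global_nce_loss(T, V, 0.1, "t_given_v"))

    def test_permutation_invariance(self):
        V, T = unit_rows(6, 8), unit_rows(6, 8)
        perm = RNG.permutation(6)
        assert global_nce_loss(V, T, 0.07, "v_given_t") == pytest.approx(
            global_nce_loss(V[perm], T[perm], 0.07, "v_given_t"))

    def test_nonnegative_and_zero_in_one_hot_limit(self):
        # orthonormal embeddings: as t -> 0 the softmax is one-hot at the diagonal
        V = np.eye(4)
        assert global_nce_loss(V, V, 0.07, "v_given_t") >= 0
        assert global_nce_loss(V, V, 0.005, "v_given_t") == pytest.approx(0.0, abs=1e-6)

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            global_nce_loss(np.zeros((0, 4)), np.zeros((0, 4)), 0.07, "v_given_t")


class TestRelevanceAttentionContext:
    def test_orthonormal_identity_block(self):
        basis = np.eye(4)[:, :3]
        s = relevance_map(basis, basis)
        np.testing.assert_allclose(s.s, np.eye(3))

    def test_orthogonal_subspaces_zero(self):
        v = np.eye(6)[:, :2]
        t = np.eye(6)[:, 3:5]
        np.testing.assert_allclose(relevance_map(v, t).s, np.zeros((2, 2)))

    def test_matches_entrywise_loop(self):
        v, t = unit_columns(3, 4), unit_columns(3, 2)
        s = relevance_map(v, t).s
        for j in range(4):
            for i in range(2):
                assert s[j, i] == pytest.approx(np.dot(v[:, j], t[:, i]))

    def test_dim_mismatch_raises(self):
        with pytest.raises(ValueError):
            relevance_map(np.zeros((3, 2)), np.zeros((4, 2)))

    def test_attention_rows_sum_to_one_and_uniform_case(self):
        s = np.zeros((5, 2))       # constant scores per word
        a = attention_over_regions(s, 0.07).a
        np.testing.assert_allclose(a, np.full((2, 5), 0.2))

    def test_hand_softmax_two_regions(self):
        t2 = 0.3
        s = np.array([[0.0], [t2 * np.log(2)]])     # M=2, W=1
        a = attention_over_regions(s, t2).a
        np.testing.assert_allclose(a[0], [1 / 3, 2 / 3], atol=1e-12)

    def test_low_temperature_one_hot_limit(self):
        s = RNG.normal(size=(6, 3))
        a = attention_over_regions(s, 1e-4).a
        np.testing.assert_allclose(a.max(axis=1), 1.0, atol=1e-8)
        assert (a.argmax(axis=1) == s.T.argmax(axis=1)).all()

    def test_context_selection_and_mean(self):
        v = unit_columns(4, 3)
        one_hot = np.array([[0.0, 1.0, 0.0]])
        np.testing.assert_allclose(context_vectors(one_hot, v).c[:, 0], v[:, 1])
        uniform = np.full((1, 3), 1 / 3)
        np.testing.assert_allclose(context_vectors(uniform, v).c[:, 0],
                                   v.mean(axis=1))

    def test_context_in_convex_hull_norm_bound(self):
        v = unit_columns(4, 5)
        a = attention_over_regions(RNG.normal(size=(5, 3)), 0.07)
        c = context_vectors(a, v).c
        assert (np.linalg.norm(c, axis=0) <= 1 + 1e-9).all()


class TestLocalMatchScore:
    def test_single_word_reduces_to_similarity(self):
        v, t = unit_columns(6, 4), unit_columns(6, 1)
        a = attention_over_regions(relevance_map(v, t), 0.07)
        c = context_vectors(a, v)
        z = local_match_score(c, t, 0.07)
        assert z == pytest.approx(float(c.c[:, 0] @ t[:, 0]))

    def test_constant_similarities_closed_form(self):
        t3, W, val = 0.2, 5, 0.4
        c = np.tile([[val], [0.0]], (1, W))
        t = np.tile([[1.0], [0.0]], (1, W))
        assert local_match_score(c, t, t3) == pytest.approx(val + t3 * np.log(W))

    def test_low_temperature_smooth_max_limit(self):
        sims = np.array([0.1, 0.7, 0.3])
        c = np.stack([sims, np.zeros(3)])
        t = np.stack([np.ones(3), np.zeros(3)])
        assert local_match_score(c, t, 1e-5) == pytest.approx(0.7, abs=1e-4)

    def test_zero_words_raises(self):
        with pytest.raises(ValueError):
            local_match_score(np.zeros((3, 0)), np.zeros((3, 0)), 0.07)


class TestLocalNCE:
    def make_pairs(self, n, d=8, m=4, w=2, rng=RNG):
        return [(unit_columns(d, m, rng), unit_columns(d, w, rng))
                for _ in range(n)]

    def test_single_pair_zero(self):
        pairs = self.make_pairs(1)
        temps = TemperatureSet()
        assert local_nce_loss(pairs, temps, "v_given_t") == pytest.approx(0.0)

    def test_exchangeable_pairs_equal_directions(self):
        v, t = unit_columns(8, 4), unit_columns(8, 2)
        pairs = [(v, t), (v.copy(), t.copy())]
        temps = TemperatureSet()
        assert local_nce_loss(pairs, temps, "v_given_t") == pytest.approx(
            local_nce_loss(pairs, temps, "t_given_v"))

    @pytest.mark.parametrize("direction", ["v_given_t", "t_given_v"])
    @pytest.mark.parametrize("n", [2, 3, 8])
    def test_matches_bruteforce_oracle(self, direction, n):
        pairs = self.make_pairs(n)
        temps = TemperatureSet(t2_attn=0.2, t2_local=0.09, t3=0.15)
        got = local_nce_loss(pairs, temps, direction)
        assert got == pytest.approx(oracle_local_nce(pairs, temps, direction),
                                    abs=1e-6)

    def test_variable_word_counts_masked_correctly(self):
        rng = np.random.default_rng(5)
        pairs = [(unit_columns(8, 4, rng), unit_columns(8, w, rng))
                 for w in (1, 3, 2)]
        temps = TemperatureSet()
        for d in ("v_given_t", "t_given_v"):
            assert local_nce_loss(pairs, temps, d) == pytest.approx(
                oracle_local_nce(pairs, temps, d), abs=1e-6)

    def test_pairwise_score_matches_oracle_z(self):
        v, t = unit_columns(8, 5), unit_columns(8, 3)
        temps = TemperatureSet(t2_attn=0.11, t3=0.21)
        assert pairwise_local_score(v, t, temps) == pytest.approx(
            oracle_z(v, t, temps), abs=1e-9)

    def test_permutation_invariance(self):
        pairs = self.make_pairs(5)
        temps = TemperatureSet()
        perm = [3, 1, 4, 0, 2]
        shuffled = [pairs[i] for i in perm]
        assert local_nce_loss(pairs, temps, "v_given_t") == pytest.approx(
            local_nce_loss(shuffled, temps, "v_given_t"))


class TestTotalLoss:
    def test_isolation_of_global_terms(self):
        b = total_loss(1.0, 2.0, 3.0, 4.0, 5.0, lambda2=0.0, lambda3=0.0)
        assert b.total == pytest.approx(3.0)

    def test_unit_weights_sum_of_alignment_terms(self):
        b = total_loss(1.0, 2.0, 3.0, 4.0, 0.0)
        assert b.total == pytest.approx(10.0)

    def test_weight_linearity(self):
        b1 = total_loss(1.0, 2.0, 0.5, 0.5, 0.0, lambda1=1.0)
        b2 = total_loss(1.0, 2.0, 0.5, 0.5, 0.0, lambda1=2.0)
        assert b2.total - b1.total == pytest.approx(3.0)

    def test_breakdown_identity_invariant(self):
        b = total_loss(0.3, 0.4, 0.1, 0.2, 0.6, lambda1=0.5, lambda2=1.5,
                       lambda3=2.0)
        expect = 0.5 * 0.7 + 1.5 * 0.3 + 2.0 * 0.6
        assert b.total == pytest.approx(expect, abs=1e-9)

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            total_loss(np.nan, 0, 0, 0)


class TestGradients:
    """Finite-difference sanity of every loss with respect to embeddings."""

    @staticmethod
    def fd_check(fn, x, rel_tol=1e-3):
        t = Tensor(x.copy(), requires_grad=True)
        out = fn(t)
        out.backward()
        analytic = t.grad.copy()
        num = np.zeros_like(x)
        eps = 1e-6
        flat_x = x.ravel()
        flat_n = num.ravel()
        for i in range(flat_x.size):
            orig = flat_x[i]
            flat_x[i] = orig + eps
            fp = fn(Tensor(x)).item()
            flat_x[i] = orig - eps
            fm = fn(Tensor(x)).item()
            flat_x[i] = orig
            flat_n[i] = (fp - fm) / (2 * eps)
        denom = max(np.linalg.norm(num), 1e-12)
        assert np.linalg.norm(analytic - num) / denom < rel_tol

    def test_global_loss_gradient(self):
        V = unit_rows(3, 5)
        T = unit_rows(3, 5)
        for d in ("v_given_t", "t_given_v"):
            self.fd_check(lambda t: global_nce_loss(t, Tensor(T), 0.07, d), V.copy())
            self.fd_check(lambda t: global_nce_loss(Tensor(V), t, 0.07, d), T.copy())

    def test_local_loss_gradient(self):
        temps = TemperatureSet()
        B, M, W, D = 3, 4, 2, 8
        v = np.stack([unit_columns(D, M).T for _ in range(B)])
        t = np.stack([unit_columns(D, W).T for _ in range(B)])
        mask = np.ones((B, W))
        for d in ("v_given_t", "t_given_v"):
            self.fd_check(lambda vt: batched_local_nce(vt, Tensor(t), mask,
                                                       temps, d), v.copy())
            self.fd_check(lambda tt: batched_local_nce(Tensor(v), tt, mask,
                                                       temps, d), t.copy())
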