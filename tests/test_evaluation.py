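"""Metrics: Precision@K, AUROC, confusion table, Dice, zero-shot scoring,
attention overlays."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glocalmm.evaluation import (attention_overlay, auroc, confusion_metrics,
                                 dice_coefficient, precision_at_k,
                                 zero_shot_classify)


class TestPrecisionAtK:
    def test_all_relevant_gives_one(self):
        sim = np.random.default_rng(0).random((4, 6))
        rel = np.ones((4, 6), dtype=int)
        for k in (1, 3, 6):
            assert precision_at_k(sim, rel, k) == 1.0

    def test_single_relevant_ranked_first(self):
        sim = np.array([[0.9, 0.5, 0.4, 0.3, 0.2]])
        rel = np.array([[1, 0, 0, 0, 0]])
        assert precision_at_k(sim, rel, 5) == pytest.approx(0.2)
        assert precision_at_k(sim, rel, 1) == pytest.approx(1.0)

    def test_random_scores_approach_relevance_fraction(self):
        rng = np.random.default_rng(1)
        Q, C, rho = 400, 50, 0.3
        sim = rng.random((Q, C))
        rel = (rng.random((Q, C)) < rho).astype(int)
        rel[np.arange(Q), rng.integers(0, C, Q)] = 1  # ensure >=1 relevant
        p = precision_at_k(sim, rel, 10)
        # binomial bound around the adjusted relevance fraction
        rho_eff = rel.mean()
        assert abs(p - rho_eff) < 4 * np.sqrt(rho_eff * (1 - rho_eff) / (Q * 10))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        sim = rng.random((5, 8))
        rel = (rng.random((5, 8)) < 0.4).astype(int)
        rel[:, 0] = 1
        for k in (1, 4, 8):
            assert precision_at_k(sim, rel, k) == precision_at_k(
                np.exp(3 * sim), rel, k)

    def test_tie_break_by_candidate_index(self):
        sim = np.array([[0.5, 0.5, 0.5]])
        rel = np.array([[0, 1, 0]])
        # ties resolve to candidate 0 first
        assert precision_at_k(sim, rel, 1) == 0.0
        assert precision_at_k(sim, rel, 2) == pytest.approx(0.5)

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            precision_at_k(np.ones((2, 3)), np.ones((2, 3)), 4)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_hand_counted_case(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 2**31 - 1), st.integers(21, 60))
    @settings(max_examples=30, deadline=None)
    def test_rank_path_matches_pair_counting(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.2, 0.3, 0.4], size=n)  # force ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            return
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        expect = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert auroc(scores, labels) == pytest.approx(expect, abs=1e-12)

    def test_matches_sklearn_on_random_inputs(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = confusion_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert all(v == 1.0 for v in m.values())

    def test_hand_2x2_arithmetic(self):
        # TP=3 FP=1 FN=1 TN=5
        y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        p = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        m = confusion_metrics(p, y)
        assert m["Sens"] == pytest.approx(0.75)
        assert m["PPV"] == pytest.approx(0.75)
        assert m["F1"] == pytest.approx(0.75)
        assert m["Acc"] == pytest.approx(0.8)

    def test_all_positive_predictor(self):
        m = confusion_metrics([1, 1, 1, 1], [0, 1, 0, 1])
        assert m["Spec"] == 0.0 and m["Sens"] == 1.0
        assert m["NPV"] is None       # zero denominator -> missing, not 0


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.array([[1, 1], [0, 0]])
        b = np.array([[0, 0], [1, 1]])
        assert dice_coefficient(a, a, 1) == 1.0
        assert dice_coefficient(a, b, 1) == 0.0

    def test_half_overlap(self):
        a = np.zeros((20, 10), dtype=int)
        b = np.zeros((20, 10), dtype=int)
        a[:10] = 1          # |A| = 100
        b[5:15] = 1         # |B| = 100, overlap 50
        assert dice_coefficient(a, b, 1) == pytest.approx(0.5)

    def test_empty_empty_convention(self):
        z = np.zeros((4, 4), dtype=int)
        assert dice_coefficient(z, z, 3) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, (8, 8))
        b = rng.integers(0, 3, (8, 8))
        for c in range(3):
            assert dice_coefficient(a, b, c) == dice_coefficient(b, a, c)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2)), np.zeros((3, 3)), 0)


class TestZeroShot:
    def test_matching_class_embedding_wins(self):
        e1, e2 = np.eye(4)[0], np.eye(4)[1]
        prompts = {"A": ["a"], "B": ["b"]}
        enc = lambda p: e1 if p == "a" else e2
        out = zero_shot_classify(e1, prompts, enc)
        assert out["predicted"][0] == "A"
        assert out["cosine"][0, 0] == pytest.approx(1.0)
        assert out["cosine"][0, 1] == pytest.approx(0.0)

    def test_duplicate_prompts_idempotent(self):
        rng = np.random.default_rng(5)
        e = rng.normal(size=8)
        enc = lambda p: e
        one = zero_shot_classify(e, {"A": ["x"], "B": ["y"]}, lambda p: e if p == "x" else -e)
        two = zero_shot_classify(e, {"A": ["x", "x"], "B": ["y"]},
                                 lambda p: e if p == "x" else -e)
        np.testing.assert_allclose(one["cosine"], two["cosine"], atol=1e-12)

    def test_empty_prompt_set_raises(self):
        with pytest.raises(ValueError):
            zero_shot_classify(np.ones(4), {"A": [], "B": ["b"]}, lambda p: np.ones(4))


class TestAttentionOverlay:
    @pytest.fixture(scope="class")
    def setup(self):
        from glocalmm.encoders import AlignmentModel, EncoderSpec
        from glocalmm.phantom_forge import PhantomSpec, make_phantom
        from glocalmm.text_processing import build_vocabulary

        sample = make_phantom(PhantomSpec(
            disc_gap_fraction=(1.0, 1.0, 1.0, 1.0),
            instrumented_levels=frozenset({2})))
        vocab = build_vocabulary([sample.report])
        model = AlignmentModel(EncoderSpec.tiny(), len(vocab), seed=2)
        return sample, vocab, model

    def test_word_absent_raises(self, setup):
        sample, vocab, model = setup
        with pytest.raises(ValueError):
            attention_overlay(sample, "laminectomy", model, vocab)

    def test_heatmap_normalized_and_shaped(self, setup):
        sample, vocab, model = setup
        ov = attention_overlay(sample, "screw", model, vocab)
        assert ov.heatmap.shape == sample.image.shape
        assert ov.heatmap.max() == pytest.approx(1.0)
        assert ov.localization_score >= 0

    def test_uniform_attention_scores_one(self, setup):
        """Enrichment is 1.0 when attention mass is spread uniformly."""
        sample, vocab, model = setup
        ov = attention_overlay(sample, "screw", model, vocab)
        H, W = sample.image.shape
        region = sample.concept_regions["screw"]
        uniform = np.full((H, W), 1.0 / (H * W))
        inside = sum(uniform[r, c] for r, c in region)
        score = inside / (len(region) / (H * W))
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_concentrated_attention_enrichment(self, setup):
        """All mass inside a quarter-area region gives enrichment 4."""
        H = W = 8
        heat = np.zeros((H, W))
        heat[:4, :4] = 1.0
        heat /= heat.sum()
        region = {(r, c) for r in range(4) for c in range(4)}
        inside = sum(heat[r, c] for r, c in region)
        assert inside / (len(region) / (H * W)) == pytest.approx(4.0)

    def test_grid_mass_conserved_by_upsampling(self, setup):
        from glocalmm.nn.functional import resize_bilinear
        rng = np.random.default_rng(6)
        a = rng.random((8, 8))
        a /= a.sum()
        up = resize_bilinear(a, 64, 64)
        # row-stochastic interpolation preserves total mass up to area scaling
        assert up.sum() * (8 * 8) / (64 * 64) == pytest.approx(1.0, abs=1e-3)
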