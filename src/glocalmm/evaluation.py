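"""Task metrics and interpretability outputs.

Cross-modal retrieval Precision@K, AUROC (Mann-Whitney), zero-shot
classification by prompt-embedding similarity, confusion metrics, hard
Dice, and word-attention overlays with an enrichment-based localization
score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alignment_core import TemperatureSet, attention_over_regions, relevance_map
from .nn import Tensor
from .nn.functional import resize_bilinear

__all__ = ["RetrievalResult", "AttentionOverlay", "precision_at_k",
           "retrieval_evaluation", "auroc", "zero_shot_classify",
           "confusion_metrics", "dice_coefficient", "attention_overlay"]


@dataclass
class RetrievalResult:
    similarity: np.ndarray          # (Q, C)
    relevance: np.ndarray           # (Q, C) binary
    precision_at_k: dict[int, float]


@dataclass
class AttentionOverlay:
    word: str
    heatmap: np.ndarray             # (H, W), max-normalized
    localization_score: float


def precision_at_k(sim: np.ndarray, relevance: np.ndarray, k: int) -> float:
    """Mean over queries of the fraction of relevant candidates in the top k.

    Candidates are ranked by similarity descending with ties broken by
    candidate index (deterministic).
    """
    sim = np.asarray(sim, dtype=float)
    rel = np.asarray(relevance)
    if sim.shape != rel.shape:
        raise ValueError("similarity and relevance shapes differ")
    Q, C = sim.shape
    if k > C:
        raise ValueError(f"k={k} exceeds {C} candidates")
    if not rel.any(axis=1).all():
        raise ValueError("every query needs at least one relevant candidate")
    # stable sort on index after primary sort on -sim
    order = np.lexsort((np.arange(C)[None, :].repeat(Q, 0), -sim), axis=1)
    topk = np.take_along_axis(rel, order[:, :k], axis=1)
    return float(topk.mean())


def retrieval_evaluation(sim: np.ndarray, relevance: np.ndarray,
                         ks: tuple[int, ...] = (1, 5, 10)) -> RetrievalResult:
    pk = {k: precision_at_k(sim, relevance, k) for k in ks
          if k <= sim.shape[1]}
    return RetrievalResult(similarity=sim, relevance=np.asarray(relevance),
                           precision_at_k=pk)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + 0.5 P(tie).

    Exact pair counting below 20 points, midrank statistics otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUROC needs both classes present")
    if len(scores) <= 20:
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        return float((wins + 0.5 * ties) / (len(pos) * len(neg)))
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def confusion_metrics(predictions: np.ndarray, labels: np.ndarray
                      ) -> dict[str, float | None]:
    """Acc / Sens / Spec / PPV / NPV / F1 from the 2x2 table.

    Ratios with a zero denominator are reported as None (missing), not 0.
    """
    p = np.asarray(predictions).astype(int)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1} or set(np.unique(p)) - {0, 1}:
        raise ValueError("binary labels/predictions expected")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in labels")
    tp = int(((p == 1) & (y == 1)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())

    def ratio(num, den):
        return num / den if den > 0 else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f1 = (2 * ppv * sens / (ppv + sens)
          if ppv is not None and sens is not None and (ppv + sens) > 0 else None)
    return {"Acc": (tp + tn) / len(y), "Sens": sens, "Spec": spec,
            "PPV": ppv, "NPV": npv, "F1": f1}


def dice_coefficient(pred_mask: np.ndarray, true_mask: np.ndarray,
                     c: int) -> float:
    """Hard Dice 2|A∩B|/(|A|+|B|) for class ``c``; empty vs empty -> 1."""
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError("mask shapes differ")
    a = pred_mask == c
    b = true_mask == c
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def zero_shot_classify(v_g: np.ndarray, class_prompts: dict[str, list[str]],
                       encode_prompt) -> dict[str, np.ndarray]:
    """Score images against prompt-set class embeddings.

    v_g: (B, D) unit-norm image embeddings.  ``encode_prompt(text) -> (D,)``
    is the text pipeline of an aligned checkpoint.  Each class's prompt
    embeddings are averaged then renormalized; scores are cosine
    similarities, with a softmax over classes for calibrated output.
    """
    names = list(class_prompts)
    if len(names) < 2:
        raise ValueError("need at least two classes")
    embs = []
    for name in names:
        prompts = class_prompts[name]
        if not prompts:
            raise ValueError(f"empty prompt set for class {name!r}")
        e = np.mean([np.asarray(encode_prompt(p), dtype=float) for p in prompts],
                    axis=0)
        norm = np.linalg.norm(e)
        if norm < 1e-12:
            raise ValueError(f"degenerate prompt embedding for class {name!r}")
        embs.append(e / norm)
    class_mat = np.stack(embs)                     # (K, D)
    v = np.atleast_2d(np.asarray(v_g, dtype=float))
    cosine = v @ class_mat.T                       # (B, K)
    e = np.exp(cosine - cosine.max(axis=1, keepdims=True))
    softmax = e / e.sum(axis=1, keepdims=True)
    pred = np.array([names[i] for i in np.argmax(cosine, axis=1)])
    return {"classes": names, "cosine": cosine, "softmax": softmax,
            "predicted": pred}


def attention_overlay(sample, word: str, model, vocab,
                      temps: TemperatureSet | None = None) -> AttentionOverlay:
    """Word-attention heatmap at image resolution plus localization score.

    The word's attention row over the region grid is bilinearly upsampled
    to H x W and max-normalized.  ``localization_score`` is the attention
    mass falling inside the word's ground-truth pixel support divided by
    that region's area fraction, i.e. enrichment over a uniform-attention
    baseline (1.0 = no better than uniform).
    """
    from .training import prepare_text

    temps = temps or TemperatureSet()
    batch = prepare_text([sample.report], vocab)
    tok = batch.toks[0]
    if word not in tok.words:
        raise ValueError(f"word {word!r} not present in the report")
    w_idx = tok.words.index(word)

    v_g, v_l, grid = model.embed_images(Tensor(sample.image[None, None]))
    t_g, t_l = model.embed_texts(batch.token_ids, batch.pad_mask,
                                 batch.agg, batch.word_mask)
    s = relevance_map(v_l.data[0].T, t_l.data[0].T)       # (M, W)
    a = attention_over_regions(s, temps.t2_attn)
    row = a.a[w_idx]                                       # (M,)
    h, w = grid
    H, W = sample.image.shape
    heat = resize_bilinear(row.reshape(h, w), H, W)
    heat = np.clip(heat, 0.0, None)
    mass = heat.sum()
    if mass > 0:
        heat_norm = heat / mass
    else:
        heat_norm = heat
    region = sample.concept_regions.get(word, set())
    if region:
        inside = sum(heat_norm[r, c] for r, c in region)
        area_frac = len(region) / (H * W)
        score = float(inside / area_frac)
    else:
        score = 0.0
    peak = heat.max()
    return AttentionOverlay(word=word, heatmap=heat / peak if peak > 0 else heat,
                            localization_score=score)
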