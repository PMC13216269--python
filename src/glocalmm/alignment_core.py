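"""Global-local contrastive alignment mathematics.

Implements the bidirectional global InfoNCE objective, the region-word
relevance map, text-guided attention over image regions, attention-weighted
context vectors, the log-sum-exp local match score Z, the bidirectional
local InfoNCE objective, and the weighted total loss.

All functions accept plain numpy arrays (returning floats / arrays) or
autodiff tensors (returning tensors, so gradients flow to the embeddings).
The batched tensor paths used in training are verified against naive
double-loop oracles in the test suite.

Conventions: the relevance map ``s`` is M x W (region j, word i); attention
``a`` is W x M with rows summing to 1; embeddings carry unit-norm columns
so plain inner products are cosine similarities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, astensor, functional as F

__all__ = [
    "TemperatureSet", "RelevanceMap", "AttentionWeights", "ContextVectors",
    "LossBreakdown", "cosine_sim", "global_nce_loss", "relevance_map",
    "attention_over_regions", "context_vectors", "local_match_score",
    "local_nce_loss", "total_loss", "batched_local_nce",
]


@dataclass(frozen=True)
class TemperatureSet:
    """Softmax temperatures; the published setting fixes all at 0.07."""

    t1: float = 0.07          # global InfoNCE
    t2_attn: float = 0.07     # attention over regions
    t2_local: float = 0.07    # local InfoNCE outer scale
    t3: float = 0.07          # log-sum-exp aggregation of word similarities
    #: normalize the word aggregation by the word count (smooth mean rather
    #: than smooth sum), removing the t3*log(W) bias between reports of
    #: different lengths
    mean_words: bool = False

    def __post_init__(self):
        if min(self.t1, self.t2_attn, self.t2_local, self.t3) <= 0:
            raise ValueError("all temperatures must be strictly positive")


@dataclass
class RelevanceMap:
    s: np.ndarray             # (M, W)


@dataclass
class AttentionWeights:
    a: np.ndarray             # (W, M), rows sum to 1


@dataclass
class ContextVectors:
    c: np.ndarray             # (D, W)


@dataclass
class LossBreakdown:
    L_g_v_given_t: float
    L_g_t_given_v: float
    L_l_v_given_t: float
    L_l_t_given_v: float
    L_seg: float
    lambda1: float
    lambda2: float
    lambda3: float
    total: float


def _maybe_item(x: Tensor, tensor_in: bool):
    return x if tensor_in else x.item()


def cosine_sim(u, v) -> float:
    """Cosine similarity of two vectors, in [-1, 1]."""
    tensor_in = isinstance(u, Tensor) or isinstance(v, Tensor)
    u, v = astensor(u), astensor(v)
    nu = np.linalg.norm(u.data)
    nv = np.linalg.norm(v.data)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("cosine similarity of a zero vector is undefined")
    out = (F.l2_normalize(u, axis=-1) * F.l2_normalize(v, axis=-1)).sum()
    return _maybe_item(out, tensor_in)


def _check_direction(direction: str) -> None:
    if direction not in ("v_given_t", "t_given_v"):
        raise ValueError("direction must be 'v_given_t' or 't_given_v'")


def global_nce_loss(V, T, t1: float, direction: str):
    """Bidirectional global InfoNCE, summed over the batch.

    V, T: (N, D) with matched rows as positive pairs.  ``v_given_t``
    keeps the image index fixed and varies the text index in the
    denominator; ``t_given_v`` varies the image index.  Rows are
    normalized so inner products are cosine similarities.
    """
    _check_direction(direction)
    if t1 <= 0:
        raise ValueError("temperature must be positive")
    tensor_in = isinstance(V, Tensor) or isinstance(T, Tensor)
    V, T = astensor(V), astensor(T)
    if V.shape[0] == 0:
        raise ValueError("empty batch")
    if not (np.isfinite(V.data).all() and np.isfinite(T.data).all()):
        raise ValueError("non-finite embeddings")
    Vn = F.l2_normalize(V, axis=-1)
    Tn = F.l2_normalize(T, axis=-1)
    sim = (Vn @ Tn.T) / t1                       # (N, N), rows=image, cols=text
    axis = 1 if direction == "v_given_t" else 0
    logp = F.log_softmax(sim, axis=axis)
    n = V.shape[0]
    diag = logp[np.arange(n), np.arange(n)]
    return _maybe_item(-diag.sum(), tensor_in)


def relevance_map(v_l, t_l) -> RelevanceMap:
    """s = v_l^T t_l: similarity of every region with every word (M x W)."""
    v_l, t_l = np.asarray(v_l, dtype=float), np.asarray(t_l, dtype=float)
    if v_l.shape[0] != t_l.shape[0]:
        raise ValueError(f"embedding dim mismatch: {v_l.shape[0]} vs {t_l.shape[0]}")
    return RelevanceMap(s=v_l.T @ t_l)


def attention_over_regions(s: RelevanceMap | np.ndarray, t2_attn: float
                           ) -> AttentionWeights:
    """Word-wise softmax over regions: a[i, j] = softmax_j(s[j, i] / t2)."""
    if t2_attn <= 0:
        raise ValueError("temperature must be positive")
    s_arr = s.s if isinstance(s, RelevanceMap) else np.asarray(s, dtype=float)
    logits = s_arr.T / t2_attn                   # (W, M)
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return AttentionWeights(a=e / e.sum(axis=1, keepdims=True))


def context_vectors(a: AttentionWeights | np.ndarray, v_l) -> ContextVectors:
    """c_i = sum_j a[i, j] * v_l[:, j]: attended visual context per word."""
    a_arr = a.a if isinstance(a, AttentionWeights) else np.asarray(a, dtype=float)
    v_l = np.asarray(v_l, dtype=float)
    if a_arr.shape[1] != v_l.shape[1]:
        raise ValueError(f"region count mismatch: {a_arr.shape[1]} vs {v_l.shape[1]}")
    return ContextVectors(c=v_l @ a_arr.T)


def local_match_score(c: ContextVectors | np.ndarray, t_l, t3: float) -> float:
    """Z = t3 * log sum_i exp(<c_i, t_i> / t3): smooth-max over word matches."""
    if t3 <= 0:
        raise ValueError("temperature must be positive")
    c_arr = c.c if isinstance(c, ContextVectors) else np.asarray(c, dtype=float)
    t_arr = np.asarray(t_l, dtype=float)
    if c_arr.shape[1] == 0:
        raise ValueError("no words to aggregate (W = 0)")
    sims = np.einsum("dw,dw->w", c_arr, t_arr) / t3
    m = sims.max()
    return float(t3 * (m + np.log(np.exp(sims - m).sum())))


def pairwise_local_score(v_l, t_l, temps: TemperatureSet) -> float:
    """Z for one (image, text) pair: attention, context, then smooth-max."""
    s = relevance_map(v_l, t_l)
    a = attention_over_regions(s, temps.t2_attn)
    c = context_vectors(a, v_l)
    return local_match_score(c, t_l, temps.t3)


def batched_local_nce(v_l: Tensor, t_l: Tensor, word_mask: np.ndarray,
                      temps: TemperatureSet, direction: str) -> Tensor:
    """Vectorized local InfoNCE over a batch, differentiable.

    v_l: (B, M, D) unit rows; t_l: (B, W, D) unit rows with zero padding
    rows; word_mask: (B, W) with 1 at real words.  Attention is recomputed
    for every (image, text) cross pair.  Returns the summed loss.
    """
    _check_direction(direction)
    B = v_l.shape[0]
    Z = _batched_scores(v_l, t_l, word_mask, temps) / temps.t2_local  # (Bv, Bt)
    axis = 1 if direction == "v_given_t" else 0
    logp = F.log_softmax(Z, axis=axis)
    return -logp[np.arange(B), np.arange(B)].sum()


def _batched_scores(v_l: Tensor, t_l: Tensor, word_mask: np.ndarray,
                    temps: TemperatureSet) -> Tensor:
    """Z(x_vi, x_tk) for all cross pairs: (Bv, Bt)."""
    v_l, t_l = astensor(v_l), astensor(t_l)
    Bv, M, D = v_l.shape
    Bt, W, _ = t_l.shape
    vT = v_l.swapaxes(1, 2).reshape(Bv, 1, D, M)
    tw = t_l.reshape(1, Bt, W, D)
    s = tw @ vT                                   # (Bv, Bt, W, M)
    a = F.softmax(s / temps.t2_attn, axis=-1)
    c = a @ v_l.reshape(Bv, 1, M, D)              # (Bv, Bt, W, D)
    sims = (c * tw).sum(axis=-1)                  # (Bv, Bt, W)
    bias = np.where(word_mask > 0, 0.0, -1e9)
    if temps.mean_words:
        counts = np.maximum(word_mask.sum(axis=1, keepdims=True), 1.0)
        bias = bias - np.log(counts) * (word_mask > 0)
    return F.logsumexp(sims / temps.t3 + Tensor(bias[None]), axis=-1) * temps.t3


def local_nce_loss(pairs: list[tuple[np.ndarray, np.ndarray]],
                   temps: TemperatureSet, direction: str) -> float:
    """Local InfoNCE over a list of (v_l (D, M), t_l (D, W_i)) pairs.

    Convenience single-sample surface over :func:`batched_local_nce`;
    word counts may differ across pairs (padded and masked internally).
    """
    _check_direction(direction)
    if not pairs:
        raise ValueError("empty batch")
    B = len(pairs)
    D = np.asarray(pairs[0][0]).shape[0]
    M = np.asarray(pairs[0][0]).shape[1]
    Wmax = max(np.asarray(t).shape[1] for _, t in pairs)
    v = np.zeros((B, M, D))
    t = np.zeros((B, Wmax, D))
    mask = np.zeros((B, Wmax))
    for b, (v_b, t_b) in enumerate(pairs):
        v_b, t_b = np.asarray(v_b, dtype=float), np.asarray(t_b, dtype=float)
        v[b] = v_b.T
        t[b, :t_b.shape[1]] = t_b.T
        mask[b, :t_b.shape[1]] = 1.0
    return batched_local_nce(Tensor(v), Tensor(t), mask, temps, direction).item()


def total_loss(L_g_v_given_t, L_g_t_given_v, L_l_v_given_t, L_l_t_given_v,
               L_seg=0.0, lambda1: float = 1.0, lambda2: float = 1.0,
               lambda3: float = 1.0) -> LossBreakdown:
    """Weighted combination of global, local and segmentation losses.

    With ``L_seg = 0`` and unit weights this is exactly the sum of the four
    bidirectional alignment terms.
    """
    def val(x):
        return float(x.item() if isinstance(x, Tensor) else x)

    parts = [val(L_g_v_given_t), val(L_g_t_given_v),
             val(L_l_v_given_t), val(L_l_t_given_v), val(L_seg)]
    if not all(np.isfinite(parts)):
        raise ValueError("loss parts must be finite")
    total = (lambda1 * (parts[0] + parts[1])
             + lambda2 * (parts[2] + parts[3])
             + lambda3 * parts[4])
    return LossBreakdown(*parts, lambda1=lambda1, lambda2=lambda2,
                         lambda3=lambda3, total=total)
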