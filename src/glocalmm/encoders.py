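"""Visual and text encoders plus the shared-space projection heads.

The visual encoder is a small strided convolutional network whose final
feature map provides the local region features ``f_l`` (one column per
spatial cell, row-major) and, via global average pooling, the global
feature ``f_g``.  The text encoder maps subword tokens to contextual
embeddings; its output at the CLS position is the global text feature
``g_g`` and the token outputs form ``g_l``.  Two text architectures sit
behind the same interface: a convolutional n-gram encoder (the trainable
``tiny`` default) and a transformer encoder (the ``paper``-scale hook for
pretrained BioClinicalBERT-like backbones).  Projection heads are single
affine maps followed by Euclidean normalization, so inner products in the
shared space are cosine similarities.

Presets: ``tiny`` (trained from scratch in the test suite; <2e5
parameters per encoder) and ``paper`` (ResNet-50-like dimensions, C=2048
at stride 32 and d=768; no test trains it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Module, Linear, Conv2d, ChannelNorm, Embedding, \
    LayerNorm, TransformerEncoderLayer, concatenate, functional as F
from .text_processing import TokenizedReport, aggregate_token_embeddings

__all__ = ["EncoderSpec", "VisualFeatures", "TextFeatures", "EmbeddingPair",
           "VisualEncoder", "TextEncoder", "ConvTextEncoder", "build_text_encoder",
           "ProjectionHeads", "AlignmentModel",
           "encode_image", "encode_text", "project_global", "project_local"]


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture preset for both encoders and the shared space."""

    scale: str = "tiny"
    visual_channels: int = 48          # C of the final feature map
    downsample: int = 8                # total stride of the visual encoder
    text_dim: int = 64                 # d, token embedding width
    text_arch: str = "conv"            # "conv" (n-gram) or "transformer"
    text_kernel: int = 5               # context width of the conv text encoder
    text_layers: int = 2               # transformer depth (transformer arch)
    text_heads: int = 2
    shared_dim: int = 128              # D of the joint embedding space
    max_tokens: int = 192
    init_scale: float = 0.02
    coord_channels: bool = True        # append row/col position planes
    residual_mixing: bool = False      # nonlinear residual branch per stage

    # Reports name lumbar levels ("l2 vertebra"), so region features must
    # carry their vertical position: global average pooling would otherwise
    # erase where a finding sits.  Two fixed coordinate planes in [-1, 1]
    # restore that information (the tiny stand-in for the large receptive
    # fields of a deep backbone).

    def __post_init__(self):
        if self.downsample & (self.downsample - 1):
            raise ValueError("downsample must be a power of two")
        if self.scale not in ("tiny", "paper"):
            raise ValueError("scale must be 'tiny' or 'paper'")

    @classmethod
    def tiny(cls, shared_dim: int = 128) -> "EncoderSpec":
        return cls(scale="tiny", shared_dim=shared_dim)

    @classmethod
    def paper(cls) -> "EncoderSpec":
        # ResNet-50 / BioClinicalBERT dimensions; not trained in-repo
        return cls(scale="paper", visual_channels=2048, downsample=32,
                   text_dim=768, text_arch="transformer", text_layers=2,
                   text_heads=8, shared_dim=512)


@dataclass
class VisualFeatures:
    f_g: np.ndarray            # (C,)
    f_l: np.ndarray            # (C, M), row-major over the grid
    grid: tuple[int, int]      # (h', w'), M = h'*w'


@dataclass
class TextFeatures:
    g_g: np.ndarray            # (d,), from the CLS position
    g_l: np.ndarray            # (d, N)
    word_map: list[tuple[int, int]]


@dataclass
class EmbeddingPair:
    v_g: np.ndarray            # (D,), unit norm
    t_g: np.ndarray            # (D,), unit norm
    v_l: np.ndarray            # (D, M), unit-norm columns
    t_l: np.ndarray            # (D, W), unit-norm columns


def _channel_schedule(c_final: int, n_stages: int) -> list[int]:
    # halve the width per stage going backwards, floor at 8
    chans = [c_final]
    for _ in range(n_stages - 1):
        chans.append(max(8, chans[-1] // 2))
    return chans[::-1]


class VisualEncoder(Module):
    """Strided conv encoder; one stride-2 stage per factor of 2 downsampling."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        self.spec = spec
        n_stages = int(np.log2(spec.downsample))
        chans = _channel_schedule(spec.visual_channels, n_stages)
        self.stage_channels = chans
        self.convs_down: list[Conv2d] = []
        self.convs_mix: list[Conv2d] = []
        self.norms_down: list[ChannelNorm] = []
        self.norms_mix: list[ChannelNorm] = []
        c_in = 3 if spec.coord_channels else 1
        for c_out in chans:
            self.convs_down.append(Conv2d(c_in, c_out, 3, rng, stride=2, padding=1,
                                          init_scale=spec.init_scale))
            self.convs_mix.append(Conv2d(c_out, c_out, 3, rng, stride=1, padding=1,
                                         init_scale=spec.init_scale))
            self.norms_down.append(ChannelNorm(c_out))
            self.norms_mix.append(ChannelNorm(c_out))
            c_in = c_out

    def forward(self, x: Tensor) -> list[Tensor]:
        """x: (B, 1, H, W) -> feature pyramid, one tensor per stage."""
        H, W = x.shape[-2], x.shape[-1]
        ds = self.spec.downsample
        if H % ds or W % ds:
            raise ValueError(f"input size {H}x{W} must be divisible by {ds}")
        if self.spec.coord_channels:
            from .nn import concatenate
            B = x.shape[0]
            rows = np.broadcast_to(np.linspace(-1, 1, H)[None, None, :, None],
                                   (B, 1, H, W))
            cols = np.broadcast_to(np.linspace(-1, 1, W)[None, None, None, :],
                                   (B, 1, H, W))
            x = concatenate([x, Tensor(rows.copy()), Tensor(cols.copy())],
                            axis=1)
        # linear main path with nonlinear residuals: phantom findings are
        # close to linearly decodable from pixels, and a linear cascade
        # preserves that while the residual branch adds expressivity
        pyramid = []
        for down, mix, n1, n2 in zip(self.convs_down, self.convs_mix,
                                     self.norms_down, self.norms_mix):
            x = n1(down(x))
            if self.spec.residual_mixing:
                x = x + n2(mix(x.relu()))
            pyramid.append(x)
        return pyramid

    @staticmethod
    def _positional_gates(C: int, h: int, w: int) -> np.ndarray:
        """Fixed cosine row-basis gates, cycling wavenumbers 0..4 over channels.

        Global average pooling of a gated map yields, per channel, the
        content's Fourier coefficient along image rows — so "which lumbar
        level carries the finding" survives the pooling instead of being
        averaged away.  Wavenumber 0 leaves a fifth of the channels as
        plain content channels.
        """
        rows = (np.arange(h) + 0.5) / h
        gates = np.empty((C, h))
        for c in range(C):
            k = c % 5
            gates[c] = 1.0 if k == 0 else np.sqrt(2.0) * np.cos(np.pi * k * rows)
        return np.repeat(gates[:, :, None], w, axis=2)

    def features(self, x: Tensor) -> tuple[Tensor, Tensor, tuple[int, int]]:
        """Return (f_g (B,C), f_l (B,C,M), grid); f_g is the GAP of f_l."""
        top = self.forward(x)[-1]
        B, C, h, w = top.shape
        key = (C, h, w)
        if getattr(self, "_gate_key", None) != key:
            self._gates = Tensor(self._positional_gates(C, h, w))
            self._gate_key = key
        f_l = (top * self._gates).reshape(B, C, h * w)
        f_g = f_l.mean(axis=2)
        return f_g, f_l, (h, w)


class TextEncoder(Module):
    """Small transformer encoder over subword ids; CLS output is global."""

    def __init__(self, spec: EncoderSpec, vocab_size: int, rng: np.random.Generator):
        self.spec = spec
        self.vocab_size = vocab_size
        d = spec.text_dim
        self.tok_emb = Embedding(vocab_size, d, rng, init_scale=spec.init_scale)
        self.pos_emb = Embedding(spec.max_tokens, d, rng, init_scale=spec.init_scale)
        self.blocks = [TransformerEncoderLayer(d, spec.text_heads, rng,
                                               init_scale=spec.init_scale)
                       for _ in range(spec.text_layers)]
        self.ln_out = LayerNorm(d)

    def forward(self, token_ids: np.ndarray, pad_mask: np.ndarray | None = None
                ) -> tuple[Tensor, Tensor]:
        """token_ids: (B, N) ints -> (g_g (B, d), g_l (B, N, d))."""
        token_ids = np.asarray(token_ids, dtype=int)
        if token_ids.max() >= self.vocab_size or token_ids.min() < 0:
            raise ValueError("token id out of vocabulary range")
        B, N = token_ids.shape
        if N > self.spec.max_tokens:
            raise ValueError(f"sequence length {N} exceeds max_tokens "
                             f"{self.spec.max_tokens}")
        x = self.tok_emb(token_ids) + self.pos_emb(np.arange(N))
        for block in self.blocks:
            x = block(x, pad_mask=pad_mask)
        x = self.ln_out(x)
        return x[:, 0, :], x


class ConvTextEncoder(Module):
    """Convolutional n-gram text encoder.

    Token + position embeddings pass through a width-``text_kernel``
    one-dimensional convolution (a sum of shifted linear taps), LayerNorm
    and a pointwise mixing layer.  Each token feature therefore summarizes
    its +/- kernel//2 neighborhood — wide enough to bind a finding word to
    the lumbar level it names ("degeneration at the l2 disc space") — and
    the encoder output at the CLS position is defined as the masked mean of
    the content-token features, giving a compositional bag-of-phrases
    global summary.  Shallow by design: it trains from scratch within a
    small step budget where a from-scratch transformer does not.
    """

    def __init__(self, spec: EncoderSpec, vocab_size: int, rng: np.random.Generator):
        self.spec = spec
        self.vocab_size = vocab_size
        d = spec.text_dim
        s = spec.init_scale
        self.tok_emb = Embedding(vocab_size, d, rng, init_scale=s)
        # no absolute position embeddings: the convolution supplies local
        # order, and absolute sentence offsets vary spuriously with report
        # length
        self.taps = [Linear(d, d, rng, init_scale=s, bias=(j == 0))
                     for j in range(spec.text_kernel)]
        self.ln1 = LayerNorm(d)
        self.mix = Linear(d, d, rng, init_scale=s)
        self.ln2 = LayerNorm(d)

    @staticmethod
    def _shift(x: Tensor, offset: int) -> Tensor:
        """Shift along the token axis with zero fill (length preserved)."""
        if offset == 0:
            return x
        B, N, d = x.shape
        pad = Tensor(np.zeros((B, abs(offset), d)))
        if offset > 0:
            return concatenate([x[:, offset:, :], pad], axis=1)
        return concatenate([pad, x[:, :offset, :]], axis=1)

    def forward(self, token_ids: np.ndarray, pad_mask: np.ndarray | None = None
                ) -> tuple[Tensor, Tensor]:
        token_ids = np.asarray(token_ids, dtype=int)
        if token_ids.max() >= self.vocab_size or token_ids.min() < 0:
            raise ValueError("token id out of vocabulary range")
        B, N = token_ids.shape
        if N > self.spec.max_tokens:
            raise ValueError(f"sequence length {N} exceeds max_tokens "
                             f"{self.spec.max_tokens}")
        if pad_mask is None:
            pad_mask = np.ones((B, N))
        mask = Tensor(pad_mask[..., None])
        x = self.tok_emb(token_ids) * mask
        k2 = self.spec.text_kernel // 2
        h = None
        for j, tap in enumerate(self.taps):
            term = tap(self._shift(x, j - k2))
            h = term if h is None else h + term
        h = self.ln1(h)
        if self.spec.residual_mixing:
            h = h + self.ln2(self.mix(h.relu()))
        h = h * mask
        # CLS output := masked mean of content tokens (positions 1..N-1)
        content = pad_mask.copy()
        content[:, 0] = 0.0
        weights = content / np.maximum(content.sum(axis=1, keepdims=True), 1.0)
        g_g = (h * Tensor(weights[..., None])).sum(axis=1)
        return g_g, h


def build_text_encoder(spec: EncoderSpec, vocab_size: int,
                       rng: np.random.Generator) -> Module:
    if spec.text_arch == "conv":
        return ConvTextEncoder(spec, vocab_size, rng)
    if spec.text_arch == "transformer":
        return TextEncoder(spec, vocab_size, rng)
    raise ValueError(f"unknown text_arch {spec.text_arch!r}")


class ProjectionHeads(Module):
    """Four affine maps into the shared space (R_vg, R_tg, R_vl, R_tl)."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        D = spec.shared_dim
        s = spec.init_scale
        self.vg = Linear(spec.visual_channels, D, rng, init_scale=s)
        self.tg = Linear(spec.text_dim, D, rng, init_scale=s)
        self.vl = Linear(spec.visual_channels, D, rng, init_scale=s)
        self.tl = Linear(spec.text_dim, D, rng, init_scale=s)


def _normalize_or_raise(x: Tensor, axis: int) -> Tensor:
    norms = np.sqrt((x.data ** 2).sum(axis=axis))
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm vector before normalization (degenerate input)")
    return F.l2_normalize(x, axis=axis)


class AlignmentModel(Module):
    """Bundles both encoders and the projection heads; batched embedding path."""

    def __init__(self, spec: EncoderSpec, vocab_size: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.visual = VisualEncoder(spec, rng)
        self.text = build_text_encoder(spec, vocab_size, rng)
        self.heads = ProjectionHeads(spec, rng)

    def embed_images(self, images: Tensor) -> tuple[Tensor, Tensor, tuple[int, int]]:
        """images (B,1,H,W) -> v_g (B,D) unit rows, v_l (B,M,D) unit rows, grid."""
        f_g, f_l, grid = self.visual.features(images)
        v_g = _normalize_or_raise(self.heads.vg(f_g), axis=-1)
        v_l = _normalize_or_raise(self.heads.vl(f_l.transpose(0, 2, 1)), axis=-1)
        return v_g, v_l, grid

    def embed_texts(self, token_ids: np.ndarray, pad_mask: np.ndarray,
                    agg: np.ndarray, word_mask: np.ndarray
                    ) -> tuple[Tensor, Tensor]:
        """token_ids (B,N); agg (B,Wmax,N) row-stochastic word-aggregation
        matrices; word_mask (B,Wmax).  Returns t_g (B,D) and t_l (B,Wmax,D)
        with unit rows at valid words and zero rows at padding."""
        g_g, tokens = self.text(token_ids, pad_mask=pad_mask)
        t_g = _normalize_or_raise(self.heads.tg(g_g), axis=-1)
        proj = self.heads.tl(tokens)                       # (B, N, D)
        words = Tensor(agg) @ proj                         # (B, Wmax, D)
        t_l = F.l2_normalize(words, axis=-1) * Tensor(word_mask[..., None])
        return t_g, t_l


# ---------------------------------------------------------------------------
# single-sample functional surface

def encode_image(image: np.ndarray, spec: EncoderSpec,
                 encoder: VisualEncoder) -> VisualFeatures:
    """Encode one H x W image into global + local raw visual features."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    f_g, f_l, grid = encoder.features(Tensor(image[None, None]))
    return VisualFeatures(f_g=f_g.data[0], f_l=f_l.data[0], grid=grid)


def encode_text(tok: TokenizedReport, spec: EncoderSpec,
                encoder: TextEncoder) -> TextFeatures:
    """Encode one tokenized report into global (CLS) + token features."""
    ids = np.asarray(tok.token_ids)[None, :]
    g_g, tokens = encoder(ids)
    return TextFeatures(g_g=g_g.data[0], g_l=tokens.data[0].T,
                        word_map=tok.word_map)


def project_global(f_g: np.ndarray, g_g: np.ndarray,
                   heads: ProjectionHeads) -> tuple[np.ndarray, np.ndarray]:
    """Affine + unit-normalize both global features into the shared space."""
    v_g = _normalize_or_raise(heads.vg(Tensor(f_g)), axis=-1)
    t_g = _normalize_or_raise(heads.tg(Tensor(g_g)), axis=-1)
    return v_g.data, t_g.data


def project_local(f_l: np.ndarray, g_l: np.ndarray,
                  word_map: list[tuple[int, int]],
                  heads: ProjectionHeads) -> tuple[np.ndarray, np.ndarray]:
    """Project region/token features, aggregate tokens to words, normalize.

    f_l: (C, M); g_l: (d, N).  Returns (v_l (D, M), t_l (D, W)) with
    unit-norm columns; tokens are projected first, then averaged per word,
    then normalized.
    """
    v_l = _normalize_or_raise(heads.vl(Tensor(np.asarray(f_l).T)), axis=-1)
    proj_tokens = heads.tl(Tensor(np.asarray(g_l).T))      # (N, D)
    words = aggregate_token_embeddings(proj_tokens.data.T, word_map)  # (D, W)
    t_l = _normalize_or_raise(Tensor(words.T), axis=-1)
    return v_l.data.T, t_l.data.T


def aggregation_matrix(word_map: list[tuple[int, int]], n_tokens: int,
                       w_max: int) -> np.ndarray:
    """Row-stochastic (w_max, n_tokens) matrix averaging token spans to words."""
    A = np.zeros((w_max, n_tokens))
    for w, (a, b) in enumerate(word_map):
        A[w, a:b] = 1.0 / (b - a)
    return A
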