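"""Text-guided U-Net segmentation decoder.

The decoder mirrors the visual encoder's feature pyramid: at each stage the
current map is bilinearly upsampled, concatenated with the encoder skip
feature, and convolved.  When text modulation is enabled, word embeddings
act as attention queries over the stage's spatial positions (keys/values);
the per-word attended summaries are pooled over words, projected back to
the stage's channel width, and added residually — so disabling modulation
(or passing no words) reduces exactly to a plain U-Net.  A final 1x1
convolution and per-pixel softmax produce class probabilities over
{background, vertebra, disc, instrumentation}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Module, ChannelNorm, Conv2d, Linear, concatenate, \
    functional as F

__all__ = ["DecoderConfig", "SegPrediction", "TextModulation", "SegmentationModel",
           "decode_segmentation", "dice_loss", "cross_entropy_loss",
           "segmentation_loss", "one_hot"]


@dataclass(frozen=True)
class DecoderConfig:
    n_stages: int = 3                     # must match the encoder's stride-2 stages
    k_classes: int = 4                    # background + vertebra + disc + hardware
    text_modulation: bool = True
    modulation_stages: tuple[int, ...] | None = None   # None = all decoder stages
    attn_dim: int = 16
    aux_alignment: bool = False
    aux_weight: float = 0.1
    dice_smoothing: float = 1.0

    def __post_init__(self):
        if self.k_classes < 2:
            raise ValueError("k_classes must be >= 2")
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")


@dataclass
class SegPrediction:
    probs: np.ndarray          # (H, W, K), rows sum to 1
    argmax_mask: np.ndarray    # (H, W) int


class TextModulation(Module):
    """Cross-modal attention: words query spatial positions; residual add."""

    def __init__(self, channels: int, text_dim: int, attn_dim: int,
                 rng: np.random.Generator, init_scale: float = 0.02):
        self.wq = Linear(text_dim, attn_dim, rng, init_scale)
        self.wk = Linear(channels, attn_dim, rng, init_scale)
        self.wv = Linear(channels, attn_dim, rng, init_scale)
        self.wo = Linear(attn_dim, channels, rng, init_scale)
        self.attn_dim = attn_dim

    def forward(self, fmap: Tensor, t_l: Tensor | None,
                word_mask: np.ndarray | None = None) -> Tensor:
        """fmap: (B, C, h, w); t_l: (B, W, D) word embeddings (zero-padded).

        With no text (t_l None or zero words) the input passes through
        unchanged.
        """
        if t_l is None:
            return fmap
        B, C, h, w = fmap.shape
        W = t_l.shape[1]
        if W == 0:
            return fmap
        if word_mask is None:
            word_mask = np.ones((B, W))
        if not word_mask.any():
            return fmap
        flat = fmap.reshape(B, C, h * w).swapaxes(1, 2)    # (B, hw, C)
        q = self.wq(t_l)                                    # (B, W, A)
        k = self.wk(flat)                                   # (B, hw, A)
        v = self.wv(flat)
        attn = F.softmax((q @ k.swapaxes(1, 2)) / np.sqrt(self.attn_dim), axis=-1)
        summaries = attn @ v                                # (B, W, A)
        # mean over real words only
        mask = word_mask / np.maximum(word_mask.sum(axis=1, keepdims=True), 1.0)
        pooled = (summaries * Tensor(mask[..., None])).sum(axis=1)   # (B, A)
        residual = self.wo(pooled)                          # (B, C)
        return fmap + residual.reshape(B, C, 1, 1)


class SegmentationModel(Module):
    """U-Net decoder over a visual encoder, with optional text modulation."""

    def __init__(self, encoder, cfg: DecoderConfig, text_dim: int,
                 seed: int = 0, init_scale: float = 0.05):
        from .encoders import VisualEncoder
        rng = np.random.default_rng(seed)
        if cfg.n_stages != len(encoder.stage_channels):
            raise ValueError(
                f"decoder has {cfg.n_stages} stages but encoder pyramid has "
                f"{len(encoder.stage_channels)}")
        self.encoder = encoder
        self.cfg = cfg
        chans = encoder.stage_channels             # e.g. [8, 16, 32]
        self.dec_convs: list[Conv2d] = []
        self.dec_norms: list[ChannelNorm] = []
        self.modulations: list[TextModulation] = []
        c_prev = chans[-1]
        for skip_c in reversed(chans[:-1]):
            self.dec_convs.append(Conv2d(c_prev + skip_c, skip_c, 3, rng,
                                         padding=1, init_scale=init_scale))
            self.dec_norms.append(ChannelNorm(skip_c))
            self.modulations.append(TextModulation(skip_c, text_dim,
                                                   cfg.attn_dim, rng))
            c_prev = skip_c
        self.final_conv = Conv2d(c_prev, c_prev, 3, rng, padding=1,
                                 init_scale=init_scale)
        self.final_norm = ChannelNorm(c_prev)
        self.classifier = Conv2d(c_prev, cfg.k_classes, 1, rng,
                                 init_scale=init_scale)

    def forward(self, images: Tensor, t_l: Tensor | None = None,
                word_mask: np.ndarray | None = None) -> Tensor:
        """images (B,1,H,W) -> class probabilities (B, K, H, W), softmaxed."""
        return F.softmax(self.logits(images, t_l, word_mask), axis=1)

    def logits(self, images: Tensor, t_l: Tensor | None = None,
               word_mask: np.ndarray | None = None) -> Tensor:
        pyramid = self.encoder(images)
        x = pyramid[-1]
        stages = self.cfg.modulation_stages
        for i, (conv, norm, mod) in enumerate(zip(self.dec_convs, self.dec_norms,
                                                  self.modulations)):
            x = F.upsample_bilinear2x(x)
            skip = pyramid[len(pyramid) - 2 - i]
            x = norm(conv(concatenate([x, skip], axis=1))).relu()
            if self.cfg.text_modulation and (stages is None or i in stages):
                x = mod(x, t_l, word_mask)
        x = self.final_norm(self.final_conv(F.upsample_bilinear2x(x))).relu()
        return self.classifier(x)


def decode_segmentation(model: SegmentationModel, image: np.ndarray,
                        t_l: np.ndarray | None = None) -> SegPrediction:
    """Run one image through the decoder and package the prediction."""
    t = Tensor(np.asarray(image, dtype=float)[None, None])
    tl_tensor = Tensor(np.asarray(t_l)[None]) if t_l is not None else None
    probs = model(t, tl_tensor).data[0]            # (K, H, W)
    probs = np.moveaxis(probs, 0, -1)              # (H, W, K)
    return SegPrediction(probs=probs, argmax_mask=np.argmax(probs, axis=-1))


def one_hot(mask: np.ndarray, k: int) -> np.ndarray:
    """(..., H, W) int labels -> (..., K, H, W) one-hot floats."""
    mask = np.asarray(mask, dtype=int)
    oh = np.eye(k)[mask]                          # (..., H, W, K)
    return np.moveaxis(oh, -1, -3)


def dice_loss(probs, target_onehot, smoothing: float = 1.0):
    """Soft Dice loss: 1 - mean over classes of the smoothed Dice score.

    probs, target_onehot: (..., K, H, W) with matching shapes; sums run
    over all pixels (and batch) per class.
    """
    tensor_in = isinstance(probs, Tensor)
    p = probs if tensor_in else Tensor(np.asarray(probs, dtype=float))
    g = Tensor(np.asarray(target_onehot.data if isinstance(target_onehot, Tensor)
                          else target_onehot, dtype=float))
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    axes = tuple(i for i in range(p.ndim) if i != p.ndim - 3)
    inter = (p * g).sum(axis=axes)
    denom = p.sum(axis=axes) + g.sum(axis=axes)
    dice = (2.0 * inter + smoothing) / (denom + smoothing)
    out = 1.0 - dice.mean()
    return out if tensor_in else out.item()


def cross_entropy_loss(probs, target_onehot, eps: float = 1e-12):
    """Mean per-pixel cross-entropy, computed from probabilities."""
    tensor_in = isinstance(probs, Tensor)
    p = probs if tensor_in else Tensor(np.asarray(probs, dtype=float))
    g = np.asarray(target_onehot.data if isinstance(target_onehot, Tensor)
                   else target_onehot, dtype=float)
    class_axis = p.ndim - 3
    picked = (p * Tensor(g)).sum(axis=class_axis)       # (..., H, W)
    out = -((picked + eps).log()).mean()
    return out if tensor_in else out.item()


def segmentation_loss(probs, target_onehot, cfg: DecoderConfig,
                      aux_loss=None):
    """Dice + mean cross-entropy (+ optional weighted auxiliary alignment)."""
    d = dice_loss(probs, target_onehot, smoothing=cfg.dice_smoothing)
    ce = cross_entropy_loss(probs, target_onehot)
    total = d + ce
    if cfg.aux_alignment and aux_loss is not None:
        total = total + cfg.aux_weight * aux_loss
    return total
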