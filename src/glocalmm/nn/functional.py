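"""Composite differentiable operations built on the autograd primitives."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, astensor, concatenate

__all__ = [
    "softmax",
    "logsumexp",
    "log_softmax",
    "l2_normalize",
    "conv2d",
    "upsample_bilinear2x",
    "bilinear_matrix",
]


def _stable_shift(x: Tensor, axis: int) -> Tensor:
    # detached max-subtraction: no gradient is needed through the shift
    shift = np.max(x.data, axis=axis, keepdims=True)
    return x - Tensor(shift)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    e = _stable_shift(astensor(x), axis).exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    x = astensor(x)
    shift = np.max(x.data, axis=axis, keepdims=True)
    out = (x - Tensor(shift)).exp().sum(axis=axis, keepdims=True).log() + Tensor(shift)
    if not keepdims:
        out = out.reshape(np.squeeze(out.data, axis=axis).shape)
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = astensor(x)
    return x - logsumexp(x, axis=axis, keepdims=True)


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """Unit-normalize along ``axis``; eps inside the sqrt keeps the gradient
    finite for all-zero slices (padding rows map to zero vectors)."""
    x = astensor(x)
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps**2).sqrt()
    return x / norm


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation.

    x: (B, C, H, W); weight: (O, C, kh, kw); bias: (O,).
    Returns (B, O, H', W').  Implemented as unfold + matmul so the whole
    operation rides on primitives with verified gradients.
    """
    B, C, H, W = x.shape
    O, Cw, kh, kw = weight.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {Cw}")
    if padding:
        x = x.pad2d(padding, padding)
    patches = x.unfold2d(kh, kw, stride)          # (B, C, H', W', kh, kw)
    Ho, Wo = patches.shape[2], patches.shape[3]
    patches = patches.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    out = patches @ weight.reshape(O, C * kh * kw).T          # (B*Ho*Wo, O)
    out = out.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.reshape(1, O, 1, 1)
    return out


def bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (n_out x n_in).

    Uses the half-pixel-center convention: output center i maps to input
    coordinate (i + 0.5) * n_in / n_out - 0.5, clamped at the borders.
    """
    A = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        pos = (i + 0.5) * scale - 0.5
        lo = int(np.floor(pos))
        frac = pos - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        A[i, lo_c] += 1.0 - frac
        A[i, hi_c] += frac
    return A


_BILINEAR_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _cached_matrix(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    if key not in _BILINEAR_CACHE:
        _BILINEAR_CACHE[key] = bilinear_matrix(n_out, n_in)
    return _BILINEAR_CACHE[key]


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling of a (..., H, W) tensor via interpolation matrices."""
    x = astensor(x)
    H, W = x.shape[-2], x.shape[-1]
    A = Tensor(_cached_matrix(2 * H, H))
    Bm = Tensor(_cached_matrix(2 * W, W))
    return (A @ x) @ Bm.T


def resize_bilinear(img: np.ndarray, h_out: int, w_out: int) -> np.ndarray:
    """Non-differentiable bilinear resize of a 2-D array (for overlays)."""
    A = _cached_matrix(h_out, img.shape[0])
    Bm = _cached_matrix(w_out, img.shape[1])
    return A @ np.asarray(img, dtype=float) @ Bm.T
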