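"""Neural-network layers: parameter containers and the building blocks
used by the tiny encoders and the segmentation decoder."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate
from . import functional as F

__all__ = ["Module", "Linear", "Conv2d", "LayerNorm", "Embedding",
           "TransformerEncoderLayer", "Sequential"]


class Module:
    """Minimal parameter container with recursive traversal.

    Parameters are ``Tensor`` attributes with ``requires_grad=True``;
    submodules are ``Module`` attributes or items of list attributes.
    Attributes whose names start with an underscore are not traversed
    (used for frozen companion models that must not be optimized).
    """

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for name, v in vars(obj).items():
                    if not name.startswith("_"):
                        visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        visit(self)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, v in vars(self).items():
            if name.startswith("_"):
                continue
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out.append((key, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, t in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {t.data.shape}")
            t.data[...] = arr

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init_scale: float | None = None, bias: bool = True):
        scale = init_scale if init_scale is not None else 1.0 / np.sqrt(d_in)
        self.weight = _param(rng, (d_out, d_in), scale)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.T
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, init_scale: float | None = None):
        scale = init_scale if init_scale is not None else 1.0 / np.sqrt(c_in * kernel * kernel)
        self.weight = _param(rng, (c_out, c_in, kernel, kernel), scale)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class ChannelNorm(Module):
    """LayerNorm over the channel axis of a (B, C, H, W) feature map.

    Keeps activation scale O(1) through deep conv stacks regardless of
    weight init, which conditions the optimization at small learning rates.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.ln = LayerNorm(channels, eps=eps)

    def forward(self, x: Tensor) -> Tensor:
        return self.ln(x.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator,
                 init_scale: float = 0.02):
        self.weight = _param(rng, (n_embeddings, dim), init_scale)

    def forward(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids, dtype=int)]


class TransformerEncoderLayer(Module):
    """Pre-norm transformer block with multi-head self-attention."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: float = 2.0, init_scale: float = 0.02):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)
        self.wq = Linear(dim, dim, rng, init_scale)
        self.wk = Linear(dim, dim, rng, init_scale)
        self.wv = Linear(dim, dim, rng, init_scale)
        self.wo = Linear(dim, dim, rng, init_scale)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng, init_scale)
        self.fc2 = Linear(hidden, dim, rng, init_scale)

    def _split(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        return x.reshape(B, N, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        """x: (B, N, D); pad_mask: (B, N) with 1 for real tokens, 0 for padding."""
        h = self.ln1(x)
        q, k, v = self._split(self.wq(h)), self._split(self.wk(h)), self._split(self.wv(h))
        logits = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(self.head_dim)  # (B,H,N,N)
        if pad_mask is not None:
            bias = np.where(pad_mask[:, None, None, :] > 0, 0.0, -1e9)
            logits = logits + Tensor(bias)
        attn = F.softmax(logits, axis=-1)
        ctx = attn @ v                                        # (B,H,N,hd)
        B, H, N, hd = ctx.shape
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, N, H * hd)
        x = x + self.wo(ctx)
        h = self.ln2(x)
        x = x + self.fc2(self.fc1(h).relu())
        return x


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x):
        for m in self.modules:
            x = m(x)
        return x
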