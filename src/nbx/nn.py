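"""Parameter containers and layer functions used by the model modules.

Parameters live in flat ``dict[str, Tensor]`` namespaces ("param dicts");
layers are pure functions of (input tensors, params).  This keeps the
forward passes transparent enough to compare against loop-based oracles
and lets optimizers treat a model as a list of named arrays.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, concat

ParamDict = dict[str, Tensor]


def param(rng: np.random.Generator, shape, scale: str | float = "he") -> Tensor:
    """A trainable tensor initialised from a seeded generator.

    ``scale='he'`` uses Kaiming-normal on the fan-in (first trailing dim for
    matrices, full receptive field for conv kernels); a float is an explicit
    std; ``'zeros'`` gives zeros (biases).
    """
    shape = tuple(shape)
    if scale == "zeros":
        data = np.zeros(shape)
    else:
        if scale == "he":
            fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
            std = np.sqrt(2.0 / max(fan_in, 1))
        else:
            std = float(scale)
        data = rng.normal(0.0, std, size=shape)
    return Tensor(data, requires_grad=True)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w.T (+ b)`` with ``w`` of shape (out, in)."""
    out = x @ w.transpose(1, 0)
    if b is not None:
        out = out + b
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    xhat = (x - mu) / ((var + eps) ** 0.5)
    return xhat * gamma + beta


def multi_head_attention(x: Tensor, p: ParamDict, prefix: str, heads: int) -> Tensor:
    """Standard self-attention over (B, T, D) token sequences."""
    b, t, d = x.shape
    dh = d // heads
    q = linear(x, p[f"{prefix}.wq"], p[f"{prefix}.bq"])
    k = linear(x, p[f"{prefix}.wk"], p[f"{prefix}.bk"])
    v = linear(x, p[f"{prefix}.wv"], p[f"{prefix}.bv"])

    def split(z: Tensor) -> Tensor:        # (B,T,D) -> (B,heads,T,dh)
        return z.reshape(b, t, heads, dh).transpose(0, 2, 1, 3)

    q, k, v = split(q), split(k), split(v)
    att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
    att = att.softmax(axis=-1)
    out = (att @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
    return linear(out, p[f"{prefix}.wo"], p[f"{prefix}.bo"])


def init_mha(rng: np.random.Generator, p: ParamDict, prefix: str, d: int) -> None:
    std = 1.0 / np.sqrt(d)
    for nm in ("q", "k", "v", "o"):
        p[f"{prefix}.w{nm}"] = param(rng, (d, d), std)
        p[f"{prefix}.b{nm}"] = param(rng, (d,), "zeros")


def encoder_block(x: Tensor, p: ParamDict, prefix: str, heads: int,
                  mlp_ratio: float) -> Tensor:
    """Pre-norm transformer encoder block with a GELU MLP."""
    h = layer_norm(x, p[f"{prefix}.ln1.g"], p[f"{prefix}.ln1.b"])
    x = x + multi_head_attention(h, p, f"{prefix}.attn", heads)
    h = layer_norm(x, p[f"{prefix}.ln2.g"], p[f"{prefix}.ln2.b"])
    h = linear(h, p[f"{prefix}.mlp.w1"], p[f"{prefix}.mlp.b1"]).gelu()
    h = linear(h, p[f"{prefix}.mlp.w2"], p[f"{prefix}.mlp.b2"])
    return x + h


def init_encoder_block(rng: np.random.Generator, p: ParamDict, prefix: str,
                       d: int, mlp_ratio: float) -> None:
    hidden = int(d * mlp_ratio)
    init_mha(rng, p, f"{prefix}.attn", d)
    p[f"{prefix}.ln1.g"] = Tensor(np.ones(d), requires_grad=True)
    p[f"{prefix}.ln1.b"] = param(rng, (d,), "zeros")
    p[f"{prefix}.ln2.g"] = Tensor(np.ones(d), requires_grad=True)
    p[f"{prefix}.ln2.b"] = param(rng, (d,), "zeros")
    p[f"{prefix}.mlp.w1"] = param(rng, (hidden, d))
    p[f"{prefix}.mlp.b1"] = param(rng, (hidden,), "zeros")
    p[f"{prefix}.mlp.w2"] = param(rng, (d, hidden))
    p[f"{prefix}.mlp.b2"] = param(rng, (d,), "zeros")


def num_params(p: ParamDict) -> int:
    return int(sum(t.size for t in p.values()))


def zero_grads(p: ParamDict) -> None:
    for t in p.values():
        t.grad = None


__all__ = ["ParamDict", "param", "linear", "layer_norm", "multi_head_attention",
           "init_mha", "encoder_block", "init_encoder_block", "num_params",
           "zero_grads", "concat"]
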