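"""Optimizers: SGD with momentum, Nadam, and RAdam with fractional decay.

Presets follow the training protocol this package reproduces:
Nadam at lr 1e-3; SGD at lr 0.01 with momentum 0.9; RAdam at a base lr of
5e-4 with a fractional (power-law) learning-rate decay
``lr_t = lr0 * (1 + t)^(-decay_exponent)`` applied per step.  A decay
exponent of 0 reduces fractional RAdam to plain RAdam, which tests use as
a differential check.

``make_optimizer`` returns a *fresh* state each call, so re-initialising
an optimizer between cross-validation folds is the natural usage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor
from .nn import ParamDict

__all__ = ["OptimizerSpec", "Optimizer", "make_optimizer", "PRESETS"]


@dataclass(frozen=True)
class OptimizerSpec:
    name: str = "sgd"
    lr: float = 0.01
    momentum: float = 0.9            # sgd only
    decay_exponent: float = 0.5      # fractional_radam only
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


PRESETS: dict[str, OptimizerSpec] = {
    "nadam": OptimizerSpec(name="nadam", lr=1e-3),
    "sgd": OptimizerSpec(name="sgd", lr=0.01, momentum=0.9),
    "fractional_radam": OptimizerSpec(name="fractional_radam", lr=5e-4,
                                      decay_exponent=0.5),
    "radam": OptimizerSpec(name="fractional_radam", lr=5e-4, decay_exponent=0.0),
}


class Optimizer:
    """Shared state machinery; ``step`` consumes gradients on the params."""

    def __init__(self, spec: OptimizerSpec, params: ParamDict):
        self.spec = spec
        self.params = params
        self.t = 0
        self.state: dict[str, dict[str, np.ndarray]] = {
            k: {} for k in params}

    def step(self) -> None:
        self.t += 1
        for name, p in self.params.items():
            if p.grad is None:
                continue
            self._update(name, p, np.asarray(p.grad))

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def _update(self, name: str, p: Tensor, g: np.ndarray) -> None:
        raise NotImplementedError


class SgdMomentum(Optimizer):
    def _update(self, name, p, g):
        st = self.state[name]
        buf = st.get("momentum")
        if buf is None:
            buf = np.zeros_like(p.data)
        buf = self.spec.momentum * buf + g
        st["momentum"] = buf
        p.data = p.data - self.spec.lr * buf


class Nadam(Optimizer):
    """Nesterov-accelerated Adam (Dozat's formulation)."""

    def _update(self, name, p, g):
        s = self.spec
        st = self.state[name]
        m = st.get("m", np.zeros_like(p.data))
        v = st.get("v", np.zeros_like(p.data))
        t = self.t
        m = s.beta1 * m + (1 - s.beta1) * g
        v = s.beta2 * v + (1 - s.beta2) * g * g
        st["m"], st["v"] = m, v
        m_hat = m / (1 - s.beta1 ** (t + 1))
        g_hat = g / (1 - s.beta1 ** t)
        v_hat = v / (1 - s.beta2 ** t)
        update = (s.beta1 * m_hat + (1 - s.beta1) * g_hat) / (np.sqrt(v_hat) + s.eps)
        p.data = p.data - s.lr * update


class FractionalRAdam(Optimizer):
    """Rectified Adam with per-step power-law learning-rate decay."""

    def _update(self, name, p, g):
        s = self.spec
        st = self.state[name]
        m = st.get("m", np.zeros_like(p.data))
        v = st.get("v", np.zeros_like(p.data))
        t = self.t
        m = s.beta1 * m + (1 - s.beta1) * g
        v = s.beta2 * v + (1 - s.beta2) * g * g
        st["m"], st["v"] = m, v
        lr_t = s.lr * (1.0 + (t - 1)) ** (-s.decay_exponent)
        m_hat = m / (1 - s.beta1 ** t)
        rho_inf = 2.0 / (1.0 - s.beta2) - 1.0
        rho_t = rho_inf - 2.0 * t * s.beta2 ** t / (1 - s.beta2 ** t)
        if rho_t > 4.0:
            v_hat = np.sqrt(v / (1 - s.beta2 ** t))
            r_t = np.sqrt(((rho_t - 4) * (rho_t - 2) * rho_inf)
                          / ((rho_inf - 4) * (rho_inf - 2) * rho_t))
            p.data = p.data - lr_t * r_t * m_hat / (v_hat + s.eps)
        else:
            p.data = p.data - lr_t * m_hat


def make_optimizer(spec: OptimizerSpec | str, params: ParamDict) -> Optimizer:
    """Instantiate a fresh optimizer (preset name or explicit spec)."""
    if isinstance(spec, str):
        if spec not in PRESETS:
            raise ValueError(f"unknown optimizer {spec!r}; "
                             f"presets: {sorted(PRESETS)}")
        spec = PRESETS[spec]
    cls = {"sgd": SgdMomentum, "nadam": Nadam,
           "fractional_radam": FractionalRAdam}.get(spec.name)
    if cls is None:
        raise ValueError(f"unknown optimizer name {spec.name!r}")
    return cls(spec, params)
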