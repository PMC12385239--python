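"""CNN encoder with channel-wise morphological attention.

The encoder turns an image batch I (B, 3, H, W) into a feature map
F_cnn = E(I) of shape (B, C, H', W').  A squeeze-and-excitation style gate
then re-weights channels:

    z = GAP(F_cnn)                    (spatial mean per channel)
    w = sigmoid(W2 @ relu(W1 @ z))    (bias-free two-layer gate)
    F_att = F_cnn * w                 (broadcast over space)

followed by global average pooling to the vector f_cnn.  Because w lies
strictly in (0, 1), gating only attenuates channels; with zero gate
parameters w = 0.5 exactly and the map is halved.

Two backbones are provided: ``tiny`` — an explicit three-stage conv stack
small enough for loop-oracle tests and CPU training — and ``paper_b0``, a
reduced stack whose last stage outputs the 1280-channel width contract of
an EfficientNet-B0 encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._tensor import Tensor, conv2d
from ..nn import ParamDict, param


@dataclass(frozen=True)
class ConvStage:
    out_channels: int
    kernel: int = 3
    stride: int = 2

    @property
    def pad(self) -> int:
        return self.kernel // 2


TINY_STAGES = (ConvStage(16, 3, 2), ConvStage(32, 3, 2), ConvStage(32, 3, 2))
# Width-faithful stand-in for an EfficientNet-B0 encoder: strided stages
# ending in a 1x1 projection to the 1280-channel contract.
B0_STAGES = (ConvStage(32, 3, 2), ConvStage(64, 3, 2), ConvStage(128, 3, 2),
             ConvStage(256, 3, 2), ConvStage(1280, 1, 1))


@dataclass
class CnnConfig:
    backbone: str = "tiny"
    stages: tuple[ConvStage, ...] = ()
    gate_reduction: int = 16          # hidden width = max(C // reduction, 1)

    def __post_init__(self) -> None:
        if not self.stages:
            if self.backbone == "tiny":
                self.stages = TINY_STAGES
            elif self.backbone == "paper_b0":
                self.stages = B0_STAGES
            else:
                raise ValueError(f"unknown backbone {self.backbone!r}")

    @property
    def out_channels(self) -> int:
        return self.stages[-1].out_channels

    @property
    def stride_product(self) -> int:
        return int(np.prod([s.stride for s in self.stages]))

    @property
    def gate_hidden(self) -> int:
        return max(self.out_channels // self.gate_reduction, 1)


def init_cnn(cfg: CnnConfig, rng: np.random.Generator,
             in_channels: int = 3) -> ParamDict:
    p: ParamDict = {}
    c = in_channels
    for i, st in enumerate(cfg.stages):
        p[f"cnn.conv{i}.w"] = param(rng, (st.out_channels, c, st.kernel, st.kernel))
        p[f"cnn.conv{i}.b"] = param(rng, (st.out_channels,), "zeros")
        c = st.out_channels
    # the gate is bias-free and its input z = GAP(ReLU(conv)) is >= 0, so a
    # zero-mean W1 can leave every hidden unit dead; start W1 non-negative
    w1 = param(rng, (cfg.gate_hidden, cfg.out_channels))
    w1.data = np.abs(w1.data)
    p["gate.w1"] = w1
    p["gate.w2"] = param(rng, (cfg.out_channels, cfg.gate_hidden))
    return p


def cnn_forward(images: Tensor | np.ndarray, cfg: CnnConfig, params: ParamDict
                ) -> Tensor:
    """Run the conv stages (each conv + ReLU) and return the feature map."""
    x = images if isinstance(images, Tensor) else Tensor(images)
    side = x.shape[-1]
    if side % cfg.stride_product != 0:
        raise ValueError(
            f"input side {side} not divisible by backbone stride "
            f"{cfg.stride_product}")
    for i, st in enumerate(cfg.stages):
        x = conv2d(x, params[f"cnn.conv{i}.w"], params[f"cnn.conv{i}.b"],
                   stride=st.stride, pad=st.pad)
        x = x.relu()
    return x


def morph_attention(fmap: Tensor, params: ParamDict
                    ) -> tuple[Tensor, dict[str, Tensor]]:
    """Channel gate: returns (gated map, {"z": pooled means, "w": gate})."""
    b, c, h, w_ = fmap.shape
    if params["gate.w1"].shape[1] != c:
        raise ValueError(
            f"gate expects {params['gate.w1'].shape[1]} channels, got {c}")
    z = fmap.mean(axis=(2, 3))                                  # B x C
    hidden = (z @ params["gate.w1"].transpose(1, 0)).relu()
    w = (hidden @ params["gate.w2"].transpose(1, 0)).sigmoid()  # B x C
    gated = fmap * w.reshape(b, c, 1, 1)
    return gated, {"z": z, "w": w}


def pool_cnn(fmap: Tensor) -> Tensor:
    """Global average pooling over space: (B, C, H', W') -> (B, C)."""
    return fmap.mean(axis=(2, 3))
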