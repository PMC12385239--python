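"""Full model assembly: configs, ablations, forward pass, checkpoints.

``BridgeClassifier`` wires the CNN branch, ViT branch, bridge, classifier
and Meta-XAI controller together and exposes a single ``forward`` that
returns every intermediate needed downstream (attention gates for
inspection, the feature map for Grad-CAM, the policy for explanation
selection).

Ablations mirror the component-removal study grid:

* ``full``          — the complete architecture;
* ``no_bridge``     — fusion replaced by a plain linear projection to 256;
* ``no_meta_xai``   — no policy head, lambda_x = 0;
* ``no_morph``      — channel gate fixed to 1;
* ``no_vit``        — f_vit dropped (bridge reads f_cnn alone);
* ``cnn_only``      — classifier directly on pooled CNN features.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .._tensor import Tensor
from ..nn import ParamDict, linear, num_params, param
from .bridge import (BRIDGE_WIDTH, HeadConfig, XAI_METHODS, bridge_forward,
                     classify, init_head, meta_xai_policy)
from .cnn import CnnConfig, cnn_forward, init_cnn, morph_attention, pool_cnn
from .vit import VitConfig, conceptual_attention, init_vit, patch_embed, \
    transformer_stack

ABLATIONS = ("full", "no_bridge", "no_meta_xai", "no_morph", "no_vit", "cnn_only")


@dataclass
class ModelConfig:
    side: int = 64
    cnn: CnnConfig = field(default_factory=CnnConfig)
    vit: VitConfig = field(default_factory=VitConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    ablation: str = "full"

    def __post_init__(self) -> None:
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}; "
                             f"choose from {ABLATIONS}")

    # -- derived structure ---------------------------------------------------
    @property
    def has_vit(self) -> bool:
        return self.ablation not in ("no_vit", "cnn_only")

    @property
    def has_bridge(self) -> bool:
        return self.ablation != "cnn_only"

    @property
    def has_policy(self) -> bool:
        return self.ablation not in ("no_meta_xai", "cnn_only")

    @property
    def has_gate(self) -> bool:
        return self.ablation != "no_morph"

    @property
    def lambda_x(self) -> float:
        return self.head.lambda_x if self.has_policy else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cnn"]["stages"] = [list(s.values()) if isinstance(s, dict) else s
                              for s in d["cnn"]["stages"]]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        import yaml
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        import yaml
        return _config_from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class FeatureBundle:
    """Everything one forward pass produces, kept as live graph tensors."""

    feature_map: Tensor            # pre-gate CNN map (Grad-CAM layer)
    gate: dict[str, Tensor] | None
    f_cnn: Tensor
    f_vit: Tensor | None
    alpha: Tensor | None           # conceptual-attention weights
    f_bridge: Tensor
    logits: Tensor
    probs: Tensor
    policy: Tensor | None

    def predictions(self) -> np.ndarray:
        return np.argmax(self.probs.data, axis=-1)


class BridgeClassifier:
    """The assembled classifier with its parameter dict."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 params: ParamDict | None = None):
        self.config = config
        self.seed = seed
        if params is not None:
            self.params = params
        else:
            self.params = self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng: np.random.Generator) -> ParamDict:
        cfg = self.config
        p = init_cnn(cfg.cnn, rng)
        if not cfg.has_gate:
            p.pop("gate.w1"), p.pop("gate.w2")
        if cfg.has_vit:
            p.update(init_vit(cfg.vit, rng, cfg.side))
        cnn_w = cfg.cnn.out_channels
        vit_w = cfg.vit.embed_dim if cfg.has_vit else 0
        if cfg.has_bridge:
            p.update(init_head(cfg.head, rng, cnn_w, vit_w,
                               with_policy=cfg.has_policy))
            if cfg.ablation == "no_bridge":
                # plain projection replaces the two-layer tanh bridge
                p.pop("bridge.w1"), p.pop("bridge.w2")
                p["proj.w"] = param(rng, (BRIDGE_WIDTH, cnn_w + vit_w))
                p["proj.b"] = param(rng, (BRIDGE_WIDTH,), "zeros")
        else:
            p["cls.w1"] = param(rng, (cfg.head.classifier_hidden, cnn_w))
            p["cls.w2"] = param(rng, (cfg.head.num_classes,
                                      cfg.head.classifier_hidden))
            p["cls.b"] = param(rng, (cfg.head.num_classes,), "zeros")
        return p

    # -- forward -------------------------------------------------------------
    def forward(self, images: Tensor | np.ndarray) -> FeatureBundle:
        cfg = self.config
        x = images if isinstance(images, Tensor) else Tensor(images)
        # standard input normalization: [0, 1] pixels to zero-centred [-1, 1]
        x = x * 2.0 - 1.0
        fmap = cnn_forward(x, cfg.cnn, self.params)
        if cfg.has_gate:
            gated, gate = morph_attention(fmap, self.params)
        else:
            gated, gate = fmap, None
        f_cnn = pool_cnn(gated)

        f_vit = alpha = None
        if cfg.has_vit:
            t0 = patch_embed(x, cfg.vit, self.params)
            tl = transformer_stack(t0, cfg.vit, self.params)
            f_vit, alpha = conceptual_attention(tl, self.params)

        if cfg.has_bridge:
            if cfg.ablation == "no_bridge":
                from ..nn import concat
                fused = f_cnn if f_vit is None else concat([f_cnn, f_vit], axis=-1)
                f_bridge = linear(fused, self.params["proj.w"],
                                  self.params["proj.b"])
            else:
                f_bridge = bridge_forward(f_cnn, f_vit, self.params)
        else:
            f_bridge = f_cnn
        logits, probs = classify(f_bridge, self.params)
        policy = meta_xai_policy(f_bridge, self.params) if cfg.has_policy else None
        return FeatureBundle(feature_map=fmap, gate=gate, f_cnn=f_cnn,
                             f_vit=f_vit, alpha=alpha, f_bridge=f_bridge,
                             logits=logits, probs=probs, policy=policy)

    __call__ = forward

    def predict_probs(self, images: np.ndarray) -> np.ndarray:
        return self.forward(images).probs.data

    # -- profiling -----------------------------------------------------------
    def parameter_count(self) -> int:
        return num_params(self.params)

    def mac_estimate(self) -> int:
        """Closed-form multiply-accumulate estimate for one image."""
        cfg = self.config
        side = cfg.side
        macs = 0
        c_in, s = 3, side
        for st in cfg.cnn.stages:
            s_out = s // st.stride
            macs += s_out * s_out * st.kernel ** 2 * c_in * st.out_channels
            c_in, s = st.out_channels, s_out
        c = cfg.cnn.out_channels
        if cfg.has_gate:
            macs += c * cfg.cnn.gate_hidden * 2
        if cfg.has_vit:
            v = cfg.vit
            n = v.num_patches(side)
            t, d = n + 1, v.embed_dim
            macs += n * (3 * v.patch_size ** 2) * d
            per_block = 4 * t * d * d + 2 * t * t * d + 2 * t * d * int(d * v.mlp_ratio)
            macs += v.depth * per_block
            macs += t * d * d + t * d          # concept scorer
        fused = c + (cfg.vit.embed_dim if cfg.has_vit else 0)
        if cfg.has_bridge:
            if cfg.ablation == "no_bridge":
                macs += fused * BRIDGE_WIDTH
            else:
                macs += fused * cfg.head.bridge_hidden \
                    + cfg.head.bridge_hidden * BRIDGE_WIDTH
            cls_in = BRIDGE_WIDTH
        else:
            cls_in = c
        macs += cls_in * cfg.head.classifier_hidden \
            + cfg.head.classifier_hidden * cfg.head.num_classes
        if cfg.has_policy:
            macs += BRIDGE_WIDTH * 64 + 64 * len(XAI_METHODS)
        return int(macs)

    # -- checkpointing -------------------------------------------------------
    def save(self, path: str | Path, vocabulary: list[str] | None = None,
             extra: dict | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {"config": self.config.to_dict(),
                "config_hash": self.config.config_hash(),
                "seed": self.seed,
                "vocabulary": vocabulary or [],
                "extra": extra or {}}
        arrays = {k: v.data for k, v in self.params.items()}
        buf = io.BytesIO()
        np.savez(buf, __meta__=np.frombuffer(
            json.dumps(meta, default=str).encode(), dtype=np.uint8), **arrays)
        path.write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> tuple["BridgeClassifier", dict]:
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        cfg = _config_from_dict(meta["config"])
        params = {k: Tensor(v, requires_grad=True) for k, v in arrays.items()}
        model = cls(cfg, seed=meta.get("seed", 0), params=params)
        return model, meta


def _config_from_dict(d: dict) -> ModelConfig:
    from .cnn import ConvStage
    cnn_d = dict(d["cnn"])
    cnn_d["stages"] = tuple(ConvStage(*s) for s in cnn_d["stages"])
    vit_d = dict(d["vit"])
    head_d = dict(d["head"])
    return ModelConfig(side=d["side"], cnn=CnnConfig(**cnn_d),
                       vit=VitConfig(**vit_d), head=HeadConfig(**head_d),
                       ablation=d["ablation"])
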