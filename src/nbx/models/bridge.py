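"""Bounded fusion bridge, classifier head, Meta-XAI policy and losses.

The pooled CNN vector f_cnn and conceptual ViT vector f_vit are fused by a
bias-free two-layer "logic bridge" bounded by tanh:

    f_bridge = tanh(W2 @ relu(W1 @ [f_cnn || f_vit]))  in (-1, 1)^256

Two small heads read f_bridge:

* the classifier, ``softmax(W2c @ relu(W1c @ f_bridge) + b_c)`` over the K
  diagnostic classes, and
* the Meta-XAI controller, a 64-hidden-unit MLP with biases producing a
  simplex over the four attribution methods in the fixed order
  (grad_cam, shap, integrated_gradients, lime).

Training minimises cross-entropy plus an optional explanation-quality
term: ``L = L_CE + lambda_x * (1 - mean_b sum_k p_k q_k)`` where q is a
per-method quality score in [0, 1], so a policy that weights the
highest-quality method minimises the auxiliary term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._tensor import Tensor, concat
from ..nn import ParamDict, linear, param

#: Fixed Meta-XAI method order; policy indices are meaningless without it.
XAI_METHODS = ("grad_cam", "shap", "integrated_gradients", "lime")

BRIDGE_WIDTH = 256
POLICY_HIDDEN = 64


@dataclass
class HeadConfig:
    num_classes: int = 4
    bridge_hidden: int = 512
    classifier_hidden: int = 128
    lambda_x: float = 0.1


def init_head(cfg: HeadConfig, rng: np.random.Generator, cnn_width: int,
              vit_width: int, with_policy: bool = True) -> ParamDict:
    p: ParamDict = {}
    in_width = cnn_width + vit_width
    p["bridge.w1"] = param(rng, (cfg.bridge_hidden, in_width))
    p["bridge.w2"] = param(rng, (BRIDGE_WIDTH, cfg.bridge_hidden))
    p["cls.w1"] = param(rng, (cfg.classifier_hidden, BRIDGE_WIDTH))
    p["cls.w2"] = param(rng, (cfg.num_classes, cfg.classifier_hidden))
    p["cls.b"] = param(rng, (cfg.num_classes,), "zeros")
    if with_policy:
        p["xai.w1"] = param(rng, (POLICY_HIDDEN, BRIDGE_WIDTH))
        p["xai.b1"] = param(rng, (POLICY_HIDDEN,), "zeros")
        p["xai.w2"] = param(rng, (len(XAI_METHODS), POLICY_HIDDEN))
        p["xai.b2"] = param(rng, (len(XAI_METHODS),), "zeros")
    return p


def bridge_forward(f_cnn: Tensor, f_vit: Tensor | None, params: ParamDict
                   ) -> Tensor:
    """Fuse the two pooled vectors into the bounded 256-d bridge vector."""
    fused = f_cnn if f_vit is None else concat([f_cnn, f_vit], axis=-1)
    if fused.shape[-1] != params["bridge.w1"].shape[1]:
        raise ValueError(
            f"bridge expects input width {params['bridge.w1'].shape[1]}, "
            f"got {fused.shape[-1]}")
    h = linear(fused, params["bridge.w1"]).relu()
    return linear(h, params["bridge.w2"]).tanh()


def classify(f_bridge: Tensor, params: ParamDict) -> tuple[Tensor, Tensor]:
    """Two-layer classifier head; returns (logits, probs).

    Softmax is computed with the log-sum-exp shift, so extreme logits do
    not overflow.  Predicted class = argmax with lowest-index tie-break
    (numpy argmax semantics).
    """
    h = linear(f_bridge, params["cls.w1"]).relu()
    logits = linear(h, params["cls.w2"], params["cls.b"])
    return logits, logits.softmax(axis=-1)


def meta_xai_policy(f_bridge: Tensor, params: ParamDict) -> Tensor:
    """Meta-XAI controller: simplex over the four attribution methods."""
    h = linear(f_bridge, params["xai.w1"], params["xai.b1"]).relu()
    return linear(h, params["xai.w2"], params["xai.b2"]).softmax(axis=-1)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-probability of the true class (from logits)."""
    labels = np.asarray(labels)
    b, k = logits.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels outside [0, {k}): {labels}")
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(b), labels]
    return -picked.mean()


def composite_loss(logits: Tensor, labels: np.ndarray, policy: Tensor | None,
                   quality: np.ndarray | None, lambda_x: float = 0.1) -> Tensor:
    """Cross-entropy plus the explanation-quality auxiliary term.

    ``quality`` holds per-sample, per-method scores in [0, 1] (rows may be
    a subsample of the batch; the auxiliary expectation is taken over the
    rows supplied).  With ``lambda_x == 0`` this is exactly cross-entropy.
    """
    ce = cross_entropy(logits, labels)
    if lambda_x == 0.0:
        return ce
    if policy is None or quality is None:
        raise ValueError("composite loss with lambda_x > 0 needs policy and quality")
    quality = np.asarray(quality, dtype=np.float64)
    if quality.ndim != 2 or quality.shape[1] != len(XAI_METHODS):
        raise ValueError(f"quality must be (n, {len(XAI_METHODS)})")
    if not np.isfinite(quality).all() or quality.min() < 0 or quality.max() > 1:
        raise ValueError("quality scores must be finite and in [0, 1]")
    if policy.shape[0] != quality.shape[0]:
        raise ValueError("policy rows must match quality rows "
                         f"({policy.shape[0]} vs {quality.shape[0]})")
    expected_q = (policy * Tensor(quality)).sum(axis=-1).mean()
    return ce + lambda_x * (1.0 - expected_q)


# -- presentation-layer rule text --------------------------------------------

_DESCRIPTOR_PHRASES = {
    "nc_ratio": "nuclear-to-cytoplasmic ratio is {}",
    "nucleus_size": "nucleus size is {}",
    "chromatin": "chromatin texture is {}",
    "boundary": "cytoplasmic boundary is {}",
}

_BENIGN_LEVELS = {"low", "small", "smooth", "fine", "regular"}


def verbalize_rules(fb_stats: dict[str, float] | None,
                    feature_descriptors: dict[str, str]) -> list[str]:
    """Render illustrative IF-THEN strings from thresholded descriptors.

    This is presentation only: the bridge layer is a differentiable
    fusion, and these templates merely narrate supplied morphology
    descriptors (e.g. from the synthetic generator's ground truth) in the
    fuzzy-rule style a hematopathologist would use.  Deterministic in its
    inputs; an empty descriptor map yields no rules.
    """
    if not feature_descriptors:
        return []
    antecedents = []
    benign_votes = 0
    for key in sorted(feature_descriptors):
        level = feature_descriptors[key]
        phrase = _DESCRIPTOR_PHRASES.get(key, key + " is {}").format(level)
        antecedents.append(phrase)
        if str(level).lower() in _BENIGN_LEVELS:
            benign_votes += 1
    consequent = ("cell is likely benign"
                  if benign_votes * 2 > len(antecedents)
                  else "cell is likely malignant")
    rule = "IF " + " AND ".join(antecedents) + f", THEN {consequent}"
    return [rule + "  [illustrative rendering, not a learned rule]"]
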