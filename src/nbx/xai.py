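"""Post hoc attribution methods and explanation-quality metrics.

Four attributions are implemented from first principles on the package's
autodiff models:

* **Grad-CAM** — channel weights are the spatial mean of the class-logit
  gradient at the last conv block, kappa_m = mean_{u,v} dzeta/dT_{m,u,v};
  the heatmap is ReLU(sum_m kappa_m T_m), bilinearly upsampled.
* **Integrated Gradients** — Gamma = (Q - B) * integral_0^1 of the input
  gradient along the straight path from baseline B (default: black image)
  to input Q, approximated by a midpoint Riemann sum; the completeness gap
  |sum Gamma - (F(Q) - F(B))| is reported alongside.
* **LIME** — a locally weighted sparse linear surrogate over superpixel
  indicator vectors: argmin_v sum_j w_j (H(I'_j) - v.z_j - c)^2 + lambda
  ||v||_1, with proximity kernel w = exp(-d^2 / k^2) on the fraction of
  hidden superpixels.
* **SHAP** — exact Shapley values by subset enumeration for small games
  (theta <= 12) and an expected-gradients estimator (background sampling
  along interpolation paths) at image scale.

Quality is scored either as IoU between the top-mass region of a map and
a ground-truth nucleus mask, or as deletion fidelity (normalised
confidence drop after removing the top-attributed pixels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from skimage.transform import resize
from sklearn.linear_model import Lasso

from ._tensor import Tensor
from .models.bridge import XAI_METHODS

__all__ = [
    "AttributionMap", "grid_segments", "grad_cam", "integrated_gradients",
    "lime_explain", "shap_exact", "shap_gradient", "explanation_quality",
    "select_explanation", "explain",
]


@dataclass
class AttributionMap:
    """Relevance scores for one image and one explained class.

    ``values`` is (H, W) for Grad-CAM, (C, H, W) for gradient methods, or
    (S,) for superpixel methods (with ``segments`` carrying the geometry).
    """

    values: np.ndarray
    method: str
    explained_class: int
    baseline_ref: np.ndarray | None = None
    segments: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def pixel_map(self) -> np.ndarray:
        """Collapse to a (H, W) saliency map (abs-sum over channels)."""
        v = self.values
        if self.segments is not None:
            out = np.zeros(self.segments.shape, dtype=float)
            for s, val in enumerate(v):
                out[self.segments == s] = val
            return out
        if v.ndim == 3:
            return np.abs(v).sum(axis=0)
        return v


# -- shared plumbing ---------------------------------------------------------

def _forward_logits(model, x: Tensor):
    out = model.forward(x) if hasattr(model, "forward") else model(x)
    return out


def _logits_of(out) -> Tensor:
    return out.logits if hasattr(out, "logits") else out


def _input_gradients(model, batch: np.ndarray, class_index: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the class logit w.r.t. each input row; returns (grads, logits)."""
    x = Tensor(batch, requires_grad=True)
    logits = _logits_of(_forward_logits(model, x))
    sel = logits[:, class_index]
    sel.sum().backward()
    return np.asarray(x.grad), sel.data.copy()


def _predict_fn(model, class_index: int):
    if callable(model) and not hasattr(model, "forward"):
        return model
    def h(batch: np.ndarray) -> np.ndarray:
        out = model.forward(Tensor(batch))
        probs = out.probs.data if hasattr(out, "probs") else \
            _logits_of(out).softmax(axis=-1).data
        return probs[:, class_index]
    return h


# -- Grad-CAM ----------------------------------------------------------------

def grad_cam(model, image: np.ndarray, class_index: int) -> AttributionMap:
    """Class-gradient-weighted activation map at the last conv block.

    The model's forward must expose the conv feature map (a live graph
    tensor) as ``feature_map`` on its output bundle.
    """
    img = np.asarray(image, dtype=np.float64)
    batch = img[None] if img.ndim == 3 else img
    x = Tensor(batch)
    out = _forward_logits(model, x)
    fmap = out.feature_map
    if fmap.ndim != 4 or fmap.shape[2] < 1:
        raise ValueError("Grad-CAM needs a spatial conv feature map")
    logits = _logits_of(out)
    logits[0, class_index].backward()
    grads = fmap.grad[0]                          # C x H' x W'
    kappa = grads.mean(axis=(1, 2))               # GAP of the spatial gradient
    cam = np.maximum((kappa[:, None, None] * fmap.data[0]).sum(axis=0), 0.0)
    side = batch.shape[-1]
    cam_up = resize(cam, (side, side), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    return AttributionMap(values=cam_up, method="grad_cam",
                          explained_class=int(class_index),
                          extras={"kappa": kappa, "raw": cam})


# -- Integrated Gradients ----------------------------------------------------

def integrated_gradients(model, image: np.ndarray, baseline: np.ndarray | None = None,
                         steps: int = 64, class_index: int = 0) -> AttributionMap:
    """Path-integrated gradients from ``baseline`` (default black) to ``image``."""
    q = np.asarray(image, dtype=np.float64)
    b = np.zeros_like(q) if baseline is None else np.asarray(baseline, dtype=np.float64)
    if b.shape != q.shape:
        raise ValueError(f"baseline shape {b.shape} != image shape {q.shape}")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    taus = (np.arange(steps) + 0.5) / steps       # midpoint rule
    points = b[None] + taus[:, None, None, None] * (q - b)[None]
    grads, _ = _input_gradients(model, points, class_index)
    avg_grad = grads.mean(axis=0)
    gamma = (q - b) * avg_grad
    # completeness: sum of attributions vs logit difference endpoint-to-endpoint
    ends, _ = _input_gradients(model, np.stack([b, q]), class_index)
    f_b = _logits_of(_forward_logits(model, Tensor(b[None]))).data[0, class_index]
    f_q = _logits_of(_forward_logits(model, Tensor(q[None]))).data[0, class_index]
    gap = abs(float(gamma.sum()) - float(f_q - f_b))
    return AttributionMap(values=gamma, method="integrated_gradients",
                          explained_class=int(class_index), baseline_ref=b,
                          extras={"completeness_gap": gap,
                                  "delta_logit": float(f_q - f_b)})


# -- LIME --------------------------------------------------------------------

def grid_segments(side: int, k: int = 4) -> np.ndarray:
    """Deterministic k x k superpixel grid (segment ids 0..k^2-1)."""
    edges = np.linspace(0, side, k + 1).astype(int)
    seg = np.zeros((side, side), dtype=int)
    for i in range(k):
        for j in range(k):
            seg[edges[i]:edges[i + 1], edges[j]:edges[j + 1]] = i * k + j
    return seg


def lime_explain(model, image: np.ndarray, segments: np.ndarray,
                 class_index: int | None = None, n_samples: int = 64,
                 lambda_l1: float = 0.0, kernel_width: float = 0.25,
                 seed: int = 0, fill_value: np.ndarray | float | None = None
                 ) -> AttributionMap:
    """Sparse linear surrogate over superpixel on/off perturbations.

    ``model`` may be a classifier (probability of ``class_index`` is
    explained) or a callable mapping an image batch to scores.  Masked
    segments are filled with the image mean colour unless ``fill_value``
    is given; ``kernel_width=np.inf`` makes the proximity weights uniform.
    """
    img = np.asarray(image, dtype=np.float64)
    seg = np.asarray(segments)
    n_seg = int(seg.max()) + 1
    rng = np.random.default_rng(seed)
    if class_index is None:
        h0 = _predict_fn(model, 0) if callable(model) and not hasattr(model, "forward") \
            else None
        if h0 is None:
            probs = model.forward(Tensor(img[None])).probs.data[0]
            class_index = int(np.argmax(probs))
        else:
            class_index = 0
    predict = _predict_fn(model, class_index)

    if fill_value is None:
        fill = img.mean(axis=(-2, -1), keepdims=True)   # per-channel mean colour
    else:
        fill = np.asarray(fill_value, dtype=np.float64)

    z = rng.integers(0, 2, size=(n_samples, n_seg)).astype(float)
    z[0] = 1.0                                     # anchor at the original image
    if np.all(z == z[0]):
        raise ValueError("degenerate perturbation design: all samples identical")

    batch = np.empty((n_samples,) + img.shape)
    for j in range(n_samples):
        pert = img.copy()
        hidden = np.isin(seg, np.flatnonzero(z[j] == 0))
        if img.ndim == 3 and img.shape[0] in (1, 3):   # channels-first
            pert[:, hidden] = np.broadcast_to(fill, img.shape)[:, hidden]
        else:
            pert[hidden] = np.broadcast_to(fill, img.shape)[hidden]
        batch[j] = pert
    y = np.asarray(predict(batch), dtype=np.float64)

    d = np.sqrt(np.mean((1.0 - z) ** 2, axis=1))       # fraction-hidden distance
    if np.isinf(kernel_width):
        w = np.ones(n_samples)
    else:
        w = np.exp(-(d ** 2) / kernel_width ** 2)

    if lambda_l1 == 0.0:
        design = np.column_stack([z, np.ones(n_samples)])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        v, intercept = coef[:-1], coef[-1]
    else:
        # scikit-learn's coordinate-descent lasso; alpha matches the
        # (1/2n)-scaled objective convention
        model_l1 = Lasso(alpha=lambda_l1 / (2 * n_samples), fit_intercept=True,
                         max_iter=50_000, tol=1e-8)
        model_l1.fit(z, y, sample_weight=w)
        v, intercept = model_l1.coef_, float(model_l1.intercept_)
    return AttributionMap(values=np.asarray(v), method="lime",
                          explained_class=int(class_index), segments=seg,
                          extras={"intercept": float(intercept),
                                  "kernel_weights": w})


# -- SHAP --------------------------------------------------------------------

def shap_exact(value_fn, n_features: int) -> np.ndarray:
    """Exact Shapley values by full subset enumeration.

    ``value_fn`` maps a tuple of feature indices (the coalition) to a real
    payoff; guarded to ``n_features <= 12`` (2^12 coalitions).
    """
    theta = int(n_features)
    if theta > 12:
        raise ValueError(f"exact enumeration guarded to theta <= 12, got {theta}")
    if theta < 1:
        raise ValueError("need at least one feature")
    values = {}
    players = tuple(range(theta))
    for r in range(theta + 1):
        for sub in combinations(players, r):
            values[sub] = float(value_fn(sub))
    fact = math.factorial
    shap = np.zeros(theta)
    for i in players:
        rest = tuple(p for p in players if p != i)
        for r in range(theta):
            coef = fact(r) * fact(theta - r - 1) / fact(theta)
            for sub in combinations(rest, r):
                with_i = tuple(sorted(sub + (i,)))
                shap[i] += coef * (values[with_i] - values[sub])
    return shap


def shap_gradient(model, image: np.ndarray, background: np.ndarray,
                  n_samples: int = 200, class_index: int = 0,
                  seed: int = 0) -> AttributionMap:
    """Expected-gradients estimator of Shapley values for pixels.

    Each Monte-Carlo draw picks a background image b and an interpolation
    point tau ~ U(0,1); the contribution is (Q - b) * grad F at
    b + tau (Q - b), averaged over draws.
    """
    q = np.asarray(image, dtype=np.float64)
    bg = np.asarray(background, dtype=np.float64)
    if bg.ndim == q.ndim:
        bg = bg[None]
    if bg.shape[0] == 0:
        raise ValueError("background set is empty")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, bg.shape[0], size=n_samples)
    taus = rng.uniform(0.0, 1.0, size=n_samples)
    diffs = q[None] - bg[idx]
    points = bg[idx] + taus[:, None, None, None] * diffs
    grads, _ = _input_gradients(model, points, class_index)
    attr = (diffs * grads).mean(axis=0)
    return AttributionMap(values=attr, method="shap",
                          explained_class=int(class_index),
                          baseline_ref=bg.mean(axis=0),
                          extras={"n_samples": int(n_samples)})


# -- quality metrics ---------------------------------------------------------

def _top_mass_binarize(sal: np.ndarray, frac: float) -> np.ndarray:
    """Binary mask selecting the top-``frac`` fraction of saliency pixels."""
    frac = min(max(frac, 0.0), 1.0)
    if frac == 0.0:
        return np.zeros_like(sal, dtype=bool)
    k = max(int(round(frac * sal.size)), 1)
    thresh = np.partition(sal.ravel(), sal.size - k)[sal.size - k]
    chosen = sal >= thresh
    return chosen


def explanation_quality(att: AttributionMap, mask: np.ndarray | None = None,
                        model=None, image: np.ndarray | None = None,
                        deletion_frac: float = 0.2) -> float:
    """Score an attribution in [0, 1].

    With a ground-truth ``mask``: binarize the saliency at its top-q mass
    (q = mask area fraction) and return the IoU with the mask.  Without a
    mask: deletion fidelity — mask the top ``deletion_frac`` attributed
    pixels and return the normalised drop in the explained-class
    probability.
    """
    sal = att.pixel_map()
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.size == 0 or mask.shape != sal.shape:
            raise ValueError("mask must be a non-empty array matching the saliency")
        frac = mask.mean()
        if frac == 0:
            raise ValueError("empty ground-truth mask")
        chosen = _top_mass_binarize(sal, frac)
        inter = np.logical_and(chosen, mask).sum()
        union = np.logical_or(chosen, mask).sum()
        return float(inter / union) if union else 0.0
    if model is None or image is None:
        raise ValueError("fidelity mode needs the model and the image")
    img = np.asarray(image, dtype=np.float64)
    predict = _predict_fn(model, att.explained_class)
    p0 = float(predict(img[None])[0])
    chosen = _top_mass_binarize(sal, deletion_frac)
    masked = img.copy()
    fill = img.mean(axis=(-2, -1), keepdims=True)
    if img.ndim == 3 and img.shape[0] in (1, 3):
        masked[:, chosen] = np.broadcast_to(fill, img.shape)[:, chosen]
    else:
        masked[chosen] = np.broadcast_to(fill, img.shape)[chosen]
    p1 = float(predict(masked[None])[0])
    if p0 <= 0:
        return 0.0
    return float(np.clip((p0 - p1) / p0, 0.0, 1.0))


def select_explanation(policy: np.ndarray) -> list[str]:
    """Per-sample argmax over the policy simplex (lowest-index tie-break)."""
    pol = np.asarray(policy, dtype=np.float64)
    if pol.ndim == 1:
        pol = pol[None]
    if pol.shape[-1] != len(XAI_METHODS):
        raise ValueError(f"policy rows must have {len(XAI_METHODS)} entries")
    if not np.allclose(pol.sum(axis=-1), 1.0, atol=1e-5) or (pol < -1e-9).any():
        raise ValueError("policy rows must lie on the probability simplex")
    return [XAI_METHODS[i] for i in np.argmax(pol, axis=-1)]


# -- dispatch ----------------------------------------------------------------

def explain(model, image: np.ndarray, method: str = "auto",
            class_index: int | None = None, mask_background: np.ndarray | None = None,
            seed: int = 0, ig_steps: int = 64, shap_samples: int = 200,
            lime_samples: int = 64, segment_grid: int = 4) -> AttributionMap:
    """Compute one attribution, with ``method='auto'`` deferring to the
    model's Meta-XAI policy for this image."""
    img = np.asarray(image, dtype=np.float64)
    bundle = model.forward(Tensor(img[None]))
    if class_index is None:
        class_index = int(np.argmax(bundle.probs.data[0]))
    if method == "auto":
        if bundle.policy is None:
            raise ValueError("model has no Meta-XAI policy head; pick a method")
        method = select_explanation(bundle.policy.data)[0]
    if method == "grad_cam":
        return grad_cam(model, img, class_index)
    if method == "integrated_gradients":
        return integrated_gradients(model, img, steps=ig_steps,
                                    class_index=class_index)
    if method == "shap":
        bg = mask_background if mask_background is not None \
            else np.zeros_like(img)[None]
        return shap_gradient(model, img, bg, n_samples=shap_samples,
                             class_index=class_index, seed=seed)
    if method == "lime":
        seg = grid_segments(img.shape[-1], segment_grid)
        return lime_explain(model, img, seg, class_index=class_index,
                            n_samples=lime_samples, seed=seed)
    raise ValueError(f"unknown method {method!r}")
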