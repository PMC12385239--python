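# nbx — neuro-symbolic bridge classifier for blood smears

`nbx` implements an interpretable image classifier for leukemia
diagnosis from peripheral-blood-smear (PBS) images, at desk scale and
fully offline: a CNN encoder with channel-wise *morphological
attention*, a vision transformer pooled by token-wise *conceptual
attention*, a bounded tanh "logic bridge" fusing the two, a
classifier head, and a **Meta-XAI controller** — a small MLP that
outputs, per image, a probability distribution over four post hoc
attribution methods (Grad-CAM, SHAP, Integrated Gradients, LIME) and
selects the explanation strategy best suited to that input. All four
attribution methods are implemented from their defining formulas, each
validated against an independent oracle (closed forms, finite
differences, exact Shapley enumeration, weighted least squares).

The package is aimed at researchers who want to study this
architecture family and its adaptive-explanation mechanism without the
external Kaggle datasets or a GPU: a seeded synthetic blood-smear
generator produces class-dependent cell morphology **with ground-truth
nucleus masks**, which makes explanation quality (saliency-vs-nucleus
IoU) a measurable training signal rather than a qualitative claim.
Everything — model, training, attributions — runs on a small
self-contained numpy autodiff engine; there is no deep-learning
framework dependency.

## The model in brief

For an image batch `I`:

```
F      = E_cnn(I)                                  # conv stages
w      = σ(W₂ φ(W₁ GAP(F)))                        # morphological gate, φ=ReLU
f_cnn  = GAP(F ⊙ w)
T_L    = τ_L ∘ … ∘ τ₁([t_cls ‖ patches(I)] + P_pos)  # transformer stack
α_i    = softmax_i(v·φ(W T_i));  f_vit = Σ α_i T_i  # conceptual attention
f_br   = tanh(W₂ φ(W₁ [f_cnn ‖ f_vit])) ∈ (−1,1)²⁵⁶ # logic bridge
y      = softmax(W₂ᶜ φ(W₁ᶜ f_br) + b)              # classifier
p_xai  = softmax(W₂ˣ ReLU(W₁ˣ f_br + b₁) + b₂) ∈ Δ⁴ # Meta-XAI policy
```

Training minimises `L_CE + λₓ(1 − E[Σₖ pₖ qₖ])` where `qₖ` is the
measured explanation quality of method *k* (nucleus-mask IoU on
synthetic data). The surrounding protocol is reproduced exactly at the
count level: class-aware augmentation balancing (rotation ≤30°, zoom
≤20%, horizontal flip, brightness 0.8–1.2), stratified fixed 80/20
split, seeded stratified 5-fold cross-validation with per-fold
re-initialisation, and the ablation grid
(`no_bridge`, `no_meta_xai`, `no_morph`, `no_vit`, `cnn_only`).

## Worked example

```python
import numpy as np
from nbx import synthetic
from nbx.models import ModelConfig
from nbx.train import RunConfig, fixed_split, train, evaluate
from nbx.xai import grad_cam, explanation_quality
from nbx.data import load_image, plan_balance

# balancing arithmetic on the four-class ALL-subtype counts
plan = plan_balance({"Benign": 504, "Pre": 963, "Pro": 804, "Early": 985})
print(plan.per_class_deficit)
# {'Benign': 481, 'Pre': 22, 'Pro': 181, 'Early': 0}   -> 3940 images total

# synthetic smears, tiny profile, SGD preset, 10 epochs
manifest = synthetic.generate_dataset(
    synthetic.desk_spec(per_class=200, image_side=64, seed=1), "smears")
tr, va = fixed_split(manifest, frac=0.2, seed=1)
model, hist = train(ModelConfig(side=64), tr, va, "sgd",
                    RunConfig(epochs=10, batch_size=32, seed=1))
print(round(evaluate(model, va).accuracy, 4))
# 0.9625

# does Grad-CAM look at the nucleus?
row = va.iloc[0]
img = load_image(row["path"], 64)
mask = load_image(row["mask_path"], 64).mean(axis=0) > 0.5
cls = int(np.argmax(model.predict_probs(img[None])[0]))
print(round(explanation_quality(grad_cam(model, img, cls), mask=mask), 3))
```

The printed `0.9625` is the validation accuracy on the held-out
stratified 20% (160 images): the pipeline separates the four synthetic
morphology classes almost perfectly within the fixed 10-epoch budget.
The last number is the IoU between the Grad-CAM top-mass region and
the ground-truth nucleus — across 50 validation images its median
(0.158 in this run) exceeds a spatially shuffled control (0.128),
i.e. the trained model's saliency genuinely concentrates on nuclei.

A CLI wraps the same functions:

```bash
nbx generate smears --per-class 200 --side 64 --seed 1
nbx balance --manifest smears/manifest.csv --out balanced --plan-only
nbx train --manifest smears/manifest.csv --out-dir runs/sgd --optimizer sgd
nbx explain --checkpoint runs/sgd/checkpoint.npz --image smears/Pro/Pro_0.png
```

## Layout

| Module | Contents |
| --- | --- |
| `nbx.synthetic` | seeded smear generator, class morphologies, masks |
| `nbx.data` | manifests, balancing plans, augmentation, label encoding |
| `nbx.models` | CNN+gate, ViT+conceptual attention, bridge/heads, configs |
| `nbx.xai` | Grad-CAM, IG, LIME, SHAP (exact + gradient), quality metrics |
| `nbx.train` | splits, optimizers, training loop, CV, ablations, profiling |
| `nbx._tensor`, `nbx.nn` | the numpy autodiff engine and layer helpers |

See `docs/methods.md` for modelling choices, defaults and limitations.
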