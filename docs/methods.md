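# Methods

`nbx` is a desk-scale, fully seeded implementation of a hybrid
neuro-symbolic classifier for peripheral-blood-smear (PBS) images,
together with the class-balancing, training, cross-validation and
explanation machinery around it. This note documents the model, the
numerical choices, the synthetic data the package ships with, and what
the test suite does and does not establish.

## The model

One forward pass computes, for an image batch `I ∈ [0,1]^{B×3×H×W}`
(internally renormalised to `[-1,1]`):

1. **CNN encoder.** A stack of strided conv+ReLU stages produces a
   feature map `F = E(I) ∈ R^{B×C×H'×W'}`. Two backbones exist:
   `tiny` (three stages, ≤32 channels — the profile every test and the
   acceptance run uses) and `paper_b0`, a reduced stack whose final
   stage projects to the 1280-channel width of an EfficientNet-B0
   encoder. `paper_b0` preserves the width contract (pooled vector in
   `R^1280`), not EfficientNet's internal topology; no deep-learning
   framework is a dependency of this package — all models run on the
   package's own numpy autodiff engine (`nbx._tensor`).
2. **Morphological attention.** A bias-free squeeze-excitation gate:
   `z = GAP(F)`, `w = σ(W2 φ(W1 z))` with `φ = ReLU`, and
   `F_att = F ⊙ w` broadcast over space. `w ∈ (0,1)` so the gate only
   attenuates; with zero parameters it halves the map exactly
   (`σ(0) = ½`), a closed form the tests pin down. The hidden width is
   `C/16` (squeeze-excitation convention), configurable. Because the
   gate is bias-free and its input `z ≥ 0` (pooled ReLU output), a
   zero-mean first-layer init can leave every hidden unit dead; `W1` is
   therefore initialised non-negative.
3. **ViT branch.** Non-overlapping `P×P` patches are flattened,
   linearly projected to `D` dims, a learnable class token is
   prepended and learnable positional encodings added
   (`T_0 = [t_cls ‖ X_p] + P_pos`), then `L` pre-norm transformer
   encoder blocks (multi-head self-attention + GELU MLP) refine the
   sequence. Pooling is **conceptual attention** over all `N+1`
   tokens: `α_i = softmax_i(v·φ(W T_i))`, `f_vit = Σ α_i T_i` — a
   convex combination of tokens, not the class token. Profiles:
   `paper` (P=16, D=768, L=6, 8 heads — the depth and head count are
   not pinned by the protocol this reproduces, so they are config, not
   constants) and `tiny` (P=8, D=64, L=2, 4 heads).
4. **Logic bridge.** `f_bridge = tanh(W2 φ(W1 [f_cnn ‖ f_vit])) ∈
   (-1,1)^{B×256}` — the bounded fusion the architecture interprets as
   fuzzy-logic reasoning. Bias-free, matching the printed form; hidden
   width 512 by default.
5. **Classifier head.** `y = softmax(W2^cls φ(W1^cls f_bridge) + b)`
   with hidden width 128 (a free choice). Predicted class = argmax
   with lowest-index tie-break (documented because macro metrics
   depend on it).
6. **Meta-XAI controller.** A 64-hidden-unit MLP with biases mapping
   `f_bridge` to a simplex over the four attribution methods, in the
   fixed order **(grad_cam, shap, integrated_gradients, lime)**.
   Policy indices are meaningless without this order, so it is pinned
   in `nbx.models.bridge.XAI_METHODS` and asserted in tests.

### Training loss

`L = L_CE + λ_x (1 − E[Σ_k p_k q_k])`, where `p` is the policy row and
`q_k ∈ [0,1]` a per-method explanation-quality score. The quality
signal is not specified by the protocol this package reproduces; the
package's choice is: mask-IoU of method *k*'s attribution against the
ground-truth nucleus mask when masks exist (synthetic data always has
them), else a deletion-fidelity score. Quality is computed on a
subsample of each batch (default 4 images) with reduced budgets
(IG 8 steps, 8 expected-gradient samples, 16 LIME perturbations on a
4×4 segment grid) to keep a training step tractable. `λ_x = 0.1` by
default; it is exposed config, not an asserted constant. With
`λ_x = 0` the loss is exactly cross-entropy.

### Optimizers

Three presets mirror the experimental protocol: Nadam (lr 1e-3), SGD
(lr 0.01, momentum 0.9) and "fractional RAdam". The latter is defined
in the source protocol only as RAdam with "fractional decay"; the
package's reading is the RAdam update with a per-step power-law
learning rate `lr_t = lr₀ (1+t)^{-γ}`, `γ = 0.5` by default, and
`γ = 0` reducing exactly to plain RAdam (used as a differential test).
`make_optimizer` returns fresh state per call, so cross-validation
folds are independent by construction.

## Attribution methods

All four are implemented from first principles on the autodiff engine:

* **Grad-CAM**: `κ_m = mean_{u,v} ∂ζ^{(δ)}/∂T_{m,u,v}` at the last
  conv block, heatmap `ReLU(Σ_m κ_m T_m)`, bilinear upsampling to
  image size. Heatmap normalisation to [0,1] is presentation-only and
  never feeds metrics.
* **Integrated Gradients**: midpoint Riemann approximation of
  `Γ = (Q−B) ⊙ ∫₀¹ ∇F(B + τ(Q−B)) dτ`; baseline defaults to the black
  image; 64 steps by default. The completeness gap
  `|ΣΓ − (F(Q)−F(B))|` is computed and returned with every map; the
  midpoint rule makes it O(steps⁻²).
* **LIME**: superpixels are a deterministic k×k grid by default
  (segmentation choice is free in the source protocol; a grid is
  reproducible and test-friendly). Perturbations mask segments to the
  image mean colour; proximity kernel `ω = exp(−d²/k²)` with `d` the
  RMS fraction of hidden segments; the surrogate is weighted
  L1-penalised least squares — scikit-learn's coordinate-descent Lasso
  (tol 1e-8) for `λ>0`, a direct weighted least-squares solve for
  `λ=0`.
* **SHAP**: exact Shapley values by full subset enumeration for games
  with ≤12 features (used for oracle tests and induced superpixel
  games), and an expected-gradients estimator at image scale
  (background image + uniform interpolation point per draw), matching
  the "gradient explainer" formulation.

`select_explanation` is argmax over the policy with lowest-index
tie-break.

## Synthetic blood smears

The real benchmarks (a four-class ALL-subtype set: Benign 504 /
Early 985 / Pre 963 / Pro 804 = 3256 images; and a binary
blast-vs-normal set: 3389 / 7272) are external downloads. The
generator emulates their *structure*: per-class subfolders, a manifest
CSV, the same class counts when asked, and class-dependent cell
morphology. Each image is one leukocyte — a cytoplasm ellipse over a
noisy pale background with a stained nucleus disc plus chromatin
speckle — with the nucleus mask returned exactly as drawn. Class
morphology follows classic cytology: blast-like classes get a larger
nucleus (radius fractions 0.12/0.20/0.28/0.36 across the four
classes), coarser chromatin and a higher nucleus-to-cytoplasm ratio.
These values are free choices of this package, not estimates of the
real datasets (which publish no per-subtype morphometry). Default desk
image side is 64 px (the full protocol trains at 128; both are
supported).

What the synthetic data does **not** emulate: staining physics,
multi-cell scenes, imaging artefacts, intra-class morphological
overlap of real smears. Consequently a high validation accuracy here
shows the pipeline learns the planted morphology signal end-to-end —
it says nothing about accuracy on real PBS images, which the protocol's
headline numbers refer to and which are explicitly out of scope.

## Balancing protocol

`plan_balance` raises every class to the majority count;
`apply_balance` synthesises the deficit by augmenting round-robin over
a seeded shuffle of the class's originals (every original used before
any repeats — minimises duplicate-heavy synthetic sets). Augmentations:
rotation ±30°, zoom ±20%, horizontal flip, multiplicative brightness
0.8–1.2, sampled uniformly from a seeded RNG; rotation/zoom use
reflect padding to avoid black-corner shortcuts. On the printed class
counts this reproduces the printed arithmetic: +481/+22/+181/0 →
3940 total, and +3883 → 14544. Plan-only mode materialises no pixels,
so count-level checks run in seconds. Balance-before-split mirrors the
source protocol; a `split_first` mode exists because balancing before
splitting can leak augmented near-duplicates across folds — neither
behaviour is asserted as the original study's.

## Evaluation harness

Fixed split: stratified 80/20, seeded. Cross-validation: stratified
5-fold (the protocol table says "stratified"), seeded shuffle, model
and optimizer re-initialised per fold, per-fold checkpoints, mean
accuracy = (1/5)Σ fold accuracies. Metrics come from the confusion
matrix; macro = unweighted class mean, weighted = support-weighted;
ROC-AUC is one-vs-rest macro for K>2 and plain binary otherwise.
Undefined precision/recall (a class never predicted or with zero
support) scores 0 with a logged warning — the convention needed to
reproduce degenerate single-class collapse, where a balanced binary
set scored all-one-class gives accuracy 0.5 and macro F1 1/3.

Ablation grid: `full`, `no_bridge` (plain linear projection to 256),
`no_meta_xai` (λ_x=0, no policy head), `no_morph` (gate ≡ 1),
`no_vit` (bridge reads f_cnn alone), `cnn_only` (classifier straight
on pooled CNN features). `profile` reports exact trainable-parameter
counts and a closed-form per-image MAC estimate.

## Numerical choices

* All arithmetic is float64 numpy; runs are deterministic given seeds
  (one RNG stream per generated image keyed by (seed, class, index),
  so generation order is irrelevant).
* Softmax/log-softmax use the log-sum-exp shift; the bridge's tanh may
  saturate to ±1.0 in float64 for extreme pre-activations — the open
  interval is a real-arithmetic property.
* Inputs are zero-centred inside the model (`2x−1`); with `[0,1]`
  inputs and the fixed SGD preset, uncentred pixels destabilised
  training badly in early experiments, and centring is the standard
  normalisation the preprocessing protocol calls for.
* Gradients are clipped to a global L2 norm of 1.0 before each update
  (`RunConfig.max_grad_norm`, settable to `None`). Momentum SGD at the
  fixed preset occasionally takes large steps on this small model and
  oscillates between epochs; global-norm clipping is the standard
  remedy and makes the epoch trajectory monotone-ish without touching
  the printed optimizer presets.
* Initialisation: He-normal fan-in for conv/linear weights, zeros for
  biases, 0.02-std for class/positional tokens, non-negative first
  gate layer (see above).
* Degenerate inputs raise: empty manifests, singleton classes at
  split time, zero counts, out-of-range morphology or augmentation
  parameters (errors name the offending field), unknown labels at
  transform time, >12-feature exact Shapley.

## Problem sizes

Tests and the acceptance script use the `tiny` profile at 64 px with
4×200 images (stratified 20% validation), 10 epochs, batch 32 — the
point where a full run finishes in minutes on one CPU while every
component (both branches, gate, bridge, policy, quality-in-the-loss)
is exercised. The localization measurement uses 50 validation images.
Oracle tests run on 4–8-feature games and ≤8×8 fixtures.

## Known limitations

* `paper_b0` is width-faithful, not EfficientNet; parameter counts of
  the full-scale architecture therefore do not reproduce the published
  ~51 M figure, which also depends on unstated ViT depth/heads. The
  profiling op reports counts; none is asserted against that figure.
* The ViT is trained from scratch; no pretrained weights exist for
  either branch.
* Grad-CAM IoU against the nucleus mask is modest in absolute terms
  (the last conv map is 8×8 at desk scale); the asserted property is
  relative — real maps beat spatially shuffled controls.
* LIME's λ>0 path inherits scikit-learn's `alpha` scaling convention
  (the package maps `λ/(2n)`); exact-value tests therefore pin the
  λ=0 closed form and use λ>0 only for sparsity behaviour.
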