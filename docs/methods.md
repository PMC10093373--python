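# Methods

This note documents the models implemented in `mafcnn`, the choices made
where the underlying method descriptions leave details open, and what the
synthetic study conditions do and do not demonstrate.

## Problem setting

Dermoscopic skin-lesion classification: given RGB lesion images and class
labels (e.g. melanoma / seborrheic keratosis / nevus), learn a classifier
and report per-class and macro accuracy, sensitivity, specificity, F-score
and MCC on a stratified 70/30 split. The pipeline has four stages: adaptive
Wiener denoising, a CoT-attention CNN ("MAFNet") used as a feature
extractor, Henry Gas Solubility Optimization (HGSO) for the extractor's
training hyperparameters, and a deep belief network (DBN) classifier on the
extracted features.

## Wiener pre-processing

Each channel is filtered independently with

    out(x,y) = in(x,y) − (σ_n² / σ_L²(x,y)) · (in(x,y) − μ_L(x,y)),

where μ_L and σ_L² are the mean and variance over an odd square window
(default 3×3, reflect borders) and σ_n² is the global noise variance. As
printed, the shrinkage ratio is unbounded when the local variance is small;
the only reading consistent with the filter's limiting behaviour
(identity when σ_n² = 0, local mean when σ_L² ≈ σ_n², identity when
σ_L² ≫ σ_n²) is the classical clamped form, so the ratio is clamped to 1
wherever σ_L² ≤ σ_n² — this also removes the division by zero in flat
windows. `auto` noise variance uses the mean of the local variances, the
standard estimator. The implementation is vectorised with
`scipy.ndimage.uniform_filter`; tests verify exact agreement (1e-10) with a
literal per-pixel double loop.

## MAFNet

A residual CNN: 1×1 convolution stem → four stages of bottleneck modules
distributed [2,2,2,2] → global average pooling → a fully-connected feature
layer (the extracted representation) → dropout → softmax head. Each
bottleneck is 1×1 reduce / spatial operator / 1×1 expand with a residual
connection; stages 2–4 halve resolution with 2×2 average pooling. The
spatial operator is a Contextual Transformer (CoT) block: a grouped 3×3
convolution produces static contextual keys; a two-layer 1×1 convolution on
the concatenated [keys, input] emits one attention logit per 3×3
neighbourhood position; a softmax over the nine positions weights the
unfolded value embedding; static and dynamic paths are summed. The
published CoT design shares its attention map across channel heads — here a
single head is used, a deliberate desk-scale simplification. Plain 3×3
convolutions are available for ablation (`use_cot=False`); both variants
have identical shapes and module counts, different parameter counts.

Counting the stem, three convolutions per bottleneck and the FC head as
"convolution modules", the default configuration has 1 + 3·8 + 1 = 26; the
count is exposed via introspection and follows the configured composition.

Training: softmax cross-entropy (probabilities floored at 1e-12 before the
log), SGD with momentum 0.9 (the simplest optimizer consistent with a bare
learning-rate schedule), and the step schedule lr = lr0 · 0.1^⌊epoch/30⌋ —
the exponent is floored because the decay is specified "per 30 epochs".
Default channel widths (8, 16, 32, 64), 32 px inputs and a 64-d feature
layer are desk-scale choices; all are configurable. The classifier head is
initialised near zero so the untrained network predicts approximately
uniformly (initial loss ≈ log K). Everything runs on a package-internal
reverse-mode autodiff core over numpy (`mafcnn._autodiff`), whose
primitives are validated against central finite differences in the test
suite; with a fixed seed, training is bit-reproducible in a single-threaded
run.

The network is trained on the classification task and then used as a
feature extractor (penultimate activations) — consistent with the FC head's
stated classification role during training.

## HGSO

Implemented as a general bounded minimizer. Per iteration t (T(t) =
exp(−t/max_iter), T_θ = 298):

- Henry coefficient: H_j ← H_j · exp(−C_j (1/T(t) − 1/T_θ)) — strictly
  decreasing for C_j > 0 since T(t) < 1 ≪ T_θ.
- Solubility: S_ij = K · H_j · P_ij.
- Position update toward the cluster best and the solubility-scaled global
  best, with γ = β · exp(−(F_best+ε)/(F_ij+ε)), ε = 0.05.
- Worst-agent renewal: Nw = round(N(rand(C₂−C₁)+C₁)) agents (C₁ = 0.1,
  C₂ = 0.2; round half to even, clamped to [1, N]) re-seeded uniformly.

Init constants l₁ = 5·10⁻², l₂ = 100, l₃ = 10⁻²; α = 1; β and K default
to 1 (only described as "fixed values"). The direction flag F in the
position update is undefined in the source description; it is a ±1 flag
resampled per agent per iteration, the convention of the original HGSO
publication. Fresh U(0,1) draws are used for each stochastic term (the
symbol r is reused ambiguously in the source). Positions are clipped to the
bounds after every move; the best-so-far archive makes the convergence
history monotone. Defaults N = 30, 5 clusters, 100 iterations.

Hyperparameter tuning minimises the misclassification percentage
(100 · wrong/total) of the extractor+DBN on an inner 70/30 validation split
(a single split, the default; cross-validation can be layered on top by the
caller). The search space spans lr0 ∈ [1e-4, 1e-1] (log), batch size
{2..64}, epochs {5..50}, dropout [0, 0.7], which contains the reference
setting (0.01, 5, 50, 0.5). Integer dimensions decode by rounding to the
nearest valid value; log dimensions live on a log10 scale so the search is
uniform in magnitude. Fitness evaluations cap epochs at `proxy_epochs`
(default 3) and use a lightened DBN schedule; the final model retrains at
the winning settings' full budget.

## DBN

Bernoulli RBMs with energy E(v,h) = −a·v − b·h − vᵀWh (a indexes visible
units, b hidden — the consistent reading of the stated parameterisation).
The partition function is computed exactly by enumeration for n+m ≤ 20,
which powers the oracle tests (normalisation, conditionals, and the CD
learning signal measured as exact log-likelihood).

Training is CD-k (default k = 1): hidden states are sampled from p(h|v),
visible reconstructions use mean-field probabilities, and updates are plain
minibatch gradients without momentum. Greedy stacking feeds each RBM the
previous layer's hidden probabilities; three hidden layers by default
(widths 256/128/64, capped at 4× the feature dimension for desk-scale
feature sets). A multinomial logistic output layer is attached and the
whole stack is fine-tuned by backpropagated cross-entropy (SGD momentum
0.9), initialised from the RBM weights. Continuous features are min–max
rescaled to [0,1] and treated as visible activation probabilities;
Gaussian visible units are out of scope. Default learning rates (0.5 for
both CD and fine-tuning) are comparatively high because the visible
dimensionality is small and inputs are in [0,1]; with the conventional 0.1
the stack underfits noticeably at these widths and epoch counts.

## Evaluation protocol

Per-class metrics are one-vs-rest (class k positive, rest pooled):
accuracy (TP+TN)/N, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
F-score 2TP/(2TP+FP+FN), MCC (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Zero-denominator metrics are defined as 0. The "average" row is the
unweighted (macro) mean — the natural reading of an equal-weight average
row, and per-class accuracy/specificity are only meaningful one-vs-rest.
The 70/30 split is stratified: per-class training counts are floored and
remaining slots go to the largest fractional remainders (ties to the larger
class). Display tables use the 0–100 scale with two decimals.

## Synthetic data

Each class is a prototype of (asymmetry, border irregularity, colour,
scale): a rotated super-ellipse (exponent 2.5) whose boundary radius is
modulated by `1 + 0.18·irregularity·sin(5θ+φ)`, filled with the class
colour on a skin-toned background, plus additive Gaussian pixel noise
(clipped to [0,1]). Colours come from a palette with pairwise L∞ distance
≥ 0.35 before a ±0.05 seeded jitter, so any two prototypes differ by ≥ 0.2
in some channel and a nearest-centroid classifier on mean RGB already
separates noiseless classes — by construction the study conditions are
learnable, which is what makes the end-to-end check meaningful. The
star-shaped geometry guarantees a single connected lesion occupying 5–60%
of the image across the admissible parameter ranges.

What this does not emulate: hair and ruler artifacts, illumination
gradients, intra-class colour variegation, multi-focal lesions, or
dermoscopy-native resolution. Passing the end-to-end criteria therefore
demonstrates that the implementation is correct and the stages compose —
not that the pipeline reaches any particular accuracy on real dermoscopy
corpora. Loaders for the real datasets accept a flat image directory with
a `filename,label` CSV manifest.

## Study-condition sizes and numerical choices

The end-to-end study uses 3 classes × 60 images at 64 px (resized to the
extractor's 32 px input before filtering), HGSO with 6 agents × 5
iterations, and the reference settings for the no-tuning ablation — sizes
chosen so a complete run finishes in minutes on one CPU core.
Miscellaneous numerics: softmax is shift-stabilised; cross-entropy floors
probabilities at 1e-12; the worst-agent count rounds half to even after
suppressing floating-point noise at the 1e-9 level; metric and RBM oracle
comparisons use absolute tolerances of 1e-12 and 1e-10 respectively;
fitness ties in cluster ranking resolve to the lowest agent index.

## Known limitations

- CPU-only, float64, small models: not intended for the full public
  corpora at native resolution.
- Single-head CoT attention (see above).
- Bernoulli-only RBMs; no persistent CD or wake–sleep fine-tuning.
- Bit-reproducibility is guaranteed within one platform/BLAS build, not
  across different numerical libraries.
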