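# Methods

This note records the model, the estimators, the defaults and the numerical
conventions implemented in `graphuq`, and what the synthetic benchmark does
and does not establish.

## Acquisition model and transforms

An observed graph is treated as a node-permuted copy of the true graph with
additive Gaussian noise on a random subset of feature rows:
X_obs = P X̃ + ε, A_obs = P Ã Pᵀ. The permutation ξ is uniform over all
|V|! orderings; the noisy subset has exactly round(f·|V|) nodes (f the
`noisy_fraction`) and its rows are i.i.d. N(0, σ²) per channel. The
transform is exactly invertible — subtract ε, apply ξ⁻¹ — and the package
asserts bitwise adjacency round-trips. Noise is applied to features only;
keeping the adjacency binary is what makes the inverse exact, so all
adjacency randomness is carried by the walk resampler instead.

The default noise scale is σ = 0.1 × (mean per-feature standard deviation
of the training set) (`default_noise_sd`). This is a scale-free choice: the
perturbation is always small relative to the natural feature spread,
whatever the featurization.

**Structural resampling.** The edge set is resampled as the union of edges
traversed by R random walks of length W with restart probability r
(defaults R=20, W=10, r=0.1). Start nodes are uniform; at each step a
restart uniform is drawn, then a uniform neighbor. This construction only
*drops* edges — the resampled edge set is a subset of the observed one, and
converges to it as R·W grows on a connected graph. A mechanism that also
proposes unobserved edges (e.g. triadic closure) would be a natural
extension; the sampler is the module's single extension point
(`structural_uncertainty(sampler=...)`).

## Classifier and parameter decoder

The classifier is an L-layer GCN: each layer computes
ReLU(D^{-1/2}(A+I)D^{-1/2} · H · W_l + b_l), followed by mean readout, a
linear head and softmax. Symmetric normalization with self-loops plus mean
readout makes the network permutation-invariant at graph level and the
saliency permutation-equivariant — the property that makes pushing saliency
maps through ξ meaningful. Default backbone: 2 layers of width 16.

The decoder q_θ(Ω|z) is a feed-forward network z → Ω with Sigmoid hidden
activations and hidden sizes 512/256/128 (defaults). Because Sigmoid
outputs are nonnegative and GNN weights need both signs, the final output
is squashed by a Sigmoid and affinely rescaled to (−s, s), s=1 by default.
q_θ(Ω|z) = N(mean_θ(z), σ_Ω² I) with σ_Ω fixed (default 0.05); latent
dimension 16.

**Loss.** The KL between the implicit mixture E_z[q_θ(Ω|z)] and the
standard-Gaussian prior is intractable, so training minimizes the Jensen
upper bound E_z KL[q_θ(Ω|z) ‖ N(0,I)], which is closed-form per z-sample
and upper-bounds the mixture KL, so minimizing it minimizes the intended
objective. At σ_Ω = 0 the divergent constant is dropped and the penalty
degrades gracefully to ‖mean_θ(z)‖²/2. The likelihood term applies a
freshly sampled inverse transform to each training graph per Monte-Carlo
draw; γ (default 0.1) balances the KL against the summed per-batch
log-likelihood. Optimization is Adam at learning rate 0.001; per-step MC
sizes default to 2 latents × 2 transforms. Training variants: `no_transform`
(identity transforms during training) and `point` (decoder removed, one
weight vector optimized directly under the same Gaussian prior — a plain
GCN; with `dropout_rate > 0` its weight draws become a Monte-Carlo
weight-dropout comparator).

## Saliency

Node saliency is graph Grad-CAM: α_k = (1/|V|) Σ_n ∂y^c/∂H_{n,k} over the
final message-passing layer's embeddings H, S_n = ReLU(Σ_k α_k H_{n,k}).
y^c is the pre-softmax logit (standard Grad-CAM practice; post-softmax
gradients vanish at confident predictions). Edge saliency is
|∂y^c/∂A_{ij}| with the derivative taken through the degree normalization
(the normalized adjacency depends on every entry's row/column sums), then
symmetrized as (s_ij + s_ji)/2 and optionally masked to the edge support.
Both are validated against central finite differences in the tests. A
`rectify=False` switch exposes the pre-ReLU Grad-CAM score, whose
distribution under Gaussian feature noise is itself Gaussian — that is the
quantity with the closed-form variance used as an analytic oracle.

## Uncertainty estimators

* **Measurement**: elementwise variance of T_ξ(g(T_ξ⁻¹(X−ε), Ã, Ω)) over I
  transform draws, Bessel-corrected (1/(I−1)), with the MC mean reported
  alongside.
* **Structural**: same over I walk-resampled graphs.
* **Decomposition**: a J×K grid of saliency maps — J weight draws from the
  decoder, K data draws (transform, walk resample, or both; default both).
  aleatoric = mean over j of within-row variance, epistemic = variance over
  j of row means, total = grand variance. The law of total variance makes
  total = aleatoric + epistemic **exactly** under uncorrected (1/N)
  moments; the package asserts the identity to 1e−10 and reports
  Bessel-corrected versions alongside for comparability with the
  single-source estimators.
* **Common random numbers**: the K data draws are shared across the J
  weight draws. This leaves both marginal estimators unbiased while making
  a degenerate (point-mass) posterior show exactly zero epistemic variance,
  rather than zero-plus-MC-noise.
* **Prediction uncertainty**: the population (ddof=0) variance of the
  predicted-class probability across the J·K per-sample predictive vectors.
  Per-class variances are returned; the scalar used for ROC ranking is the
  predicted class's. For explanation-level detection the per-element total
  variance is used. No distributional assumptions are made anywhere — the
  ReLU makes saliency non-Gaussian, so everything is sample-based.

## Evaluation conventions

* Misclassified samples are ROC positives; AUC is the trapezoidal/
  Mann-Whitney statistic (scikit-learn), cross-checked in the tests against
  exhaustive pair counting.
* Explanation binarization: min-max normalize each map, threshold at 0.5
  with ≥ counting positive, computed in the symmetric form
  (v − lo) ≥ (hi − v) with a 1e−9·(hi−lo) tolerance so exact midpoints
  survive binary rounding; constant maps binarize to all-zeros.
* Explanation detection: an element is "wrong" when its binarized saliency
  disagrees with the truth mask; elements are pooled across graphs, AUC is
  computed from the chosen per-element variance, and ACC is taken at the
  median-uncertainty threshold (the protocol reports a score-based detector
  without a canonical threshold; the median is deterministic and
  prevalence-free).
* Noise robustness: Gaussian noise on 0/5/10% of each test graph's nodes,
  ACC/AUC/F1 over replicates (default 10), AUC ranked by the positive-class
  mean predictive probability.

## Synthetic benchmark

`generate_motif_dataset` emulates the structure the method assumes about
molecular property data: binary labels driven by a small substructure, and
features observed with noise. Label-1 graphs are Erdős–Rényi backgrounds
(edge probability 0.15, 8–16 nodes) with a planted 4-clique whose members
get a +1.0 shift on feature channel 0; label-0 graphs are pure background;
features carry N(0, 0.5²) noise; classes are balanced. The clique's nodes
and edges are the ground-truth explanation masks. Defaults were fixed once
as a realistic desk-scale analogue — signal-to-noise of 2 on the shifted
channel, motif occupying roughly a third of a small graph — and the
end-to-end checks run at 500 graphs with the 2-layer backbone, which keeps
the full pipeline (training included) at a few minutes on one CPU.

What passing the synthetic checks shows: the estimators, the decomposition
identity, the equivariance contracts, and the *directional* claims —
uncertainty is higher on misclassified graphs, uncertainty-based detection
beats chance, accuracy degrades under corruption. What it does not show:
performance on real molecular data. Real datasets have skewed scaffold
distributions, label noise, and far richer chemistry than the one-hot
featurization of the planted-motif task; the molecule I/O and scaffold
splitting are tested for contract correctness, not benchmark numbers.

## Numerical and degenerate-input conventions

* All randomness flows through `numpy` Generators seeded explicitly;
  training spawns independent streams for init, stepping and evaluation
  from one `SeedSequence`, so every run is bit-reproducible from its seed.
* Variances of exactly constant samples are returned as exact zeros.
* Walk sampling on an edgeless graph returns the input with a warning; R=0
  returns an edgeless graph.
* Softmax is computed via a max-shifted log-softmax; probabilities sum to 1
  within 1e−6 and gradients are exact.
* Ties in split sizing: remainders go to train, then valid. Grouped splits
  assign groups largest-first to the split with the largest remaining
  deficit — optimal for desk-scale group structures and verified against
  brute-force enumeration in the tests.

## Known limitations

* The walk resampler cannot propose unobserved edges, so "missing edge"
  structural uncertainty is only probed by deletion.
* The decomposition's aleatoric term inherits whatever data-randomness mix
  the caller configures; measurement and structural contributions are only
  separated by the dedicated single-source estimators.
* The decoder outputs weights in (−s, s); functions requiring larger
  weights need `weight_scale` raised, which also rescales the KL geometry.
* Multi-class outputs are supported by the types but all shipped defaults
  and experiments target binary classification.
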