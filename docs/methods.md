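# Methods

`medmat` learns material categories and machine-discovered material
attributes from grayscale radiography-style images. This note records the
models, the conventions chosen where several readings were possible, the
defaults and why, and what the synthetic test bed does and does not show.

## Patch selection and categorization

Images are min-max normalized to [0, 1] (negatives inverted first; a
constant image degenerates to all zeros with a warning). Candidate patches
are 32×32 squares anchored below and to the right of grid points spaced
`grid_spacing` pixels apart (top-left, 0-based, half-open extent). Each
candidate is assigned by rules evaluated in a fixed order:

1. **null** — average brightness B̄ < `b_null`; evaluated first, so a very
   dark patch is null even if its brightness also clears the window;
2. otherwise the patch must satisfy B̄ ∈ [`b_min`, `b_max`] or be rejected;
3. **expert** — mask coverage ≥ 1 − T, where T is the mask tolerance;
4. **naïve** — mask coverage ≤ T; the naïve category is bound per source
   image (per modality), e.g. "bone" for knee X-rays;
5. coverage strictly between T and 1 − T straddles the mask boundary and is
   rejected: mixed-material patches would blur the categories.

Requiring T < 0.5 (asserted at configuration load) makes the expert and
naïve rules mutually exclusive. Module defaults: `b_null` = 0.05,
`b_min` = 0.1, `b_max` = 0.95, T = 0.05, `grid_spacing` = 8; all
overridable per modality at run time. Sampling is round-robin balanced
across categories; every kept patch originates from a unique
(image, x, y). With `n_target=None` the generator enumerates every grid
point deterministically — the mode the oracle-equivalence test exercises.

## Siamese similarity network and the distance matrix

A shared-weight convolutional encoder embeds both patches of a pair; the
head takes the **absolute elementwise difference** of the embeddings
through two fully connected layers and a sigmoid. The absolute difference
makes the prediction exactly symmetric in pair order. Output ŷ ∈ (0, 1):
0 = same category, 1 = different; the decision threshold is 0.5. Training
minimizes binary cross-entropy over pair decisions (predictions clamped to
[1e−7, 1 − 1e−7] before the logs). Comparison samples hold one reference
patch plus K comparisons, one per category in shuffled order, exactly one
of them same-class; reference classes are balanced across samples.

After every epoch the validation loss is measured; whenever it reaches a
new minimum the weights are snapshotted together with the distance matrix
computed from that epoch's validation decisions, so the saved matrix always
corresponds to the saved weights.

Two aggregations of the decisions are provided:

* **scalar** (default): pooled different-rate per comparison category,
  `D[k,k'] = |p_k − p_k'|`;
* **profile**: per-reference-category K-vectors of pooled rates,
  `D[k,k']` the Euclidean distance between profiles.

The scalar pooling has a structural blind spot: with balanced reference
classes, symmetric confusion between two categories moves both pooled
rates toward (K−1)/K by the same amount, so most of the confusion signal
cancels and D is nearly degenerate whenever the network is accurate. The
profile variant retains the reference-class information. The library
default stays scalar; the end-to-end study feeds the **profile** matrix to
the attribute stage and states so in its provenance.

## Attribute discovery

Given a K×K distance matrix D, the K×M matrix A (rows = category attribute
probability vectors, entries in [0, 1]) minimizes

    Σ_{k,k'} (‖a_k − a_k'‖₂ − D_{kk'})² + γ Σ_{p∈P} β(p) ln(β(p) / q(p; A))

with β the Beta(0.5, 0.5) (arcsine) density — attributes should be strongly
present or absent, rarely lukewarm — and q the equal-weight Gaussian KDE of
the entries of A with bandwidth h. Conventions and defaults:

* the pair sum runs over **ordered** pairs (each unordered pair twice); the
  constant factor does not move the argmin;
* `a_k` is **row** k of A (category k's attribute vector);
* P is 101 equispaced points on [0.005, 0.995], chosen to stay clear of the
  unbounded Beta endpoints; the grid-spacing factor of the Riemann sum is
  absorbed into γ's scale;
* h = 0.1: wide enough to smooth K·M ≈ 16 entries on a unit interval,
  narrow enough to resolve bimodality;
* optimization is box-constrained L-BFGS-B on the raw entries with an
  analytic gradient (verified against finite differences in the tests),
  best of 5 restarts, entries initialized i.i.d. uniform on [0.1, 0.9] so
  the first KL evaluation avoids the density's endpoints;
* q is floored at 1e−12 before the log.

At γ = 0 the optimizer is a pure metric-embedding solver; the tests verify
it reproduces the pairwise distances of known point configurations to
RMS ≤ 1e−2 (the points themselves are identifiable only up to isometry).

## Category+attribute network

A convolutional backbone feeds a category head of two fully connected
layers — 512 then 2048 wide, narrow-then-wide as specified for the
reference architecture (a `swap_head` flag reverses the order) — ending in
K logits. One auxiliary classifier per backbone stage response, plus the
stem's pooled response, maps its globally pooled feature vector through a
two-layer **clipped-linear** head `h(W₂ h(W₁x + b₁) + b₂)`, h clamping to
[0, 1] with hidden width 64; a combiner of the same form merges the
concatenated stage predictions into the final M attribute probabilities.
The clipped-linear activation passes gradient only on (0, 1), so hidden
biases start at 0.5 and the weight init gain is reduced (0.35): units that
start or drift outside the band receive no gradient and die — the
zero-variance-attribute failure mode the tests watch for.

The loss has three terms: the batch-averaged negative log-likelihood of the
softmaxed category predictions; γ₁ times the KL divergence from the Beta
target to the Gaussian KDE of the batch's attribute predictions (same P
grid and bandwidth as the attribute stage); and γ₂ times the squared error
between each category's row of the fixed A and the mean attribute
prediction over that category's samples in the batch (absent categories
contribute nothing). The category term is *averaged*, not summed: the
attribute terms are per-category means whose magnitude does not grow with
the batch, so a summed category term would make their relative weight
vanish at realistic batch and set sizes.

Training uses Adam, batches of 50, 15 epochs, best-validation checkpoint,
and a scheduler that divides the learning rate by exactly 10 after any
epoch in which validation loss rose. Defaults follow the published recipe
(initial rate 1e−4 for the category+attribute network, 1e−3 for the
Siamese network; γ₁ = 1e−2, γ₂ = 1). The 1e−4 default presumes a
pretrained backbone; the end-to-end study trains from random
initialization and uses 1e−3 (Siamese) and 1e−3 (MAC), where the smaller
rate demonstrably underfits within the 15-epoch budget.

## Neural-network core

Training runs on a small reverse-mode automatic-differentiation core over
NumPy arrays written for this package: dense and 3×3 same-padding
convolutional layers (im2col via `sliding_window_view` + `einsum`), 2×2
average pooling, global average pooling, ReLU/sigmoid/clamp
nonlinearities, broadcasting arithmetic with gradient un-broadcasting, a
numerically shifted log-softmax, and Adam. Every primitive is
gradient-checked against central finite differences in the test suite.
Two backbones are provided: `tiny` (stem + four plain conv blocks,
~100K parameters — the default and the tested configuration) and `resnet`
(a small residual variant for larger category sets). All computation is
float64 and deterministic given the seed: same-seed runs produce identical
training histories.

## Synthetic test bed

The generator emulates the structure of annotated radiographs: a
near-black background frame (brightness 0.02), a textured tissue square,
and, on lesion-bearing scenes, a brighter masked disk. Textures are value
noise on a lattice ("speckle", the spongy-bone stand-in), white noise
("smooth"), or sparse smoothed bumps ("blob"), each clipped to [0, 1]
after scaling to the spec's mean and amplitude. Scenes are pure functions
of (config, seed).

The four-category study uses two synthetic modalities mirroring how real
datasets bind one naïve category per modality: tissue-A scenes (with and
without a masked lesion, as tumor datasets mix scans with and without
findings; naïve category "tissue_a") and plain tissue-B scenes. Tissues A
and B are the designed similar pair — mean brightness 0.47 vs 0.53 and the
same speckle pattern at different lattice scales — far closer to each
other than either is to the background (0.02) or the lesion (0.75), while
remaining learnable: the regime in which the real system distinguishes
perceptually similar tissues at ~92%. Study scale: 85 scenes of 160×160,
~2000 balanced patches split 60-20-20, the `tiny` backbones, 500
comparison samples per epoch, raised study constraint `b_min` = 0.30 so
patches straddling the background frame are rejected rather than polluting
the tissue categories.

What passing the synthetic study shows — and does not. It shows the full
pipeline is wired correctly end to end: the similarity network learns pair
decisions from patches alone, confusions concentrate on the designed
similar pair, the profile distance matrix recovers the designed ordering,
the attribute matrix respects it, and the joint classifier reaches high
held-out accuracy with attributes that separate categories better than raw
pixels. It does not show clinical performance: real radiographs have
anatomy-scale structure, intensity inhomogeneity, acquisition artifacts,
inter-patient variation, and expert masks with genuinely ambiguous
boundaries, none of which the generator models.

## Numerical choices and degenerate inputs

* Probabilities are clamped to [1e−7, 1 − 1e−7] before logs; KDE values
  floored at 1e−12; log-softmax shifted by the row max.
* A constant-valued image normalizes to all zeros with a logged warning;
  an absent mask yields mask fraction 0 by convention.
* Zero-variance attributes or categories produce NaN (missing) correlation
  entries, logged, never silently 0.
* Silhouette comparisons are computed on seeded 2-D stochastic-neighbor
  embeddings; identical features or a single category raise instead of
  returning an undefined score.
* Distance matrices are validated on construction (symmetry, zero
  diagonal, non-negativity); the profile variant symmetrizes away the
  ~1e−16 float asymmetry before validation.

## Known limitations

* The scalar distance reading carries little signal at high accuracy (see
  above); analyses that need a structured D should use the profile mode.
* The clipped-linear attribute heads can still lose units on aggressive
  schedules; the init mitigates but does not eliminate this.
* The `resnet` backbone is provided for larger problems but the study and
  the acceptance checks run the `tiny` configuration; pretrained encoder
  weights can be loaded from a file but no weights ship with the package.
* Sliding-window maps are reported raw — no smoothing or structured
  post-processing — so isolated misclassified cells are expected and
  visible, matching the per-patch nature of the classifier.
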