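# Methods

This note records the models implemented in `eagledrp`, the parameter
choices that matter, what the synthetic data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Non-negativity-constrained sparse autoencoder (NNCAE)

A single-hidden-layer autoencoder with logistic-sigmoid encoder and
decoder, untied weights, and the cost

J = J_recon + β·Σ_j KL(p ‖ ρ̂_j) + Σ_{layers} Σ_{ij} f(w_ij),

* **J_recon** — mean over samples of the squared reconstruction error
  (sum over features).  Inputs are expected in [0, 1]; the preprocessing
  pipeline scales features there before training (see below).
* **KL sparsity** — Bernoulli divergence between the target activation
  rate p and each unit's batch-mean activation; the standard form for
  sparse autoencoders (the divergence couples samples in a batch, which
  the analytic gradient accounts for).  Mean activations are clipped to
  [1e−12, 1−1e−12] before the divergence; the clip is treated as flat in
  the gradient.
* **Composite decay f(w)** — zero for w ≥ 0 (the boundary w = 0 sits on
  the zero branch); for w < 0 it is α₁·⌈(w, k) + (α₂/2)·w², where
  ⌈(z, k) = ‖z‖ for ‖z‖ > k and ‖z‖²/(2k) + k/2 otherwise.  The smoothed
  L1 restores differentiability at the origin; both branches and their
  gradients agree at the seam ‖z‖ = k.  Biases are never penalized.

Training is mini-batch gradient descent with a fixed step ε; the exact
analytic gradient is verified against central finite differences
(≤ 1e−5 relative) in the test suite for random hyperparameter draws.

**Defaults** (`NNCAEConfig`): p = 0.05, β = 3, α₁ = 3e−4, α₂ = 3e−3,
k = 0.1, ε = 0.1, batch 32 — a conventional sparse-autoencoder working
set for unit-interval inputs; none of these has a theoretically forced
value and all are exposed.  The *pipeline* overrides the feature-learning
settings (36 hidden units, p = 0.2, β = 0.1, ε = 0.3, 900 epochs):
feature extraction ahead of a classifier wants the code to retain every
reconstructable direction, and strong KL pressure makes the encoder drop
low-loading directions — which can include the class signal — while
undertrained encoders turned out to be the dominant source of
seed-to-seed variation in downstream accuracy, hence the mild sparsity
and the longer schedule.

**What the penalty does — and what it does not.**  Increasing α₁ = α₂
over {0, 1e−4, 1e−3, 1e−2} monotonically shrinks the *negative weight
mass* Σ|min(w, 0)| (tested).  It does not reliably reduce the *count* of
negative entries: the smoothed penalty's force vanishes as w → 0⁻, so
gradient flow compresses negative weights toward zero without pushing
them across, and under KL pressure (positive-mean inputs) the shrunken
negatives are compensated by a slight downward drift of all weights.
Negative mass, not sign count, is the meaningful measure of
non-negativity pressure here.

## Preprocessing pipeline

Fixed stage order: **detect → impute → scale → train NNCAE → flag
outliers → balance**.  No feature or sample is ever dropped from a table;
outlier-flagged rows are merely excluded from classifier training.

* **High-missingness detection** flags columns with strictly more than
  1/3 missing cells (reported; imputation treats them like any other
  column).  The rule is per column.
* **KNN imputation** (k = 5 default) replaces each missing cell by the
  uniform mean of the feature over the k nearest rows, with nan-aware
  Euclidean distance normalized by the number of mutually observed
  features (delegated to scikit-learn's `KNNImputer`, whose distance is a
  monotone transform of that definition and therefore selects the same
  neighbours).  Degenerate cases: an all-missing column imputes to 0 with
  a warning; a row with no shared observed features falls back to column
  means.
* **Scaling** maps each feature onto [0, 1] by its 1st–99th percentile
  range (clipped).  A plain min–max map would let a handful of extreme
  rows compress the data bulk into a sliver of the unit interval and
  starve the sigmoid autoencoder of dynamic range.
* **Outlier flagging** computes per-row NNCAE reconstruction errors and
  flags rows whose robust z-score — (e − median)/(1.4826·MAD) — exceeds
  z_cut = 3.  The robust centre/spread is essential: the plain mean/sd
  are inflated by the outliers themselves and mask all but the most
  extreme rows.  With an infinite cut, or a degenerate spread, nothing is
  flagged.
* **Class balancing** oversamples the minority class by latent-space
  interpolation: encode two random minority rows, mix codes with
  λ ~ U(0, 1), decode.  Synthetic samples therefore lie in the sigmoid
  range (0, 1) and near the minority manifold.  Appending continues until
  minority/majority reaches the target ratio (1.0 default); the majority
  class is untouched.

## Conv-LSTM classifier

Two ingredients are provided:

* the **ConvLSTM cell** (convolutional gate pre-activations with Hadamard
  peephole terms on the cell state), exposed as a forward recurrent block
  and checked element-for-element against a scalar loop oracle; and
* the **trainable classifier**: per branch, convolution → activation →
  max-pool blocks with train-time Gaussian noise; concatenated branch
  outputs → dropout → fully-connected → reshape (the flattened feature
  dimension becomes the time axis, one scalar per step) → stacked plain
  LSTM layers with Gaussian noise → global max pooling over time →
  softmax head.  The tuned preset mirrors the published optimal
  configuration: five conv blocks (16→256 filters, 3×3 kernels, 2×2
  pools, sigmoid), fully-connected 278, two LSTM layers of 128 tanh
  units, learning rate 0.1.

Numerical decisions:

* **Pooling sizing** is valid pooling with stride = window and the window
  clamped to the spatial extent (output max(⌊n/p⌋, 1)).  This is the only
  sizing that reproduces the preset's printed shape chain
  24→12→6→3→1→1 once a dimension collapses to 1.
* **Convolutions** use same padding (odd kernels pad symmetrically), so a
  3×3 kernel remains well-defined on a width-1 map.
* The preset's flatten size is computed from actual shapes (2048 from
  (256, 8, 1)); a printed value of 1536 is not reproducible from the
  preceding shape and is ignored.
* **Optimizer** is plain mini-batch SGD on categorical cross-entropy; the
  per-epoch history records full-data loss in inference mode (noise and
  dropout off), so a zero learning rate yields a constant history and
  training-progress tests are noise-free.
* **Initialization** is a seeded Glorot-uniform draw; identical configs
  produce identical models and parameter counts.
* Gaussian noise sd defaults to 0.01, train-time only; inference is
  deterministic.

Backpropagation through every layer (conv via im2col, max-pool argmax
scatter, BPTT through the LSTM, global-max routing) is hand-written and
verified against numerical gradients of the cross-entropy on a small
model.

## Golden Eagle Optimization

Single-objective GEO: positions initialized uniformly in the box; per
iteration each eagle selects a prey uniformly from the flock's memories,
moves by Δx = r₁∘p_a·A/‖A‖ + r₂∘p_c·C/‖C‖, is clipped to the box, and
updates its memory only on improvement (so the flock-best history is
non-increasing).  The cruise vector is constructed exactly: hyperplane
constant d = A·x through the eagle's own position, free coordinates
uniform on [0, 1], pivot coordinate (uniformly chosen among nonzero
attack components) solved as c_k = (d − Σ_{j≠k} a_j c_j)/a_k, destination
minus position returned — orthogonality A·C = 0 holds to machine
precision and is asserted over 1000 random draws.

**Propensity schedule.**  p_a and p_c interpolate linearly (signed)
between endpoints.  Because the step terms are norm-normalized, the final
step scale *is* the final propensity value; defaults are p_a: 2→0,
p_c: 1→0 (attack dominating cruise 2:1 throughout, both annealed to
zero), which contracts the search and reaches ~1e−4 on the 5-D sphere
benchmark with pop 50 over 300 iterations.  Non-decaying schedules leave
O(1) steps at the end and stall around 1e−2.

MOGEO adds an external archive (capacity 25 default) of mutually
non-dominated solutions.  Crowding is the printed second-difference
density index averaged over objectives (it can be negative; sparsity
S = 1 − clip(C, 0, 1)); members extreme in any objective get crowding 0 /
sparsity 1 and are thereby protected from elimination.  Prey selection is
a roulette wheel over sparsity (favouring sparse regions); elimination at
capacity is a roulette over crowdedness 1 − S.  A candidate with
objectives identical to an incumbent is rejected, keeping the archive
free of duplicates.  An eagle whose attack vector is zero adopts its prey
as the iteration's solution.  Box constraints are the only constraint
handling.

## Hyperparameter tuning

Eagle positions live in [0, 1]^D.  Decoding: continuous dims rescale
affinely; integer dims additionally round half-up; categorical dims index
by ⌊u·n_options⌋ (clipped).  The objective pair is (1 − validation
accuracy, log10 parameter count): accuracy is what the method optimizes,
and model size keeps the front meaningful while breaking ties toward
smaller networks.  Fitness evaluations are cached by decoded-config
identity, with the training seed derived from that identity so duplicate
positions get bit-identical fitness.  A stratified 80/20 train/validation
split is made inside `tune`; a training divergence maps to a worst-case
sentinel fitness.  Probabilities are binarized at 0.5; RMSE and the
Pearson/Spearman correlations compare the positive-class probability with
the 0/1 label (the only continuous score a classifier provides).  With
binary labels the label ranks are tied, so a Spearman of exactly 1 is
only attainable when the probabilities equal the labels.

## Synthetic data

`generate_dataset` draws a low-rank latent-factor table: labels
Bernoulli(minority_fraction), latent factors N(0, 1) with the first
factor shifted by `class_separation` for positive samples, nonnegative
loadings |N(0, 1)| (so a non-negativity-constrained encoder is
well-posed), Gaussian noise, a fraction of rows scaled ×10 as outliers,
a fraction of columns masked strictly above the 1/3 imputation-trigger
level, and uniform cell masking elsewhere (capped so only the designated
columns cross 1/3).  `generate_paired_branch_data` drives a cell-line
table and a drug table from the same latents and labels.

The generator emulates the *statistical* shape the pipeline consumes —
dimensions, missingness pattern, imbalance, outliers, controllable Bayes
error — not pharmacology: no dose-response curves, IC50s, drug-target
structure, batch effects, or feature correlations beyond the low-rank
factor model.  Passing tests therefore demonstrate that the machinery is
correct and that the pipeline recovers separable structure at desk scale;
they say nothing about accuracy on real GDSC exports, which involve far
larger samples, heavier tails and unknown label noise.

## Problem sizes

Desk-scale defaults keep every run on one CPU: the end-to-end pipeline
uses 360 samples × 22 features, a 36-unit code reshaped to 6×6 images,
a one-block CNN, pop-4/2-iteration tuning at 5 budget epochs and a
100-epoch final fit (a few seconds per seed); optimizer benchmarks use
pop 50 × 300 iterations (sphere) and pop 40 × 200 (bi-objective).

## Known limitations

* The NNCAE is single-layer; stacked/denoising variants are out of scope.
* Only box constraints in (MO)GEO; general inequality/equality
  constraints are not handled.
* The ConvLSTM cell is forward-only (used as an analysis block); the
  trainable classifier uses plain LSTM layers, as in the tuned preset.
* The count of negative weights is not a reliable readout of the
  non-negativity penalty (see above); use negative mass.
* Single train/validation split in tuning; no cross-validation.
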