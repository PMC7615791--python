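# Methods

## Problem setting

Resting-state fMRI cohorts for dementia research are small: a balanced
two-class study (healthy controls vs. late mild cognitive impairment)
typically has on the order of 150 subjects, while the object of interest —
the brain functional network (BFN), a 90 x 90 matrix of Pearson
correlations between regional BOLD time series — has ~4000 free edges.
Data-driven classifiers overfit badly at this ratio. This package
implements a generative augmentation method: a distribution-regularized
adversarial graph autoencoder (DAGAE) with a transformer generator that
synthesizes class-conditional BFNs, plus the full harness needed to judge
whether the synthetic networks actually help downstream diagnosis.

## Model

Four networks are trained jointly on a cohort of subjects
(F in R^{N x T} regional time series, A_ori in R^{N x N} Pearson BFN,
label y in {0, 1}; defaults N = 90, T = 187):

* **Graph encoder** E: two graph-convolution layers (T -> 64 -> p, ReLU
  then tanh) over the normalized adjacency
  Ahat = D^{-1/2}(A + I)D^{-1/2}, giving latent node codes
  H = E(A_ori, F) in (-1, 1)^{N x p} with p = 32.  Degrees are computed
  from |A| + I because Pearson weights are signed and signed row sums can
  be non-positive, which would make D^{-1/2} undefined; the signed A is
  kept in the propagation product.
* **Label-distribution prior**: per ROI and class, a Gaussian-kernel KDE
  over dimension-reduced node features (see below).  A "real" latent
  matrix X is sampled row-wise from the class-matched prior.
* **Discriminator** D: N per-ROI sub-networks (p+1 -> 32 -> 64 -> 1,
  sigmoid) whose extra input is the sample's class label (+-1 coded); the
  output is the mean of the sub-network outputs.  It is trained to score
  prior samples X high and encoder codes H low
  (L_dis = -E log D(X) - E log(1 - D(H))), while the encoder is trained
  with L_enc = E log(1 - D(H)).  At the optimum the conditional
  distributions coincide and D outputs 0.5 on both streams.  The label
  conditioning is load-bearing: a label-blind discriminator can only match
  the class *mixture* of codes to the prior, which leaves the per-class
  mode pairing unidentified — empirically the encoder's latent class
  direction then decorrelates from the prior's (r ~ 0.1) and
  class-conditional generation fails or inverts; with the conditioned
  judge the alignment reaches r ~ 0.8.  Matched-class prior sampling only
  conditions the model if the judge can tell the classes apart.
* **Classifier** C: a five-layer perceptron (N*p -> 1024 -> 256 -> 64 ->
  16 -> 2, softmax) on the flattened codes, trained with cross-entropy
  L_cla; it keeps the latent space class-discriminative.
* **Transformer generator** G: three connectivity-transformer (CT) layers
  — pre-norm multi-head self-attention over the N node tokens with a
  residual connection, head counts 4/8/11 — interleaved with two
  dimension-upscaling (DU) affine+ReLU layers p -> 64 -> T.  The
  connectivity head predicts A = tanh(M' M'^T / d) with the diagonal
  forced to 1, where d is the final embedding width.  G is trained with a
  mean-L1 reconstruction loss L_rec = mean|G(E(A, F)) - A| and a
  node-representation-consistency loss L_nrc = mean|E(G(H), F) - H| that
  re-encodes the reconstructed network.

Optimization alternates, per batch: (1) `t_dis` Adam steps on L_dis for
the discriminator alone; (2) updates of encoder, classifier and generator
on L_enc + L_cla + L_rec + L_nrc (the discriminator receives gradients
but is never stepped there, and vice versa).  Under the default *staged*
scheme — encoder, classifier and discriminator first, generator second —
the encoder is driven by the adversarial, classification and consistency
terms while reconstruction shapes the generator on detached codes.  This
split matters: feeding reconstruction gradients to the encoder (the
*joint* scheme, available via ``TrainConfig.update_scheme``) drags the
per-ROI code means far off the centred prior (|offset| ~ 0.6 vs the
prior's ~ 0.04), the discriminator reads the offset, and the full-scale
game diverges instead of settling at 0.5/0.5.  Defaults follow the
small-cohort regime: batch 16, encoder lr 1e-3, all other networks 1e-4,
t_dis = 1, a fixed number of epochs (default 500) with convergence
reported post hoc from the history rather than used as a stopping rule,
for determinism.

After training, augmentation samples X from the class-y prior and emits
A_gen = G(X) with label y, round(k * n_train_class) networks per class
(default k = 1).

## Dimension reduction and the latent prior

The prior must exist before adversarial training starts, so it cannot be
built from encoder outputs.  The reduction is a PCA of the per-ROI
T-vectors with a *shared* basis by default: one T -> p set of principal
axes fitted on the T-vectors of all ROIs of all training subjects pooled
(deterministic sign convention: largest-magnitude loading positive),
while each ROI keeps its own mean, so per-ROI center distributions still
differ.  A per-ROI basis (`axes="per_roi"`) is available; note that with
noise-like time series the per-ROI sample covariances are noise-dominated,
making per-ROI bases N mutually arbitrary rotations.  Two further choices
matter:

* **Scale matching.** Encoder codes live in (-1, 1) (tanh).  Raw PCA
  coordinates have arbitrary scale; if prior samples routinely fall
  outside the encoder's range the discriminator can separate the two
  streams on magnitude alone and the adversarial game has no reachable
  optimum.  Reduced coordinates are therefore rescaled to a per-dimension
  standard deviation of 1/3, which keeps essentially all prior mass inside
  the code space while preserving relative structure.
* **Granularity.** The default `per_roi` mode keeps one KDE per ROI per
  class (n_Y centers each), so sampled rows preserve ROI identity — which
  the per-ROI discriminator sub-networks presuppose.  A `pooled` mode
  (one density over all N*n_Y centers per class) is available; it is the
  literal reading of a single kernel sum over all ROIs of all same-class
  subjects.

Bandwidths use Scott's rule, b = sigma_hat * m^(-1/(p+4)), per center set;
zero-variance center sets fall back to a 1e-6 floor with a warning.
Sampling draws a uniform center plus isotropic Gaussian noise of sd b.
Two refinements keep the high-dimensional game honest:

* **Generation-time variance correction.**  Samples used for generation
  are shrunk toward the center mean by Silverman's smoothed-bootstrap
  factor (1 + b^2/sigma^2)^{-1/2}, so the sampled distribution keeps the
  empirical mean and variance; uncorrected kernel noise inflates every
  dimension's variance (~77% at p = 32 with ~100 centers) and pushes
  generated inputs off the manifold the generator was trained on.
* **Symmetric smoothing of the discriminator's streams.**  The
  discriminator judges ``center + b*eps`` against ``H + b*eps`` with the
  same per-ROI/class bandwidth.  A deterministic encoder yields a fixed
  finite set of codes, while prior draws are freshly jittered; as the
  latent dimension grows the discriminator simply memorizes the code
  points (measured mean D(fake) fell from 0.44 at p = 16 to 0.26 at the
  full scale) and the game diverges.  Smoothing both sides makes the game
  compare the *kernel-density estimates* of the code and label
  distributions — precisely the regularization intended — and is the
  instance-noise stabilization standard in adversarial training.
Note that row-wise sampling deliberately discards cross-ROI dependence
within a latent matrix: a sampled X is a "chimera" subject whose rows come
from different training subjects of the same class.  Mean class structure
survives; subject-level coherence is partly washed out, which bounds how
sharp individual generated networks can be.

## Numerical choices

* **Connectivity-head scaling.**  The inner product in the head is divided
  by the embedding width d before the tanh.  The upstream ReLU makes
  embeddings positive-mean, so raw inner products grow linearly with d
  (O(30-90) at d = 187); the tanh then saturates at initialization and
  generator gradients vanish identically.  Scaling by 1/d makes the
  predicted connectivity the mean elementwise product of two node
  embeddings — intensive in d — and keeps the tanh in its sensitive range
  at any width.
* **Cross-entropy sign.**  The classifier term is the standard negative
  log-likelihood (the quantity is minimized); probabilities inside any
  logarithm are clamped to (1e-7, 1 - 1e-7).
* **Generated diagonal.**  tanh of a squared norm is not 1, so the head
  overwrites the diagonal with exactly 1 to match the Pearson convention;
  graph metrics zero the diagonal again before computing statistics.
* **Zero-variance time series** correlate 0 with everything (not NaN) so
  graph-convolution inputs stay finite.
* **Parameter initialization** is Glorot-uniform from a run-level seed;
  all randomness (cohort, initialization, batching, prior sampling) is
  driven by explicit seeds, and identical seeds reproduce bit-identical
  cohorts, loss histories and fold splits.
* **Training dtype** is float32 (configurable); gradient correctness is
  verified against finite differences in float64.
* **Degenerate metric denominators** (no positive or no negative subjects
  in a fold) yield NaN, never a silent 0.

## Synthetic cohorts

No real imaging data ships with the package.  The generator emulates the
statistical skeleton such a method assumes: each class has a modular
block-correlation template (`within_corr` inside modules, `between_corr`
across, defaults 0.5/0.1 over 6 modules); the patient class adds
`effect_size` (default 0.3) to a seeded random fraction `effect_edges`
(default 0.15) of inter-module edges, mimicking abnormal long-range
functional connections.  Off-diagonals are clipped to [-0.95, 0.95] and
templates repaired to valid correlation matrices by eigenvalue clipping
and re-normalization to unit diagonal.  Subjects draw T i.i.d. time
points from N(0, template + symmetric jitter of sd `subject_noise_sd`).
Defaults mirror the two-class resting-state setting: 90 ROIs, 187 time
points, 75 subjects per class.

The class effect has a second, marginal component: regions incident to an
altered edge carry a constant baseline offset (`roi_shift_effect`,
default 0.5 signal units) in the patient class's time series — the
regional-amplitude abnormality familiar from dementia fMRI.  This
component is essential to the method's mechanism, not decoration: with a
purely correlational class effect every ROI's *marginal* time series is
distributionally identical across classes, so a label prior built from
per-ROI feature marginals would provably carry no class information and
class-conditional generation could not work on such data.  Because the
Pearson network is invariant to per-row constant shifts, the offset
changes the feature marginals (and hence the prior) without altering the
connectivity effect model or any network-level property — a linear
classifier on the networks still sits at chance when `effect_size` is 0.

What this emulates well: dimensionality, balanced two-class structure,
modular connectivity, controllable class effect and subject variability.
What it does not: temporal autocorrelation and hemodynamics (irrelevant to
Pearson networks, which are permutation-invariant in time), scanner and
motion artifacts, site effects, the heavy-tailed and spatially structured
correlations of real BOLD data.  Passing tests on these cohorts therefore
demonstrates mechanism (the pipeline learns and transfers class-conditional
connectivity structure), not clinical performance.

## Evaluation harness

Five-fold stratified cross-validation (15 + 15 per fold at the default
cohort size).  Per fold, the entire pipeline — reducer, prior, adversarial
training, generation — sees only the four training folds; the classifier
trains on original plus generated networks and is evaluated on the
held-out originals.  An assertion fails if any test subject id reaches the
augmentation inputs.  Three classifier heads are provided: a
graph-convolutional classifier (two GCN layers of 32 and 16 units over the
network itself, with the network's rows as node features, mean pooling and
a two-unit softmax; Adam lr 1e-4, default 1000 epochs), an RBF SVM and an
MLP (128 -> 32 -> 2) on vectorized upper-triangle edges.  The GCN head
follows a two-stage protocol when augmentation is on: pretrain on the
original training networks, then fine-tune (same epoch budget, warm
start) on the original-plus-generated mixture, so the generated data
regularizes the real-data solution instead of replacing it; SVM/DNN fit
the union jointly.  Metrics are
ACC/SEN/SPE from the confusion counts (patient class positive) and
rank-based (Mann-Whitney) AUC.  The k-sweep reports
DeltaACC(k) = ACC_k - ACC_0 under identical folds, training the
adversarial model once per fold and reusing it across k; DeltaACC is not
assumed monotone in k.  Ablations: `no_DU` (constant-width CT-only
generator; head counts fall back to the largest divisor <= the default,
i.e. 4/8/8 at p = 32), `no_CT` (generator reduced to the two affine DU
layers), and `no_encoder` / `no_discriminator` / `no_classifier` (the
corresponding loss terms and update steps are dropped).

Generated-network quality is profiled by six weighted graph statistics on
absolute weights with zero diagonal — Onnela clustering, node strength,
betweenness on 1/weight distances, Louvain modularity, Latora-Marchiori
global and local efficiency — plus a seeded t-SNE embedding of vectorized
networks for qualitative overlap.  Absolute weights are used because
strengths and shortest-path statistics are undefined for signed weights.

## Problem sizes used in the shipped checks

The equilibrium check runs at the full study scale (60 subjects per
class, N = 90, T = 187, 300 epochs) and asserts that the mean
discriminator output on both streams, averaged over the last 50 epochs,
is within 0.15 of the theoretical 0.5.  The recovery/utility study runs
at reduced scale (N = 20, T = 36, 15 subjects per class, 300 epochs,
five cohort seeds, calibrated so the plain-CV baseline sits near the
~0.70 operating point where augmentation is claimed to matter) and
checks direction only: generated class means sit
closer to their own class template than to the other's, augmentation
does not reduce mean cross-validated accuracy, and the full generator is
at least as good as the attention-free variant.  Reduced scale trades
statistical resolution for tractability on a single CPU; the directional
claims are the ones the method's value rests on.

## Known limitations

* Row-independent prior sampling caps the sharpness of individual
  generated networks (see above).
* Generated edge weights are substantially more uniform than Pearson
  weights: the width-averaged inner-product head concentrates its
  outputs, so per-network Onnela clustering sits near its dense-graph
  ceiling while betweenness and modularity sit near their uniform-graph
  floors.  Strength and efficiency distributions overlap the originals';
  the path-structure metric distributions do not.
* Equilibrium and conditional sharpness pull against each other: at the
  adversarial optimum the codes match the class-conditional prior, whose
  classes overlap substantially, and the L1-optimal generator on
  overlapping conditionals interpolates the class means.  The generated
  set therefore improves downstream classification (a regularization
  effect under the pretrain-then-fine-tune protocol) even when the
  elementwise geometry of its class means barely separates the
  templates.  Configurations that sharpen conditional generation do so by
  letting the codes drift off the prior — visible as the discriminator
  pulling away from 0.5.
* The adversarial game is judged by discriminator output, not by any
  formal convergence guarantee; a fixed epoch budget with post-hoc
  diagnostics replaces early stopping.
* All networks are CPU-sized; no GPU path, no mixed precision, no
  learning-rate schedules.
* Binary classification only; category-imbalanced cohorts are out of
  scope.
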