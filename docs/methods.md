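# Methods

## Model

The network is a fully connected recurrent architecture with an input layer
(layer 1) and `L = 2` hidden layers. Layer 1 has `C² (+ 2)` units: the
flattened `C × C` fixation crop plus, when the efference copy is enabled,
two units carrying the saccade vector `Δp = (Δx, Δy)` in raw pixels. The
input drive into layer 1 is fixed and non-learnable; layer 1 additionally
receives learnable top-down feedback from hidden layer 1. Every hidden layer
has bottom-up, lateral and, where a layer above exists, top-down weights.
There are no bias terms anywhere: biases would let the network buy constant
inhibition for free and muddy the energy account.

The update is fully synchronous with a one-step delay: at step `t`, every
pathway reads the ReLU of the *previous* step's preactivations,

```
pre₁(t)   = drive(t) + W_td₀ · relu(h₁(t−1))
pre_hℓ(t) = W_buℓ · relu(a_{ℓ−1}(t−1)) + W_latℓ · relu(h_ℓ(t−1))
            + W_tdℓ · relu(h_{ℓ+1}(t−1))       (top-down term if ℓ < L)
```

Synchrony is the simplest staging rule consistent with a fixed number of
steps per fixation; no within-step ordering of pathways is assumed.

Every layer (including layer 1) carries a learnable bias on its
preactivation, the standard linear-layer convention, initialized
U(−1/√N_in, +1/√N_in). The biases are load-bearing for the warm-up step:
with a zero initial state and no biases, the pre-sequence zero-input step
would provably produce all-zero activity and the first fixation's input
could never be inhibited — contradicting the warm-up step's stated purpose
of enabling an initial inhibition. With biases, the warm-up activates a
learned tonic state whose top-down projection subtracts an average-scene
template from the first crop; empirically this removes the first fixation's
energy handicap entirely (its onset loss falls from the uninhibited mean
crop value to the level of the average-template controls). A `use_bias`
flag restores the bias-free variant, which the lesion-oracle identity (a
full hidden-population lesion reproduces the zero-weight network exactly)
requires, since a layer-1 bias is not a hidden unit and survives any
lesion.

Each fixation is presented for `T = 6` steps; the efference copy occupies
the two extra input slots from step `⌈T/2⌉` onward (the last three steps at
`T = 6`) and is zero before. Each sequence starts with one warm-up step
whose input vector is all-zero; from a zero initial state this step is
silent, and it is excluded from all loss bookkeeping. State carries over
across fixations within a sequence and is reset to zeros between sequences.

Weights are initialized He-uniform, `U(−√(6/N_in), +√(6/N_in))`, with
`N_in` the width of the matrix's source layer (gain 2 for ReLU). At both
desk and full scale this initialization gives the recurrent loop an
effective gain above one, so the *untrained* network's activity grows over
the 43 recorded steps and its energy loss is orders of magnitude above any
trained model's — the untrained baseline is a genuinely high lower bound of
performance, not a near-miss.

## Objectives

**Energy.** `L = 1/(T·N) Σ_t Σ_i |preactivation_{i,t}|`, averaged over all
layers (N counts layer-1 and hidden units), all fixation steps, all
fixations and the batch. Minimizing preactivation jointly penalizes firing
and synaptic transmission while the fixed input drive rules out a learned
shutdown.

**Categorization (control).** A sigmoid readout of 91 classes (desk: 8)
attached to the top hidden layer at the final step of the final fixation,
trained with multi-hot binary cross-entropy. Internally the loss is
computed from logits in softplus form (`softplus(z) − y·z`), which is
numerically stable and has an exact gradient; the public
`bce_categorization_loss` operates on probabilities.

**Temporal contrastive (control).** InfoNCE with cosine similarity and
temperature τ = 0.1 on top-layer activations: the anchor at step `t` is
paired with the same sequence's representation at `t − 2` (across fixation
boundaries), against 8 negatives taken from the same step of other
sequences in the batch (different scenes).

**Untrained baseline.** He-initialized weights, no training.

Gradients for all objectives are derived analytically and backpropagated
through the entire recorded sequence (full BPTT over all `1 + F·T` steps;
truncation is available but off by default). The energy gradient is checked
against central finite differences in the test suite (relative error
≤ 1e−4 on a toy network). Training arithmetic runs in float32 for speed;
weights are returned as float64. Optimization is Adam (β₁ = 0.9,
β₂ = 0.999, ε = 1e−8) with a per-matrix learning rate: a matrix whose
source layer is wider than its target is rescaled by `W_target/W_source`
(the first bottom-up matrix at full scale: 2,048/16,384 ≈ 0.125), all
others keep the base rate. This reproduces the published worked instance
while leaving equal-width matrices untouched; the rule is our
interpretation of the single printed case.

## Synthetic world

Scenes are 1/f-filtered Gaussian noise (amplitude spectrum ∝ f^−1, hence
power ∝ f^−2, matching natural-image statistics), min–max rescaled to
[0, 1] — strictly non-negative, as the input drive requires. When the
categorization control is used, a random subset of eight fixed oriented
gratings is mixed into each scene and recorded as a multi-hot label — a
desk-scale stand-in for object-category labels.

Scanpaths start at the scene center and take i.i.d. isotropic Gaussian
steps (σ = side/4 by default), rounded to integer pixels and clamped to the
region where the crop stays inside the scene. This preserves the two
properties the model exploits — a mixture of short and long saccades, and
frequent overlap between consecutive crops — without a saliency model.
Crops are pure slices (half-open square `[c − C/2, c + C/2)`); no padding
is ever applied, because generation pre-clamps. The efference copy of
fixation `f` is `coords[f+1] − coords[f]`; the final fixation's copy is the
zero vector. The shuffled-efference control permutes the coordinate order
within each sequence (never the identity, seeded), keeps the crops in their
original order, and recomputes the efferences from the permuted
coordinates.

What the generator does *not* emulate: object structure, photometric
nonlinearities, saliency-driven fixation selection, or any correlation
between scene content and fixation placement. Passing tests therefore show
that the mechanisms emerge under naturalistic second-order statistics and
human-like saccade geometry — not that the learned predictions would
transfer to photographs.

## Evaluation

All conditions — networks and static templates — are compared on one
metric: the mean |preactivation| of the layer-1 **image units** at each
fixation's *first* step, the moment the saccade lands. For a template
prediction `p` the implied onset loss is mean |crop − p|: the loss a network
would incur if its feedback exactly equaled −p. The static templates
(training split only) are the average luminance, the average crop, and the
average image cropped at the current fixation; the dynamic controls are the
previous fixation crop (zero prediction at the first fixation) and the
shuffled-efference dataset evaluated under the same trained model.
Comparisons use Welch's t test over all test-set fixations, with 99%
normal-approximation confidence intervals of each condition's mean.

Feedback statistics take the spatial mean of the top-down drive to the
layer-1 image units (efference slots excluded) per crop and per step
(`n = scenes × F × T`), reporting the grand mean and its 99% CI.

**Decoding.** Hidden activations of both layers at all T steps are
concatenated per fixation (step-major). Scenes — not rows — are split into
fit and evaluation subsets; columns are z-scored with fit-split parameters;
the readout is OLS, or leave-one-out-validated ridge in the rank-deficient
regime (at desk scale the design has ~3,000 columns and a comparable number
of rows, so the ridge path is the operative one). Per-unit beta magnitudes
sum |standardized weight| over the unit's T columns and both coordinates.

**Lesioning.** The top-beta units (k = 22 at full scale; desk:
proportional, floored at 4 → k = 4 of 512) are zeroed at runtime and
compared against an equal-sized random lesion drawn from the remaining
units, on identical fixations.

**Similarity.** For each test sequence, `M[t, j]` is the Pearson
correlation between the feedback image at step `t` and the ideal inhibition
(the negative of crop `j`). Two binary hypothesis matrices are tested:
H_future marks the steps of the fixation *preceding* crop `j` (predictive
remapping), H_current the steps of crop `j` itself (reusing the present
input). Per-sequence correlations `r(M, H)` are tested against zero with
one-sample t tests.

**Spatial memory.** All within-sequence pairwise fixation distances define
tercile thresholds (33.3/66.7 percentiles); for pairs at most 3 fixations
apart, the z-scored loss of the second fixation enters the (distance class,
lag) cell.

**Clustering.** Unit activation profiles are the mean activation per
fixation-coordinate bin (8 × 8 grid over the scene) on the test set —
z-scored, projected on the first 10 principal components, clustered with
k-means (10 restarts, fixed seed) over a scanned k-range, k chosen by
silhouette maximization; the representative of a cluster is the member most
correlated with its centroid. Identical profiles short-circuit to a single
degenerate cluster.

## Desk preset and problem sizes

The shipped study runs at desk scale: 64 px scenes, 32 px crops, two hidden
layers of 256 units, `T = 6`, `F = 7`, 500 training and 50 test scenes with
10 scanpaths each. Training uses batch 8 (with 500 scenes per epoch that is
63 Adam updates per epoch; many small steps converge substantially faster
here than the full-scale batch-to-dataset ratio would suggest), base lr
2 × 10⁻³, 100 epochs, and full-sequence BPTT. Because the L1 objective has
non-vanishing gradient magnitude at its optimum, a constant learning rate
leaves Adam circling in a noise ball proportional to the rate; the schedule
is therefore constant for the first 60% of epochs and cosine-decays to 5%
of the base rate over the rest ('late-cosine'); in our calibration runs the
decay phase lowered the held-out loss far below the constant-rate plateau
(e.g., 0.134 → 0.087 when a converged constant-rate model was given a
decaying tail). Evaluation uses one scanpath per test scene (350 fixations);
decoding uses three scanpaths per scene. Absolute loss values at this scale
are not comparable to full-scale results; the package's claims are the
*orderings and signs* of effects (model vs. controls, feedback sign,
decoding gap), which are scale-portable properties.

What desk scale does and does not reproduce. The energy-trained network
robustly develops (i) strong inhibitory top-down feedback, (ii) an
average-scene inhibition template active from the first fixation, (iii)
within-fixation inhibition of the current crop well below any static
predictor, (iv) a spatial-memory gradient (cheaper fixations near recently
visited locations), and (v) hidden activity from which the allocentric
fixation position is linearly decodable far better than from the untrained
reservoir. What it does *not* reach at this scale, in any training regime
we explored (up to ~550 epochs, batch sizes 8–125, constant and decayed
rates, raw and rescaled efference): saccade-conditioned *predictive*
remapping strong enough for the onset loss to undercut the
location-specific average template, for targeted lesions of top-decoder
units to raise the loss, or for the feedback-vs-ideal similarity to align
with the upcoming rather than the current crop. The desk network instead
converges to template-plus-current-crop inhibition with only a marginal
efference contribution (shuffling the efference copies raises its loss
slightly). The corresponding acceptance checks are kept at their full
strength and fail honestly at this scale rather than being weakened.

## Numerical choices and edge cases

- Constant activation columns are dropped (with a warning) before decoding.
- A constant feedback or crop image makes a Pearson correlation undefined;
  such similarity entries are set to 0 and counted. Detection uses a
  relative tolerance because feedback images are reconstructed as
  `preactivation − drive`.
- Constant loss vectors make z-scores degenerate; the spatial-memory table
  returns zeros in that case (relative tolerance on the standard
  deviation).
- `sign(0) = 0` serves as the subgradient of |·| at zero.
- Ties in beta-based unit selection break toward the lower unit index.
- Random-lesion controls are drawn from the non-targeted units, so the
  control never accidentally contains a targeted unit.
- Training aborts with a diagnostic if the loss becomes non-finite.

## Known limitations

- BPTT is biologically implausible; the package makes no claim about the
  learning rule, only about the objective.
- The desk-scale network does not reach full-scale decoding accuracy; the
  acceptance surface is the set of orderings listed above.
- Scanpath statistics are a Gaussian caricature of human gaze; saliency,
  center bias beyond the first fixation, and return-saccade dynamics are
  absent.
- The energy proxy is mean |preactivation|; metabolic costs not captured by
  it (e.g., maintenance costs, spike transport) are out of scope.
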