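# Methods

This note documents the models and procedures implemented in `sonodescribe`,
the assumptions behind them, the parameters that matter, and what the
synthetic experiments do and do not demonstrate.

## Pipeline overview

A grayscale breast-ultrasound image flows through five stages:

1. **Detection** — a pluggable detector proposes nodule bounding boxes with
   confidences (an adapter interface for an external one-stage detector, a
   built-in intensity-deviation blob detector, or a ground-truth oracle in
   tests).
2. **ROI standardization** — each box is cropped, rescaled only when a side
   exceeds the 450-pixel target (preserving the width-height ratio, which
   carries the orientation descriptor), and zero-padded to a square with the
   content at the top-left.
3. **Descriptor network** — a convolutional encoder with soft-attention
   pooling and one head per BI-RADS descriptor, plus a tumor-type
   ("suggestivity") head and a Boolean malignancy head.
4. **BI-RADS regression** — a multinomial logistic regression maps the seven
   categorical descriptors (never the image) to the category in
   {2, 3, 4A, 4B, 4C, 5}, with exact per-feature weight explanations.
5. **Rules and reporting** — two lexicon rules fine-tune the output, a
   template renders the narrative, and the category maps to a clinical
   intervention.

A SIFT-based auditor detects near-duplicate images in datasets before any
training, and a synthetic phantom generator provides ground-truth data for
all of the above.

## The attention classification network

The encoder is a convolutional stem (3x3 convolution, GELU, 2x2 max-pool)
followed by a VGG16-style stack of convolution blocks, each ending in a
max-pool.  The default topology downsamples 450x450 inputs to a 14x14x512
map, i.e. a feature-space matrix **F** of 196 rows (spatial cells) by d = 512
columns, which is batch-normalized (per feature dimension, over all cells in
the batch; epsilon 1e-5 keeps constant inputs finite).

Attention scores each row f_i with a single learned perceptron,
tanh(V·f_i) ∈ [−1, 1], normalizes the scores with a softmax into weights
a_i ≥ 0 with Σ a_i = 1, and pools the context **c** = Σ a_i f_i.  The printed
form of this normalization in the source architecture places the exponential
of a *sum* of scores in the denominator, which cannot normalize anything; the
accompanying text requires weights that "add up to a total of 1", so the
softmax reading is implemented.  The weights a_i double as the visual
attention map: reshaped to the g x g grid and bilinearly upsampled to the ROI.

Head wiring:

* six descriptor heads read the context only: shape (3 values), margin (4),
  orientation (2 sigmoid neurons), echogenicity (5), posterior (3), halo (2);
  all but orientation are softmax;
* the suggestivity head reads the six descriptor outputs *and* the context —
  the type of a tumor is a function of its descriptors — and has an extra
  "no clear suggestivity" label so that unclassifiable nodules are a modeled
  state (a sigmoid would force a type label on every nodule);
* the malignancy head reads the descriptors, the suggestivity output and the
  context, with a 2-way softmax.

Heads consume downstream probabilities (not logits); this choice is open in
the source description and documented here.

**Orientation decision.** Round nodules are neither parallel nor
anti-parallel, so orientation uses two independent sigmoids with a decision
threshold tau = 0.3: "none" when both values fall below tau, otherwise the
argmax among values reaching tau, ties toward "parallel" (the prevalent
class).

**Training.** The loss is a weighted sum of per-head cross-entropies,
uniform by default and config-overridable; the tiny configuration documents
a doubled weight on the shape head, which is the slowest of the multi-task
objectives to generalize at its resolution.  Orientation uses per-neuron
binary cross-entropy; nodules labeled "none" train both neurons toward zero
by default (`orientation_none="zero"`), which is what lets the three-way
decision recover the none class.  A masking variant
(`orientation_none="mask"`) that simply excludes unoriented nodules from the
orientation loss is available, but leaves the sigmoids unsupervised on round
nodules and is not recommended.  The optimizer is Adam (default learning
rate 1e-4 for the full topology; the tiny recipe is 100 epochs at 2e-3,
batch 32).  Three cheap, label-preserving regularizers are on by default and
were decisive against speckle memorization on small synthetic sets:
horizontal flips of the ROI content (every label is flip-invariant),
random placement of the content within the zero padding during training
(the top-left placement is a contract of inference, not of the optimizer),
and stochastic weight averaging over the final fifth of the epochs with a
batch-norm statistics refresh.  Inference averages the heads over the
horizontal flip (`tta`).  Training is deterministic given the config seed.
A k-fold split helper never places images flagged `extra_info` (burned-in
annotations — a "Clever Hans" cue) in validation folds; they are
train-only.

**Augmentation** (training-time, sampled per image per epoch): ROI
enlargement/reduction of [−0.1, 0.25] of the box size vertically and
[−0.1, 0.15] horizontally; zoom [−0.3, 0.3]; contrast [0.8, 1.2]; brightness
[−25, 25]; horizontal flips with p = 0.5; rotations limited to
|θ| ≤ 0.05·2π rad to preserve the orientation descriptor.  With all intervals
collapsed the augmentation is the identity standardization.

**The "tiny" configuration** (96x96 input, stem of 8 channels, conv stages
of 16, 2x32 and 2x64 channels, d = 64, hence a 36x64 feature space) is structurally identical to
the default and is first-class: the whole test-suite, including the
descriptor-recovery experiment, runs it on one CPU.  The network and its
gradients are implemented directly in NumPy (im2col convolutions, explicit
backward passes, numerically gradient-checked in the tests), which keeps
every computation inspectable and dependency-light.

## BI-RADS regression and explanations

Descriptors are one-hot encoded, one block per descriptor (orientation
"none" is its own indicator, not missing data; 24 indicators in total).  The
L2-penalized multinomial likelihood is maximized with scikit-learn's lbfgs
solver under the symmetric (non-pivot) parameterization, so a full weight
vector exists for every category and Fig.-style dot plots can show every
category's weights.  The penalty defaults to l2 = 0.1: the descriptor-to-
category table is deterministic and nearly separable, and stronger shrinkage
visibly blurs the fine 4B/4C boundaries (adjacent categories differ by one
suspicious feature).

For a prediction, the logit of category k is exactly
Σ_active w_k(feature=value) + b_k; the explanation lists these contributions
for the two leading categories.  Two identifiability facts matter when
*comparing* weights (e.g. in the coefficient-recovery test): a constant added
to all categories' weights of one feature cancels in the softmax, and a
constant added to one category's weights within one one-hot block is absorbed
by the intercept.  Recovered weights are therefore compared on the
double-centered contrasts (centered across categories and within blocks).

The regression consumes hard (argmax) descriptor values, matching a pipeline
trained on expert labels and fed model outputs; per-value probabilities are
carried alongside for inspection but not used by the category model.

The modeled category space is {2, 3, 4A, 4B, 4C, 5}: categories 0 (incomplete
study), 1 (no findings) and 6 (biopsy-proven) are procedural states a
descriptor model cannot produce, though the intervention table accepts them.

## Rules, interventions and reports

Two lexicon rules run after the regression: (1) round nodules lose their
orientation output; (2) simple cyst → 2, complex cyst → 4A, spiculated
margin → 5.  Precedence under conflict is malignancy-dominant — spiculated
overrides the tumor type, which overrides the regression — and the operation
is idempotent.  The intervention table covers the full clinical 0–6 scale
(0 → additional evaluation, 1/2 → normal procedure, 3 → control in 6 months,
4A–5 → biopsy, 6 → treatment).  Narratives are deterministic fills of a
plain-text template with named slots (shipped in English, user-replaceable);
the orientation phrase disappears when the orientation was removed, and the
structured record round-trips byte-identically through JSON.

## Near-duplicate detection

Keypoints and descriptors come from scikit-image's SIFT; candidate matches
pass a nearest-neighbor ratio test (0.75) with cross-checking, then geometric
verification by RANSAC under a similarity transform — rotation + scale +
translation, exactly the transform class of a zoomed/rotated copy.  A pair is
a duplicate when at least 25 matches are inliers; both thresholds are
exposed, and the defaults were chosen to give a wide margin between planted
copies (hundreds of inliers) and independent speckle images (near zero) on
the synthetic fixtures.  Clusters are connected components of the pairwise
graph, so chains merge.

The audit policy keeps one representative per clean cluster and (by default)
drops clusters whose members disagree on the malignancy label entirely.

Documented limitation, reproduced as a test: two renderings of the *same*
nodule with fresh speckle (frames of one nodule over time) share no stable
keypoints and are **not** detected.  Keypoint dedup cleans copied images, not
re-scanned anatomy.

## Evaluation metrics

Cohen's kappa is unweighted, (p_o − p_e)/(1 − p_e) with p_e from marginal
products; when both raters are constant and identical (p_e = 1) it is
reported as 1.0 by convention.  The agreement report gives kappa, accuracy
and the confusion matrix per descriptor and the unweighted mean kappa over
the seven descriptor outputs; the BI-RADS category's kappa is reported
separately, never folded into that mean.  The malignancy suite is the
standard 2x2 set (accuracy, recall, precision, F1, specificity) with
malignant as the positive class; recall on truth with no positives is 0 with
a warning.  Detection quality uses greedy confidence-ordered matching at
IoU ≥ 0.5 (threshold configurable) and the area under the interpolated
precision-recall curve; with no predictions, precision is reported as 0.

## The phantom generator

The generator emulates just enough B-mode appearance to make every
descriptor visually decodable with a known answer:

* background: multiplicative Rayleigh speckle (unit mean) around a sampled
  background level (100–130), lightly smoothed to emulate speckle
  correlation;
* echogenicity: interior intensity factors 0.07 (anechoic), 0.48
  (hypoechoic), 1.0 (isoechoic), 1.75 (hyperechoic), and a dark/bright blob
  patchwork (heterogeneous); every nodule carries a thin dark boundary rim
  so that isoechoic and heterogeneous silhouettes remain readable;
* shape and orientation: ellipse aspect 1.5–2.0 (oval) or, for the
  irregular class, a composite body — the union of the main ellipse with
  two or three protruding satellite ellipses plus one concave notch bitten
  out of the boundary, since ellipses (scalloped or not) are never concave;
  round nodules have axis ratio within [0.9, 1.1] and no orientation; the
  long axis runs horizontal (parallel) or vertical (anti-parallel);
* margin: sharp edge (circumscribed), Gaussian-blurred edge (indistinct,
  sigma 3.2), fine regular 12–16-lobe scalloping (microlobulated — a
  deliberately higher frequency band than the irregular form's lobes, so
  shape and margin cues stay orthogonal), or 9–13 dark radial spikes
  (spiculated);
* posterior: the column under the nodule multiplied by 1.65 (enhancement) or
  0.32 (shadowing);
* halo: a bright ring (factor 1.85) hugging the boundary.

Cue magnitudes were set so that the descriptor classes are separable by
design at the tiny network's 96-pixel resolution — the generator's purpose is
a solvable, fully labeled task, not acoustic realism.  Rendering is a pure
function of the spec and its seed.

The tumor type is generated *consistently with the descriptors*: simple cyst
⇔ anechoic + circumscribed + enhancement; complex cyst ⇔ heterogeneous +
enhancement; fibroadenoma ⇔ oval + circumscribed + parallel + hypoechoic;
anything else is "no clear suggestivity" (free draws that would collide with
a special pattern are nudged off it).  The ground-truth category is a
deterministic, monotone function of the suspicious-feature count
{irregular, microlobulated, anti-parallel, shadowing, halo} with the hard
rules pinned first (the full table is in the `derive_birads` docstring), and
the Boolean malignancy label is category ≥ 4B.  Sampling priors for every
descriptor are configurable; the defaults give each class enough prevalence
to train on (about 14% simple cysts, 14% complex cysts, 16% fibroadenomas).

Ground-truth boxes enclose the nodule, spicules and halo *plus* the posterior
column (2.2 semi-axes below the nodule), because the posterior feature can
only be read from that context; the built-in detector expands its boxes
downward for the same reason.

**What passing the synthetic experiments shows — and does not.**  The
recovery experiment (600 training / 150 held-out phantoms, tiny topology,
per-descriptor Cohen's kappa ≥ 0.8) demonstrates that the architecture,
losses, wiring and data plumbing can jointly extract every descriptor from
images where the cue is present by construction.  It says nothing about
clinical images: real ultrasound has anisotropic speckle, shadowing artifacts
unrelated to nodules, inter-expert label noise, and descriptor prevalences
this generator does not calibrate (the phantom priors are choices, not
clinical statistics).  Reported clinical-scale agreement requires expert
annotations that are not distributable with this package.

## Problem sizes and numerical choices

The test-suite and the acceptance script run everything at desk scale, chosen
to keep the full pipeline demonstrable on one CPU: the descriptor-recovery
experiment uses 750 phantoms at 160x160 canvas with the tiny topology; the
dedup fixture uses 30 uniques + 10 planted copies; the coefficient-recovery
simulation uses n = 5000.  Softmax computations subtract the row maximum;
cross-entropies clamp probabilities at 1e-9; batch-norm uses epsilon 1e-5 and
momentum 0.1; max-pooling uses floor semantics for odd sides (so 450 → 14
after five halvings); RANSAC uses a fixed rng, making dedup deterministic.
Checkpoints are single .npz archives with the config embedded as JSON.

## Known limitations

* The built-in blob detector is a test-scale fallback: it assumes one
  dominant high-contrast lesion and degrades on isoechoic nodules; real
  deployments should plug an external detector through the adapter.
* The phantom generator models neither calcifications, mixed posterior
  features, complex cystic-and-solid echogenicity (all excluded from the
  vocabularies by design) nor probe-dependent artifacts.
* The NumPy network trains the tiny topology comfortably; the full 450-pixel
  topology is provided for forward-pass fidelity and structure, but training
  it at clinical scale would call for a GPU framework behind the same
  interfaces.
* Keypoint dedup does not detect re-scanned anatomy (see above).
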