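# Methods

## The prediction problem and the model

Each patient contributes N paired grayscale images: a pre-treatment
frame X and an after-first-cycle frame Y, with a patient-level binary
label (pCR / non-pCR).  The unit of training and evaluation is the
image *pair*; class probabilities are indexed (pCR, non-pCR) and the
positive class is pCR throughout.

The dual-branch network is two VGG-style convolutional stacks with
independent parameters — the two timepoints are draws from different
distributions, so no Siamese weight tying is used.  Per branch and
layer: 3×3 convolution ('same' padding, stride 1) → batch
normalisation → ReLU.  The canonical depth is 9 layers in four blocks
(layout [2, 2, 3, 2]; 64/128/256/512 channels).  2×2/stride-2 max
pooling follows layers {2, 4, 7, 9}, taking 128×128 to 8×8; with
padding 1 this is the only geometry that makes the flattened dimension
(512·8·8) consistent with the 1024-unit fully connected head, which is
why 'same' padding and 2×2/2 pooling were fixed although unstated in
the source material.  At sharing layers {2, 4, 6, 9} the input of layer
j in each branch is the element-wise sum (FSS) or channel concatenation
(FSC) of both branches' previous feature maps; under FSC the affected
conv layers take 2× input channels.  The sharing set deliberately
follows the published literal {2, 4, 6, 9} even though layer 6 sits
mid-block while pooling is at 7; both sets are expressible in
`ModelConfig`.

After flattening, each branch maps to a `fc_width` (default 1024)
feature vector; dropout (rate 0.5) is applied after each branch's fc
layer, before fusion.  Fusion is concatenation, sum, or the convex
weighting F(Z) = α·F(X) + β·F(Y) with (α, β) = (0.2, 0.8) by default —
the weighting is applied once (the doubled weighting that a literal
reading of the fusion formula would suggest is treated as a notational
slip).  A final linear layer produces 2 logits; softmax gives
probabilities.  The classification head past the fused vector is a
design choice (only "softmax" is specified); a single linear map is the
minimal one.

Initialisation is He-normal for convolution and dense weights, zeros
for biases, batch-norm affine parameters (γ, β) = (1, 0), running
statistics (0, 1) with momentum 0.1 and ε = 1e-5 (the common defaults;
affine batch norm is assumed).  Training follows the fixed recipe:
cross-entropy (accepting soft Mixup labels), Adam with lr 0.001 and
default moments (0.9, 0.999), no weight decay or schedule, batch size
8, a fixed epoch budget, per-epoch reshuffling.  No early stopping; an
optional patient-level validation fraction only monitors loss.  Class
weighting is not used — imbalance is addressed by the augmentation
strategies under comparison.

## The NumPy engine

The network runs on a small reverse-mode autodiff tape (`dbnn.nn`):
im2col + GEMM convolution, batch norm (batch statistics in train mode,
running estimates in eval), ReLU, max pooling, inverted dropout, dense
layers, elementwise add / scalar scale / concatenation, and a fused
softmax cross-entropy.  Gradients of every op are unit-tested against
central finite differences, and the composite forward pass against a
nested-loop direct-summation oracle.

One numerical subtlety is documented here because it looks like a bug
when first encountered: at freshly initialised parameters all biases
are zero, so convolution of an all-zero region is exactly zero, batch
norm maps it to exactly zero in eval mode, and whole feature-map
regions sit precisely at the ReLU kink.  There the two one-sided
derivatives differ, central differences measure their average, and
backpropagation (which takes the subgradient 0 at the kink) genuinely
disagrees with them.  The finite-difference audits therefore run at a
generic point — parameters nudged off initialisation — where the loss
is locally smooth.  Max-pool gradients are routed to every element
attaining the window maximum; exact ties occur only on dead (all-zero)
windows, where the ReLU mask annihilates the gradient anyway.

Floating point: float64 by default for test fidelity; the scaled-down
profile uses float32 for speed.  Determinism: model seed fixes the
initialisation, the training seed drives shuffling, dropout and
augmentation draws through a single `numpy` Generator, so
(config, data, seed) reproduces trained parameters bit-for-bit in a
single-threaded run.

## The phantom generator

`dbnn.synthetic` emulates the study conditions rather than ultrasound
physics: per-patient N uniform in [16, 20] frame pairs, pCR prevalence
0.342 (rounded to a patient count), 445×445 rendering canvas (the ROI
size upstream of the 128×128 resize; setting `image_size` to the
network input renders directly at target size as a fast mode).  A
patient's lesion is a rotated ellipse, hypoechoic by `lesion_contrast`
(default 0.35 below the 0.55 background mean), over multiplicative
speckle built as the envelope of Gaussian-smoothed complex Gaussian
noise (Rayleigh-like granularity, correlation length ~1.5 px,
dispersion `speckle_scale`, default 0.5).  No transducer or beamforming
model is attempted — the phantom reproduces the *statistical
structure* of the task (textured background, darker lesion, two stages
whose difference carries the label), not the physics; conclusions from
passing tests transfer to real data only insofar as that structure is
what matters.

The class signal is placed entirely in the between-stage change:
stage-1 lesion parameters are drawn from the same priors for both
classes (verified by a Mann–Whitney test on stage-1 areas), and stage-2
axes are stage-1 axes times a response factor — default U(0.0, 0.3)
for pCR, U(0.8, 1.1) for non-pCR.  These default ranges are effect-size
knobs, not empirical claims; nothing quantitative about real lesion
change under NAC is encoded.

Splits are patient-level: per-class training slots are allocated by
largest-remainder apportionment of round(n_patients · fraction), so
the class ratio of both sides tracks the cohort as closely as integers
allow and no patient straddles the boundary.

## Preprocessing, augmentation, evaluation

Cine loops are modelled as ordered frame directories.  The chain is
frame extraction at a fixed interval (default 5; the true interval is
unstated), quality-control selection as an explicit index list (the
manual radiologist step, made reproducible), sequential pairing (frame
k with frame k — closest in acquisition time; both stages of a patient
must have equal N), ROI crop (default centred 445×445; per-sequence
boxes are configurable since the original box placement was manual),
median denoise (3×3, the smallest edge-preserving kernel; reflect
padding without edge duplication), and bilinear resize to 128×128.
Intensities are 8-bit values divided by 255; coordinates are 0-based,
half-open, row-major.

Geometric augmentation draws ONE transform (rotation ±15°, horizontal/
vertical flips, zoom 0.9–1.1 by default) per call and applies it
identically to both stage images — independent draws would destroy the
cross-stage correspondence the architecture exploits.  Mixup blends two
pairs and their one-hot labels with a single λ ~ Beta(0.2, 0.2) (the
original Mixup setting; unstated in the source) and mixes arbitrary
random pairs, not only across classes.  Minority upsampling duplicates
minority-class *training* pairs with fresh geometric transforms until
the class counts match; although the source text says transforms were
applied to non-pCR examples, non-pCR is the majority class, and the
stated goal (quantity balance) dictates upsampling the minority (pCR).

Evaluation: the decision threshold is 0.5 on the pCR probability
(unstated; the standard softmax choice).  The panel is accuracy,
sensitivity, specificity, PPV, NPV and F1 = 2TP/(2TP+FP+FN); undefined
ratios (zero denominators) are reported as missing, never as 0.  AUC is
computed as the tie-corrected Mann–Whitney pair statistic via ranks;
the ROC curve itself comes from scikit-learn.  DeLong's structural
components give the AUC variance (normal-approximation CI, no logit
transform, clipped to [0, 1]) and, with the cross-model covariance, the
paired z-test for two correlated AUCs on the same items.  Mann–Whitney
U uses exact enumeration for tie-free samples with both n ≤ 8 and the
tie-corrected normal approximation otherwise.  `reconstruct_confusion`
inverts a printed (accuracy, sensitivity, n_pos, n_neg) panel to
integer counts by exhaustive search and refuses to guess when the
solution is not unique.  A patient-level mean-score aggregate is
provided but the image pair remains the default evaluation unit.

## The scaled-down ("desk") study profile

Training the full 77M-parameter network on CPU is impractical, so the
ablation and end-to-end machinery ships with a first-class scaled
profile: 32×32 inputs rendered at network size, channels divided by 8
([8, 16, 32, 64], fc width 128), float32, 100 patients with 4–6 frame
pairs each, 30 epochs — architecture, sharing/pooling layout, fusion
weights and the training recipe unchanged.  These sizes are the
package's chosen study conditions for CPU runs; the methods and code
are identical at full scale.

The desk cohort's generator settings differ from the synthetic
defaults in two places, by design.  With the default shrinkage ranges
the stage-2 lesion is near-zero for every responder, so the stage-2
image *alone* separates the classes perfectly and a single-timepoint
model saturates at AUC 1.0 — unlike the clinical situation, where the
post-cycle-1 image alone is only moderately informative.  The desk
profile therefore widens the stage-1 size prior (semi-axes 6–30% of
the canvas) and moderates responder shrinkage to U(0.35, 0.65) (factor
ranges still disjoint from the non-responder U(0.8, 1.1)).  Stage-2
absolute size then carries partial information while the relative
change remains the dominant signal.  Over seeds 1–5 this yields median
test AUCs of 0.955 (dual), 0.854 (post-only), 0.453 (pre-only) —
reproducing the qualitative ordering that motivates the dual-branch
design: pre-treatment alone at chance, post-cycle-1 alone mid-range,
the pair clearly best.

## Known limitations

* The phantom has no acoustic shadowing, no depth-dependent gain, no
  anatomical context; a model that aces it has only demonstrated it can
  read size/texture change out of speckle.
* Real performance numbers from the private clinical cohort are not
  reproducible here and are not claimed; the package reproduces the
  in-protocol derivable quantities (metric-panel arithmetic,
  architecture inventory, split composition) and the qualitative
  orderings.
* The DeLong CI slightly undercovers at n = 200 + 200 (≈93–95% observed
  for nominal 95%), as expected for the untransformed normal
  approximation.
* Single-threaded NumPy training is ~60 s per desk-profile model; the
  full-scale recipe (500 epochs, 128×128, 64–512 channels) is supported
  by the same code but not practical without an accelerator framework.
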