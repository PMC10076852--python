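# Methods

## The segmentation problem and the model

Lung lesions in CT slices are small — often a few to tens of pixels
across — and their grey values sit close to the surrounding parenchyma.
A plain encoder-decoder therefore tends to miss them (undersegmentation)
or bleed across their blurred boundaries (oversegmentation).  RAD-UNet
addresses this with three modifications to a U-Net backbone, each
implemented as an independent, unit-tested block:

**Residual encoder.**  Each encoder stage is a pair of residual units,
`out = ReLU(conv3x3(ReLU(conv3x3(F))) + shortcut(F))`, with a 1×1
projection shortcut when the channel count changes.  Downsampling
between stages uses 2×2 max pooling, the U-Net convention; this also
keeps every convolution at stride 1, which the autodiff core exploits
(see *Numerical core*).

**Improved ASPP bottleneck.**  Five parallel branches at the coarsest
resolution: a 1×1 convolution, three 3×3 atrous convolutions at rates
(2, 3, 4), and image-level average pooling with a 1×1 convolution
broadcast back over the grid; outputs are concatenated and projected by
a 1×1 convolution, with ReLU after every branch.  The small rates are
deliberate: stacked atrous 3×3 layers accumulate receptive field as
`RF_0 = 1, RF_i = RF_{i-1} + (k−1)·r_i` (so 3, 7, 15 at rates 1, 2, 4),
and small rates keep the effective kernel dense enough for few-pixel
targets.  `stacked_receptive_field` implements exactly this recurrence.
An alternative rate set (2, 4, 6) is selectable through
`RADUNetConfig.aspp_rates`; both readings of the design circulate, and
(2, 3, 4) is the default because it is the one the block diagram
enumerates.

**DFCF decoder.**  Each of the four decoder stages upsamples the deep
stream bilinearly (×2), projects its channels with a 1×1 convolution,
and fuses it with the same-resolution encoder skip through dual-feature
cross-fusion.  Naming: the skip carries *local* semantic features (LSF),
the upsampled deep stream carries *global* semantic features (GSF).
Branch A multiplies the GSF by channel-attention weights computed from
the LSF; branch B multiplies the LSF by channel weights computed from
the GSF.  Each branch then passes a spatial-attention stage, and the two
branches are combined by concatenation + 1×1 convolution (default) or
summation (`dfcf_combine="sum"`).  The cross structure — weights from
one stream applied to the other — is the point of the module and is
asserted by test.

Three genuinely open design points, and the choices made:

* *Branch parameter sharing.*  One CAM and one SAM are shared by both
  branches.  The two branches are described identically, and sharing
  makes the module symmetric (identical input streams produce identical
  branches), which is also the cheaper choice in parameters.
* *SAM input.*  The spatial weights are computed from the branch's own
  post-multiplication map by default (`dfcf_sam_source="self"`), which
  keeps SAM a well-posed map on one tensor; computing them from the
  opposite raw stream is available as `"other"`.  The two readings are
  both defensible from the module's prose description.
* *Upsampling.*  Bilinear interpolation + 1×1 projection; a transposed
  convolution would add parameters without changing the contract.

The head is a 1×1 convolution + sigmoid: per-pixel lesion probability in
(0, 1), same spatial size as the input (asserted for 64 and 128 px
sides).  Binary masks come from thresholding at 0.5 by default; the
threshold is exposed because it is not part of the architecture.

## Attention blocks

Channel attention (CAM): `σ(MLP(AvgPool F) + MLP(MaxPool F))` with a
shared two-layer bottleneck MLP (`W0 ∈ R^{C/r×C}`, ReLU, `W1 ∈ R^{C×C/r}`),
expressed as 1×1 convolutions on the 1×1×C pooled descriptors.  The
reduction ratio defaults to r = 16 (the usual CBAM convention; it is not
fixed by the design) and is configurable; tiny test models use r = 2 so
the bottleneck stays ≥ 1 channel.  Spatial attention (SAM): channel-wise
average and max maps concatenated to H×W×2 and convolved with one 7×7
kernel, then sigmoid.  CBAM applies CAM then SAM multiplicatively.  The
zero-parameter closed forms (all weights zero ⇒ every attention weight
is σ(0) = 0.5, CBAM output = 0.25·input) are exact and used as tests.

## Loss

`L = L_BCE + L_Dice`, the standard compound objective for sparse
foregrounds.  BCE is the per-pixel mean with probabilities clamped to
[1e-7, 1−1e-7] before the logarithm.  The Dice term uses symmetric
smoothing s = 1 in numerator *and* denominator:
`1 − (2Σyŷ + 1)/(Σy + Σŷ + 1)`.  Smoothing only the numerator would
leave the all-background case undefined (0/0); the symmetric form is
exactly 0 for any perfect match, differentiable everywhere in (0, 1),
and indistinguishable from the unsmoothed form once the sums are large.
Over a batch the Dice term is computed on the pooled sums (batch-global
Dice), which is the stabler variant for very sparse masks.

## Metrics

All metrics derive from per-image pixel confusion counts:
IoU = TP/(TP+FP+FN), recall = TP/(TP+FN), precision = TP/(TP+FP),
F1 = harmonic mean, mIoU = mean of per-image IoU.  Averaging convention:
per-image metrics averaged over the evaluation set (image-averaging);
a two-class variant that averages foreground and background IoU is
available behind `include_background=True`, since either reading of
"mean" IoU is found in practice.  Degenerate denominators are explicit:
both-masks-empty gives IoU 1.0 (a correct empty prediction); every other
zero denominator gives 0.0.  Note the documented consequence that the
ordering chain IoU ≤ min(P, R) ≤ F1 ≤ max(P, R) holds whenever any mask
is nonempty but *not* in the both-empty case (IoU 1, P = R = 0 there).
Per-size-class reports assign each image to the class of its largest
ground-truth lesion (micro ≤ 5 mm, small 5–10, nodule 10–30, mass > 30;
boundaries belong to the smaller class).

## Synthetic phantoms

The generator emulates the data regime that makes the problem hard, not
lung anatomy: a low-frequency Gaussian random-field background
(white noise smoothed at σ = side/8, rescaled to σ = 0.08 around mean
0.35), plus one disk-shaped contrast bump per nodule (Δ = 0.25 on the
[0, 1] scale), Gaussian edge blur (σ = 1 px) applied to the bump only,
and i.i.d. pixel noise (σ = 0.02).  The ground-truth mask is the exact
pre-blur disk rasterization — truth is geometric and unambiguous; blur
and noise degrade only the image.  Defaults: 64×64 px, 1–2 nodules per
slice, radii 2.0–5.5 px at 1.0 mm/px spacing (diameters 4–11 mm, i.e.
micro and small nodules, with the occasional merged pair reaching the
10–30 mm class).  These defaults keep the foreground below 5% of pixels,
preserving the small-target premise.  All randomness flows from the
single `PhantomSpec.seed` (per-sample seeds are spawned from it), so a
spec is a complete, bit-reproducible description of a dataset.

What the phantoms do *not* model: vessel-attached or juxtapleural
morphology, non-spherical lesions, anatomical context (airways, chest
wall), slice-to-slice correlation, or scanner-specific noise texture.
Passing the phantom experiments therefore demonstrates that the
architecture, loss, optimizer and pipeline are implemented correctly and
can learn low-contrast small targets — not that the model reaches any
particular accuracy on clinical CT.

## Preprocessing

CT windowing maps `[level − width/2, level + width/2]` linearly onto
[0, 1] with clipping; "window position" is read as the window center,
standard radiology usage.  The lung setting for LIDC-style data is
level 250 HU, width 1490 HU.  A level-500 variant is used by some
thoracic protocols and is simply a different `WindowSpec`; it is
unusually high for lung display, and is passed through as given rather
than second-guessed.  Phantoms and other already-normalized inputs use
the identity window (level 0.5, width 1).  Train-time augmentation is
left-right and up-down flips, each applied independently with
probability 0.5 from the training seed; flips act jointly on image and
mask so geometry is preserved.

## Training protocol

Defaults follow the reference protocol: Adam, initial learning rate
1e-3, batch size 64, 300 epochs, no learning-rate schedule.  A held-out
fraction of the training set (15% by default) serves for model
selection, and the checkpoint with the best validation F1 is returned —
no early-stopping rule is part of the protocol, so best-F1 checkpointing
is this package's choice.  Non-finite loss aborts with a diagnostic.
The phantom experiments in the tests and the worked example use a
CPU-scale profile chosen by the package — 200 train / 50 test 64×64
phantoms, `base_channels=8` (≈1.08 M parameters), batch 8, 12 epochs —
which reaches ≈88% test mIoU from an untrained baseline of 0 in about
two minutes.

## Numerical core

With no GPU framework among the dependencies, the package carries its
own small reverse-mode autodiff on float32 numpy arrays (`radunet.nn`):
a tape of closures over NCHW tensors.  Convolutions are stride-1 only
and im2col-based, so forward, weight-gradient and input-gradient are all
BLAS matrix products (the input gradient is a correlation with the
180°-rotated, channel-transposed kernel at padding `d(k−1) − p`).
Max pooling routes gradients to the argmax (ties split evenly in the
generic reduction, first-occurrence in the 2×2 pool); bilinear ×2
upsampling uses half-pixel-center coefficients with an exact transpose
as backward.  The sigmoid uses the two-sided stable form.  Every op's
gradient is checked against central finite differences in the test
suite, and full-model gradient flow (no dead parameters) is asserted on
a tiny configuration.  Parameter initialization is Kaiming fan-in for
convolution weights and zeros for biases, drawn from a generator seeded
by `RADUNetConfig.seed`; builds are bit-deterministic.

## Known limitations

* Stride-1-only convolutions: downsampling must come from pooling.
* Single-channel, single-class (binary) segmentation only; 2-D only.
* CPU-bound: the training profile above is the practical desk scale;
  clinical-scale training (512×512, batch 64, 300 epochs) would need a
  GPU framework behind the same interfaces.
* The phantom realism limits listed above apply to any accuracy claim.
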