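# Methods

## Problem and approach

`kneemark` automates the imaging assessment of patellofemoral instability
(PFI) on 2-D knee images. Thirteen anatomical landmarks across three
acquisition protocols (two axial: *trochlear sulcus*, *proximal trochlea*;
one sagittal: *patellar height*) determine eight standard indices:

* trochlear dysplasia — sulcus angle (SA), trochlear facet asymmetry (TFA),
  trochlear groove depth (TGD), lateral trochlear inclination (LTI);
* patellar height — Insall-Salvati (ISI), modified Insall-Salvati (MISI),
  Caton-Deschamps (CDI), patellotrochlear index (PTI).

Landmark detection is cast as heatmap regression: each landmark label is a
channel of a per-pixel classification problem. A landmark at (a, b) is
encoded as a Gaussian channel

    H_i(x, y) = exp(-((x-a)^2 + (y-b)^2) / (2 sigma^2)),

rescaled so its discrete maximum is exactly 1, with a shared background
channel H_{L+1} = 1 - sum_i H_i so the channels form a per-pixel probability
distribution. The background channel absorbs the severe class imbalance
between landmark neighbourhoods and the rest of the image. A U-Net predicts
the L+1 channels with a per-pixel softmax head; decoding takes the hard
argmax of each landmark channel (ties break to the first maximum in
row-major order; no sub-pixel refinement).

### Handling details the encoding leaves open

* **Sub-pixel annotations.** For a continuous centre the discrete Gaussian
  maximum is below 1; each channel is divided by its own maximum so the
  "peak = 1" property holds at the nearest pixel. This is the identity for
  integer centres.
* **Overlapping Gaussians.** Where the summed landmark channels exceed 1 the
  background is clamped at 0 and the stack renormalised per pixel, so
  conservation (sum = 1) holds for every configuration. At such pixels the
  peak value can drop below 1; the two properties cannot both hold under
  overlap and conservation is the one the loss depends on.
* **sigma.** Not fixed by the problem; default 5 px at 320x320, exposed in
  `NetworkConfig`. Detection on phantoms is insensitive across sigma ~ 3-10;
  wider Gaussians give the optimiser more foreground signal early in
  training, narrower ones sharpen peaks.

## Network and training

The U-Net has 5 resolution levels, two 3x3 same-padded convolutions with
ReLU per level (He-normal init), a dropout layer after the first convolution
of each level (0.1, 0.1, 0.2, 0.2, 0.3 down the encoder; 0.2, 0.2, 0.1, 0.1
up the decoder), 2x2 max pooling, 2x2 transposed-convolution upsampling with
same-level skip concatenation, and a 1x1 convolution head. Feature widths
double per level from `base_filters` (32 at full scale). Same-padding keeps
the output spatial size equal to the input, as the equal-size heatmap
targets require. Output channels are landmarks + 1: 6, 3 and 7 for the
three protocols.

Training minimises categorical cross-entropy between the softmax output and
the *soft* Gaussian target stacks, averaged over pixels and batch (a sum
would tie the learning-rate scale to image resolution). Optimiser is Adam,
fixed learning rate 1e-3, batch 16, 200 epochs at full scale; the checkpoint
with the lowest validation loss is kept. Targets are the soft stacks rather
than thresholded one-hot maps: the encoding and the loss then fit together
without an arbitrary binarisation threshold.

The network core is implemented directly in NumPy (NHWC float32, each 3x3
convolution evaluated as nine shifted batched matrix products so the work
lands in BLAS sgemm, explicit backpropagation, inverted dropout, Adam). All
randomness — initialisation, shuffling, dropout, augmentation — flows
through seeded generators, so single-threaded runs are bit-reproducible.
Backpropagation is verified against float64 central differences in the test
suite.

## Augmentation

Eight training-time operations, each applied independently with probability
0.5 per sample: pixel multiplication [0.75, 1.25], additive pixel shift
[-0.15, 0.15], left-right flip, zoom [0.9, 1.1], rotation [-10, 10] deg,
per-axis translation [-5, 5]%, Gaussian noise (std 0.01 of the intensity
range) and Gaussian blur (sigma drawn from [0.5, 1.5] px). Geometric
operations are composed into one affine map about the image centre and
applied identically to pixels (bilinear, zero padding) and to landmark
coordinates; photometric operations touch pixels only. The order is fixed:
geometry, multiply, shift, noise, blur, clip to [0, 1]. Draws that push a
landmark off the grid are resampled (bounded retries). The per-operation
probability and the noise/blur magnitudes are package choices; the flip is
valid because the data mix left and right knees and channel semantics are
side-agnostic.

## Geometry of the indices

All constructions run on physical points (pixel coordinates times per-axis
mm spacing), which makes anisotropic spacing safe; SA and LTI are angles,
TGD is in mm, the rest are ratios. Conventions that the standard definitions
leave to the implementer:

* TFA is medial over lateral facet length, d(T4,T5)/d(T4,T3).
* TGD heights are perpendicular distances from the posterior condylar line
  (T1-T2); a flat or convex trochlea gives TGD <= 0.
* LTI takes its posterior condylar reference from the paired trochlear-
  sulcus slice of the same knee (the proximal-trochlea slice carries only
  T6/T7); the two slices are assumed rotationally aligned within a series.
* MISI and CDI use d(P1,P2) as the articular-length denominator, the closest
  proxy available from the annotated landmark set.
* PTI projects P3 orthogonally onto the P1-P2 axis and measures the overlap
  to P2, clamped at 0 when the projection falls distal to P2.

`measure_all` computes every index whose landmarks are present and reports
missing-landmark skips explicitly.

## Coordinate and resampling conventions

Coordinates are 0-based, continuous, (x = column, y = row). Intensities are
min-max scaled to [0, 1] per image (a constant image maps to zeros). Resizing
is bilinear without aspect-ratio preservation: coordinates scale by
(W/W0, H/H0) and spacing by the inverse, so physical positions
coordinate x spacing are invariant; anisotropy is absorbed by the per-axis
spacing. Splits are patient-wise: hold-out patients go to the test set
whole, the remaining image records are shuffled with a required seed and cut
at round(0.8 n); no stratification beyond that.

## Evaluation statistics

* SDR_R = #{i : ||t_i - p_i|| < R} / N x 100, strict inequality, R in
  {1, 1.5, 2, 2.5, 3, 4, 5} mm by default.
* MAE is the mean Euclidean distance in mm; STD uses the sample (n-1)
  convention.
* Index agreement uses ICC(2,1) — two-way random effects, absolute
  agreement, single measurement — with an F-based 95% CI (via pingouin),
  because the claim is agreement between the automatic measurement and the
  reference, not mere consistency. Reliability grades: poor < 0.5,
  moderate [0.5, 0.75), good [0.75, 0.9], excellent > 0.9. Degenerate
  zero-variance inputs return ICC 0 with a warning rather than NaN.

## Synthetic phantoms

The phantom generator renders stylised knee slices — soft-edged ellipses for
condyles and patella, Gaussian-profile ridge bands for facets, cartilage,
tendon and plateau, plus small marker bumps — with landmarks placed at the
exact generating coordinates, speckle noise and a mild blur. Construction
parameters are sampled first (uniformly over configurable ranges spanning
normal and dysplastic shapes: SA roughly 120-170 deg, ISI 0.6-1.6, PTI
0.15-0.9, CDI 0.6-1.4, groove depths down to near-flat), so TGD, LTI, ISI,
CDI and PTI ground truth is known in closed form before any measurement
code runs; SA, TFA and MISI follow arithmetically from the constructed
coordinates. Default canvas is 128x128 at 0.8 mm isotropic spacing. Cohorts
assign 2-3 images per synthetic patient (or, in whole-knee mode, three
rotationally aligned protocol slices per knee) so patient-wise splitting is
exercised.

What the phantoms deliberately do not model: MRI contrast physics (PD/T1/T2),
pathology textures, metal artefacts, anatomical shape variability beyond the
parameter ranges, and inter-observer annotation noise. Passing phantom tests
therefore demonstrates that the pipeline — encoding, network, decoding,
geometry, statistics — is correct and learnable end to end, not that
clinical-grade accuracy transfers to real MRI.

## Desk-scale end-to-end run

The end-to-end check trains one model per protocol needed at reduced scale:
128x128 inputs, base 16 filters, 300-phantom cohorts (250 train / 50
validation) with 50 additional held-out phantoms, sigma 4.5-6 px (narrower
for the sagittal protocol, whose distal landmarks lie closest together),
batch 8,
learning rate 2e-3, and 12 (axial) / 16 (sagittal) epochs — within a
40-epoch cap — keeping the lowest-validation-loss checkpoint; all seeds
pinned. The smaller batch and the doubled learning rate
compensate for the short schedule — at this scale an epoch is only ~34
optimiser steps, so the full-scale defaults (batch 16, lr 1e-3, 200 epochs)
would be needlessly slow to converge within the cap. Success is measured as
SDR within 5 px on the held-out phantoms and ICC between ground-truth and
predicted-landmark indices.

## Known limitations

* The detector is 2-D and per-slice; slice selection is upstream.
* Decoding is integer argmax, so landmark precision is bounded by the pixel
  grid (no sub-pixel refinement by design).
* The NumPy training core is single-threaded CPU code: adequate for
  desk-scale phantoms, not for full-scale clinical training runs.
* ICC confidence intervals assume the standard two-way ANOVA normality
  approximations.
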