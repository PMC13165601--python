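# Methods

## Problem setting and model

The package treats 2D transmission ultrasound tomography as a direct
signal-to-image learning problem.  The object of interest is a per-pixel
speed-of-sound (SoS) map on a 153×153 region of interest (0.25 mm/pixel,
38×38 mm²).  Instead of regressing continuous SoS, the value axis is
quantized onto an ordered grid — water (label 0) at 1500 m/s and seven
levels from 900 to 2250 m/s in steps of 225 — so the network solves a
per-pixel 8-class segmentation problem.  Quantization is the nearest-
representative map over all eight representative values, ties broken to
the lower label; it is total on finite inputs and exactly inverted by the
label→value rendering on the label set.

The network consumes the raw multistatic measurement tensor
(n_tx × time × n_rx, default 32 × 1001 × 32).  Each transmitter's
time × receiver record passes through one **shared-weight input network**:
a stem convolution, three shape-shifting encoder stages, two unpadded
("valid") convolutions for fine size trimming, and two transposed
convolutions (kernel 3, stride 3) that land exactly on 153×153
(17 → 51 → 153).  The 32 output feature maps are concatenated channel-wise
and fused by the **output network**, a three-level nested-skip grid in the
UNet++ style with a ×3 scale (153 → 51 → 17) and level widths (f, 3f, 9f),
ending in a 1×1 head and softmax.

Building blocks: residual "ConvNeXt-style" blocks (spatial convolution →
channel layer-norm → 1×1 expansion ×4 → SELU → 1×1 projection → residual
add; depthwise spatial convolution in the output network, full dilated
convolution inside Shift Units), and squeeze-and-excitation (SE) channel
gates after concatenations.  A **Shift Unit** is a three-stage reshaping
unit: stages 1–2 run three parallel dilated blocks with distinct kernels,
each followed by a strided shape-shift convolution, concatenated with a
strided skip of the stage input and SE-gated; stage 3 processes at
constant shape with a new kernel.  The three per-stage outputs are fused
(stage-1 output aligned by a strided 1×1 convolution) into the stage's
output channels.

Variants: `large` uses Shift Units in encoder stages 1–3 and paired blocks
at the designated processing sites; `base` replaces each Shift Unit with a
single strided convolution of equivalent total stride; `small` additionally
uses single blocks at the paired sites.

## Width calibration

The published description fixes the topology of the three variants and
their exact trainable-parameter totals, but not every per-stage filter
count.  The free widths were therefore solved by integer search in three
triangular steps: (1) the widths of the doubled-block sites (output-net
base width f = 58; valid-stage widths 208 and 245; decoder widths 79 and
8) from the small→base difference; (2) the encoder/stem widths
(16, 64, 112, 368) and the output-net SE bottleneck widths (4, 30, 22, 55)
from the small total; (3) the Shift-Unit internals (path/skip/align widths
and SE bottlenecks per stage) from the base→large difference.  The search
used the real constructors, so the frozen configuration reproduces all
three totals exactly (21,292,904 / 15,360,264 / 11,648,200) with shared
input-network weights counted once.  SE bottleneck widths double as the
fine-grained calibration knob; their defaults are therefore irregular.
This reverse-engineering recovers *a* width assignment consistent with the
published budgets, not necessarily the original one.

## Forward simulator

The acoustic model is the constant-density 2D wave equation
p_tt = c(x)² ∇²p + s with a point source injecting a Ricker pulse
(dominant frequency 0.8 MHz, 3.2 µs truncation window, unit peak).  It is
discretized with a 4th-order spatial stencil and 2nd-order leapfrog time
stepping.  At 0.25 mm and 0.8 MHz the grid carries ~7.5 points per
wavelength; the 2nd-order stencil (also available, `spatial_order=2`) has
a visible dispersion tail there, which is why 4th order is the default.
The solver sub-steps internally so that dt ≤ 0.9·dx/(c_max·√2)·(√3/2), the
von Neumann limit of the wide stencil with a 0.9 safety factor, and
records pressure at every element at the 0.1 µs output interval; the first
sample is the quiescent field at source onset, giving 1001 samples for
1000 recorded steps.

Boundaries are an exponential-damping sponge: a quadratic ramp of
absorption over the 20-pixel layer with per-output-interval edge strength
0.2.  These values were tuned against a free-field reference (a much
larger grid), not against the recorded coda, because the coda also
contains the genuine dispersive tail of the direct arrival; the measured
boundary reflection is below ~1% of the direct peak.  The recorded
quantity is raw grid pressure in solver units; absolute amplitude carries
no physical calibration, which is irrelevant for learning and for all
amplitude-ratio contracts (linearity, reciprocity, SNR).

Sensors are point sources/receivers rounded to grid nodes, indexed
clockwise from the topmost position (for the square, from the top-edge
midpoint), on a 64 mm circle (256 px) or square.  The default grid extent
is 301 px rather than 256 + 2·20: the odd extent gives an integer center,
and the two extra pixels keep the outermost rounded sensor positions
strictly outside the absorbing layer.  The emitter's own channel is
recorded (zeroing it is a config option), so the tensor is exactly
n_tx × (T+1) × n_tx.

Additive white Gaussian noise uses σ² = P_signal/10^(SNR/10) with the
signal power taken over the whole tensor (per-trace mode available);
calibration is within ±0.1 dB at the default tensor size.

## Phantoms

Disc phantoms: a primary disc (radius 70 px) on water, carrying a random
grid level, with 1–4 inner discs (radii uniform in [6, 25] px) painted
over it in order — overlaps deliberately produce nested/contour
structures.  Grid distortion perturbs a 5×5 control lattice by ±strength
pixels, interpolates the displacement bicubically and resamples labels
nearest-neighbour, so no new classes appear.  Dataset variants: original
(no warp), distorted (all warped), mixed (each sample warped with
probability 1/2).

Brain-like phantoms are a synthetic stand-in for MRI-derived anatomy:
nested deformed ellipses (smooth low-order angular wobble) forming skin,
fat, cortical skull, cancellous skull, CSF, gray matter and white matter
around a white-matter interior with carved gray pockets and CSF
ventricles.  Default per-tissue SoS ranges (m/s): skin 1600–1650, fat
1430–1470, cortical skull 2800–2900, cancellous skull 2200–2400, CSF
1500–1520, gray 1530–1550, white 1550–1570 — physiologically ordered,
user-overridable.  Pixel SoS is drawn uniformly within its tissue range,
so re-binning the continuous map by range recovers the labels exactly.

## Objective and metrics

Combined loss = focal + Dice (unit weights).  Focal defaults γ = 2,
α = 1 (no per-class weighting is published); probabilities are clipped to
[1e−7, 1−1e−7] before logs.  Dice loss is computed per class with
ε = 1e−5 and averaged over classes, matching the evaluation convention.
Metrics: per-class and macro Dice and IoU (classes absent from both maps
are excluded from the macro mean; absent from one score 0), pixel
accuracy, SSIM on the rendered SoS images with global image statistics
(c1 = (0.01L)², c2 = (0.03L)², L = scheme SoS span; a 7×7 sliding-window
mode is available), HD95 as the macro-averaged 95th percentile of
symmetric nearest-boundary distances (8-connectivity erosion boundaries),
and boundary F1 with a 1 px match tolerance.

## Training and phases

Adam (β = 0.9/0.999), Kaiming-normal initialization (fan-in) with zero
biases, batch size 10, early stopping on validation combined loss with
patience 10 and best-weight restoration.  Default learning rates follow
the published grid-search winners (8e−5 undistorted, 5e−5 otherwise);
the tiny profile uses larger rates (1e−3 from scratch, 3e−4 for
fine-tuning) appropriate to its much smaller model.  Transfer learning
loads a checkpoint and fine-tunes all layers.  The three phases —
(1) from-scratch on clean disc data, (2) transfer to 3 variants × 3 SNR
levels (20/30/40 dB), (3) transfer to a square array or brain phantoms —
run through one orchestrator at any scale; the full-scale sample counts
(18000/2000/2000 etc.) are one configuration away but are not the testing
default.

## Desk-scale study conditions

Because no GPU deep-learning stack is assumed, the network and training
run on a numpy autodiff engine, and all learning claims are exercised on
a **tiny profile**: 8 sensors on a 15 mm ring, 27×27 ROI (the ×3 grid
needs a size twice divisible by 3: 27 → 9 → 3), 200+1 time samples,
4 SoS classes (water + 1125/1575/2025 m/s), and width-reduced models of
the same architecture family.  Under these conditions the small variant
memorizes 8 phantoms to training Dice ≥ 0.9 within 200 epochs, and
fine-tuning a clean-data model on noisy re-acquisitions of the same
phantoms (SNR 20 dB, independent noise draws for adaptation and
validation) reaches a validation-Dice bar in fewer epochs than training
from scratch on every tested seed.  What these scaled-down runs show is
that the architecture, objective and transfer protocol produce the
qualitative learning behaviour claimed at full scale; they do not certify
full-scale accuracy numbers, which would require the complete simulated
corpus and GPU training.

The synthetic generators emulate the statistical structure of the original
study's data (quantized or range-sampled SoS, ring/square sensing, Ricker
excitation, calibrated noise) but not every property of real measurements:
no attenuation or density contrast, no transducer directivity or
bandwidth shaping, idealized point sensors, and a synthetic brain geometry
rather than MRI-derived anatomy.

## Numerical choices and degenerate inputs

Argmax decoding breaks ties toward the lower class index.  Non-finite
inputs are rejected at validation boundaries (quantization, SoS maps,
measurement tensors); the solver aborts if the field amplitude exceeds
10⁶ × the source peak; training aborts on a non-finite loss with the
epoch/batch in the message.  SNR is undefined (error) for an all-zero
tensor.  HD95/boundary-F1 skip classes missing from one map with a
warning and fail only if no class is shared.  All generators and training
runs are reproducible from explicit integer seeds; forward passes are
deterministic.

## Known limitations

Single acoustic parameter (SoS) only; 2D; point sources; the FDTD
stand-in is not bit-compatible with pseudospectral solvers (its contracts
are the physics invariants: travel times, reciprocity, linearity, energy
decay, boundary absorption).  The calibrated widths reproduce the
published parameter budgets but are not guaranteed to match the original
per-layer layout.  The numpy engine makes full-scale (32-sensor, 153×153)
training impractical — that path exists for completeness and small-batch
inference, not throughput.
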