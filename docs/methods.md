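# Methods

## The problem

Ptychography scans a coherent beam across a sample with spatial overlap
between neighbouring illumination spots and records far-field diffraction
intensities. Because the detector measures only |Ψ|², the sample's phase
must be recovered computationally. Iterative engines (here rPIE) do this
well but need the overlap constraint and many passes over the data, which
rules out live imaging at kHz frame rates. This package models the
alternative workflow: use the iterative engine *offline* to label data as it
arrives, continually train a small convolutional surrogate that maps one
diffraction frame to one phase patch in a single pass, and stitch those
single-shot inferences into a live image. Because the surrogate treats each
frame independently, the overlap constraint disappears, which is what
enables sparse (low-dose) scanning.

## Forward model and simulator

The simulator is a thin-sample, fully coherent far-field model:

* object transmission `T = a·exp(iφ)` with `a ∈ (0,1]` and φ inside a
  declared range (default [−0.4, 0] rad, well away from wrapping);
* exit wave `ψ = P · T_patch` with the probe `P` normalised to unit power;
* detector intensity `I = photons · |F{ψ}|²` with a centred orthonormal FFT,
  so `Σ I = photons · Σ|ψ|²` exactly (Parseval); `photons = flux_scale ×
  exposure_ms` is the expected photon budget through a unit-power probe;
* optional Poisson sampling with a seeded 64-bit generator, stored as
  unsigned 32-bit counts. Noiseless stacks keep the float expectation
  (integer rounding would break the Parseval identity that tests rely on).

Positions are in nanometres, x right / y down; the scan position is the
centre of the probe window, rounded to the nearest object pixel in the
forward model (interpolation is reserved for labels and stitching). All
reconstruction grids snap their origin to the same pixel lattice so that
nearest-pixel rounding is consistent between simulation and inversion —
without this the solver sees a systematically inconsistent data set and its
error floor rises by orders of magnitude.

The spiral is a constant-arc-length Archimedean spiral `r = aθ` with ring
pitch `2πa` equal to the step S, so consecutive-point and adjacent-winding
spacings both sit near S (median nearest-neighbour spacing within 5%).
The overlap ratio is `1 − √3·S/B` for beam size B; 0.9 at S=50 nm, B=800 nm.

The defocused zone-plate illumination is emulated as a hard annular pupil
(inner/outer radius ratio 0.4) with a quadratic defocus phase plus a smooth
seeded phase texture (rms 1.5 rad, correlation length ~n/24 pixels). The
texture plays the role of optic aberrations; without it the perfectly
symmetric ring sums coherently on axis and produces a bright axial spot
(the Arago effect) instead of the characteristic donut. The defocus is
bisected until the measured intensity FWHM — twice the outermost radius at
which the azimuthally averaged intensity is half its peak — matches the
requested spot size within 5%.

Phantoms are binary-etched: a smoothed random field thresholded at its
median (`random_etch`) or scattered stroke-rendered capital letters
(`letters`), mapped to the two phase levels with a 1-pixel edge blur.
These emulate lithographically etched test patterns with a fixed refractive
index; they do not contain grey levels, amplitude contrast, or topography.

## Iterative engine (rPIE)

Sequential projections with per-iteration reshuffled visit order (seeded).
For each position: propagate all probe modes, replace the modulus of the
summed intensity by the measurement (distributing amplitude across modes in
proportion to their modelled intensities), back-propagate, and update

* object: `O += Σ_m conj(P_m)·Δψ_m / ((1−α)|P|² + α·max|P|²)`, α = 0.25;
* probe (optional, from iteration 10): same form with roles swapped,
  β = 0.9; modes re-orthogonalised by Gram–Schmidt each iteration.

The retrieved phase is defined only up to a constant. By default each
reconstruction is *anchored*: the coverage-weighted circular mean phase is
rotated to zero. This convention makes labels cut from different scans of
one sample mutually consistent — without it each scan's labels carry a
different arbitrary offset and a network trained across scans must absorb
contradictory targets (in trials this cost tens of SSIM points on held-out
regions).

The per-iteration data error is `Σ(√I_meas − |Ψ_model|)²/ΣI_meas`. On
noiseless data with the true object and probe the error is at machine
precision (≤1e-10) and the object does not move — the fixed-point identity
used as the solver oracle. On a 200-frame, 64-pixel-probe spiral at overlap
0.9 the engine reaches SSIM ≥ 0.95 against the phantom from a random
initialisation within 300 iterations.

## Surrogate network

A fully convolutional encoder–decoder with one input channel (diffraction
counts) and one output channel (phase), 3×3 kernels throughout:

* encoder: stages of [conv, conv, 2×2 max-pool] at widths 16/32/64/128;
* bottleneck: two convolutions at width 128;
* decoder: stages of [nearest-neighbour 2× upsample, conv] mirroring the
  encoder, then a final convolution to one channel and `tanh·π`, bounding
  the output to (−π, π).

The default spec counts 687,745 trainable parameters (~0.7M), independent
of the input side. The halved widths and the missing amplitude branch are
what distinguish this lightweight variant from its 4.7M-parameter ancestor.
Nearest-neighbour upsampling plus convolution avoids checkerboard
artefacts. There are no skip connections, so the decoder cannot copy
pixel-level noise from the input — labels must be spatially smooth, which
phase maps are.

Input normalisation: by default the network sees the *modulus* √counts
divided by the corpus 99.9th-percentile modulus recorded at training time
(stored in the checkpoint so inference matches training exactly). The
square root compresses the detector's ~6-decade dynamic range; in trials it
trains more reliably at small corpus sizes than raw counts, which remain
available via `NetworkSpec(input_transform="counts")`. No clipping is
applied, so a count-level mismatch between training and inference remains
visible to the network — this is deliberate, and is what the count-variation
tolerance ladder measures.

The engine behind the network is a small NumPy implementation (im2col +
BLAS matmul convolutions, float32 activations) with Adam, mean-absolute-
error loss and a triangular cyclic learning rate (defaults 1e-4 → 5e-4, one
cycle per training increment; the scaled-down acceptance runs use
2e-4 → 1.5e-3, which suits their smaller corpus).

## Continual learning

After each scan the iterative phase is interpolated (bilinearly) onto a
128×128 regular grid centred at each beam position — exact cropping when a
position falls on a grid node, well-defined on the irregular spiral grid
otherwise — and paired with the raw frame. Each training increment appends
the new pairs to the corpus and trains for 50 further epochs; a fresh 10%
validation split is drawn every epoch (seeded), and the epoch snapshot with
the lowest validation MAE becomes the published model, with a strictly
increasing version number. A new campaign always starts from a freshly
initialised network.

The retraining policy stitches the current model's inference on the new
scan and compares it with the iterative phase: mismatch = 100 − SSIM-%.
At or above the tolerance (default 10 points; equality triggers) the
retraining service runs and suspended services resume; below it the
iterative/training services are suspended in favour of a periodic check.

Intensity rescaling supports two low-dose strategies: multiplying incoming
counts by a scale factor before normalisation (no retraining, moderate
factors), and dividing the training intensities by k ≥ 1 with optional
Poisson resampling followed by retraining (large factors).

## Stitching

Patches are bilinearly resampled onto a global regular grid with the
reconstruction pixel size (origin = bounding box of all footprints) and
averaged per pixel, uniformly or weighted by the resampled probe amplitude.
Accumulation is double precision, hence order-invariant to ~1e-15; pixels
with zero accumulated weight are NaN and excluded from every metric. No
phase unwrapping or per-patch offset harmonisation is applied.

## Evaluation

* **Accuracy** is SSIM × 100 between phase images after removing the mean
  phase difference over the valid mask (global-phase gauge freedom):
  Gaussian 11-pixel window, σ = 1.5, K1 = 0.01, K2 = 0.03, data range =
  truth max − min. Masked-out pixels are filled with the truth so the
  windowed statistics stay finite; the SSIM map is averaged over the mask.
* **Overlap sweep**: the dense scan is thinned by keeping every k-th spiral
  point, k chosen so the areal density matches the target step
  `S = B(1−ratio)/√3`; at each ratio a fresh iterative reconstruction and a
  stitched inference are scored against the ground truth on a shared,
  lattice-aligned grid.
* **Resolution**: Fourier ring correlation of two independent
  reconstructions, `|ΣF_a·conj(F_b)|` per ring normalised by the ring
  energies, against the 1/2-bit information threshold (fixed 0.5 optional);
  the resolution is the inverse frequency of the first crossing, bounded
  below by twice the pixel size.

## Scaled-down study conditions

The learning experiments run at reduced size so the whole suite executes on
one CPU: a 32-pixel probe window (16 nm pixels, 440 nm donut), a 200-point
spiral at overlap 0.9 as the training campaign, 1e9 expected photons per
frame, 250 rPIE iterations for labels, and 150 training epochs of the
(16, 32, 64)-width spec (~0.2M parameters). Under these conditions the
trained surrogate scores ~93 SSIM-% stitched at overlap 0.9, ≥ 90 at zero
overlap, > 80 after a 10,000× training-intensity downscale with Poisson
resampling on matched low-count data, and degrades in the expected order as
test counts fall 4×/16×/40× below the training level. The solver oracle
runs at the 64-pixel window with a 700 nm beam. Beamline-scale quantities
(e.g. absolute 35/20 nm FRC resolutions, 86% at 0.5 ms exposure) require
the real instrument, its data rates, and ~10⁵-pair corpora; they are out of
reach of the synthetic desk-scale conditions and are represented here by the
property suite above instead.

## What the simulator does not model

Partial coherence, detector point-spread and dead pixels, scan-position
jitter and drift, sample damage, absolute beamline flux calibration, and
network/hardware transport of the real streaming system (replaced by an
in-process event queue). Passing tests therefore demonstrate the internal
consistency and the learnability claims of the workflow on idealised data,
not detector-specific robustness.

## Numerical choices

* FFTs: centred, orthonormal; float64 physics, float32 network.
* Sub-pixel positions: rounded in the forward model and solver; bilinear
  interpolation for labels, stitching and resampling.
* Poisson sampling: `numpy.random.default_rng(seed)` per stack.
* rPIE denominators are regularised with 1e-12; NaNs raise immediately with
  the iteration index.
* The mismatch-policy boundary assigns equality to the retrain side.
* FRC DC ring is defined as correlation 1 (degenerate after mean removal).
* Spiral parameterisation: Archimedean (constant arc length); the ring
  pitch equals the step by construction.
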