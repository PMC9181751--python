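# Methods

## The estimation problem

A swept-source OCT B-scan images a cross-section of the posterior eye; the
choroid is the band between Bruch's membrane (BM) and the choroid–sclera
interface (CSI). Its thickness at column c is the axial distance
`csi_rows[c] − bm_rows[c]` in pixels (no pixel-to-micron scale is applied
anywhere; all thicknesses are in pixels). The package estimates the *mean*
thickness of a patch, and of a whole B-scan, directly from intensities,
without segmenting either boundary.

## Cropping

The B-scan (N rows × M columns) is divided into K equal-width segments;
patch width m = M/K must divide exactly — an indivisible width raises an
error rather than silently truncating, because truncation would desynchronise
patch pixels from patch labels. Within a segment, candidate vertical offsets
are 0, s, 2s, … up to N − n for stride s and patch height n, with the
terminal offset N − n appended when the stride does not land on it, so the
slide genuinely reaches the bottom row. The offset with the largest summed
intensity over the n × m window wins; ties go to the smallest offset, making
placement deterministic. Intensities are used as stored (normalised to
[0, 1]); multi-channel images are summed over channels before the search.
Coordinates are 0-based, half-open.

## Labels

Thickness is a per-column quantity, so a patch's label is the mean of the
per-column thickness over its columns only — vertical placement selects the
viewing window but cannot change the label. With equal-width disjoint
patches covering the image, the mean of the K patch labels is exactly the
full-width column mean; this identity is what makes "average the patch
estimates" a consistent B-scan estimator, and it is tested to 1e-12.

## The regressor

Seven 3 × 3 convolutions, each followed by a ReLU; a 2 × 2/stride-2 max-pool
after every second convolution (three pools in total); one fully connected
layer to a single scalar. "Same" zero padding keeps the stated patch sizes
(200 × 50 … 400 × 400) compatible with the three poolings; for very large
patches a stride-2 first convolution (`first_conv_stride=2`) bounds the
fully connected fan-in while leaving the architecture unchanged. The
channel ladder is not dictated by the design and defaults to
16, 16, 32, 32, 64, 64, 64 — small enough to train on one CPU core, deep
enough to summarise a patch; it is a configuration field, not a constant.
Pooling kind (max) and the 2 × 2 window are likewise conventional choices.

The network is implemented as a compact numpy engine (`_nn.py`):
im2col-based convolution with analytic backward passes, verified against
central finite differences (relative error ≈ 6 × 10⁻⁵ under a smooth loss).

### Initialisation

Two variants are provided. `xavier_improved` (the default) draws
convolution weights from N(0, 2/fan_in) — the ReLU-corrected Glorot scheme
popularised by the MatConvNet toolchain under that name. Plain `xavier`
(Glorot uniform) is also available, but with seven ReLU stages it
attenuates activations by roughly 0.7 per layer, leaving the fully
connected input at ~0.01 rms; under an MAE loss, whose gradient magnitude
carries no error-scale information, that starves the optimiser and a short
run never improves on a constant predictor. The dense head uses Glorot
uniform (no ReLU follows it); biases start at zero.

## Training

SGD with classical momentum 0.9 and L2 weight decay 5 × 10⁻⁴ applied to
convolution and dense weights (never biases), minimising the MAE loss.
The learning rate is piecewise constant: 0.002 for epochs 1–11, 0.0002 for
12–27, 0.00002 thereafter; 41 epochs and mini-batches of 15 by default.
The optimiser is SGD-with-momentum because momentum and weight decay are
the named hyperparameters of the regimen and it is the classical default
for that pairing. Shuffling is per-epoch and seed-driven; the last
incomplete mini-batch is used, not dropped; a non-finite loss aborts with
the offending epoch and batch named. A run is bit-reproducible for a fixed
seed on a fixed BLAS backend. The final model is the epoch-N state;
`select="best"` restores the best-validation-MAE epoch instead.

One addition to the classical regimen: `init_head_bias_to_label_mean`
(default on) starts the head bias at the mean training label. Under an MAE
loss the output can only drift toward the label mean at a rate bounded by
the learning rate times the feature energy, so a zero-initialised head
spends the first epochs of a short run closing a ~60 px gap; warm-starting
the bias spends them on structure instead. With abundant data and 41
epochs the flag is immaterial; at desk scale it matters.

## Evaluation

MAE = mean |f_s − y_s| and ME = mean (f_s − y_s), each reported ± the SD of
the underlying per-sample error list; population SDs (ddof = 0) are used
and the convention is recorded in the report metadata. PCC is the standard
Pearson correlation (covariance over the product of SDs). Interval tables
report fractions of samples with AE ≤ 5, (5, 10], (10, 15] and > 15 px;
the first bin is right-closed, so an error of exactly 5 counts as small.
Aggregation to B-scan level averages the K patch predictions and K patch
truths per scan and requires complete groups. Two identities follow from
equal group sizes and are enforced in tests: ME is identical at the two
levels, and MAE at B-scan level never exceeds patch level (Jensen).

## The phantom generator

Each phantom draws a per-scan mean thickness uniformly from
`thickness_range` and a mean BM depth from `bm_depth_range`; both
boundaries undulate with a zero-mean sum of three random-phase sinusoids
(wavelengths 120–400 px by default) bounded by `boundary_amplitude`, so the
per-scan mean thickness equals the drawn value exactly and per-column
thickness stays within ± the amplitude. Smooth low-frequency boundaries
reflect the modelling assumption that thickness varies little over a small
regional range — the premise that makes a per-patch mean label meaningful.
The raster is rendered from the boundaries with anti-aliased area-fraction
mixing: vitreous (0.06) above BM, choroidal band (0.55) with dark
blob-shaped vascular texture (low-pass-filtered noise, contrast 0.15),
sclera (0.22) below CSI, plus a Gaussian-profile bright BM line. Speckle is
modelled as multiplicative Gaussian noise clipped to [0, 1] — a nuisance
term, not interference physics. Default geometry is 596 × 800 with
thickness spanning 18–146 px, the union of the ranges a clinical cohort
exhibits; 3-channel output replicates the grayscale render.

What the phantoms do *not* emulate: real retinal layering above BM (the
region above BM is plain vitreous), fovea-centred anatomy, shadowing and
motion artifacts, vessel-induced boundary ambiguity, and device-specific
noise. Passing tests therefore demonstrate that the pipeline's mechanics
and optimisation work as designed, not that clinical-grade accuracy would
transfer to patient data.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale cohorts: 128 × 256
phantoms, 64 × 64 patches (K = 4), ~300 patches, 10–12 epochs at the
first-phase learning rate — sizes chosen so a full run takes minutes on a
single core while still being large enough for the learning-sanity margin
(validation MAE well under half the label SD, against a label SD of
~24 px). 64 × 64 patches cannot contain both boundaries once thickness
exceeds the window, so a few pixels of irreducible error remain for the
thickest scans; the criterion margins absorb this. Metric code is plain
float64 numpy and is tested against brute-force oracles to 1e-12;
window-placement ties break to the smallest offset; splits round the
validation and test sizes and give any remainder to training (a 150-subject
cohort splits exactly 90/30/30, five subjects split 3/1/1).

## Known limitations

- The regressor offers no uncertainty output; a prediction on an atypical
  scan fails silently. (Out of scope by design.)
- The numpy engine is single-threaded apart from BLAS matmuls; paper-scale
  patches (200 × 200 × 3) train slowly on CPU, though they evaluate fine.
- Thickness is measured along image columns, not perpendicular to BM; for
  strongly tilted scans the two differ.
- The phantom's intensity statistics are stationary across columns; real
  choroids darken with depth and vary laterally.
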