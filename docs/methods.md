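# Methods

This package implements an end-to-end workflow for recognizing NaCl
treatment levels from plant leaf-surface electrophysiological signals,
and for choosing *where on the plant* to record them: a synthetic
recording generator, a wavelet-based preprocessing chain, construction
of the screening and recognition datasets, the LRPNet classifier, and
the stepwise acquisition-position screening plus module-ablation
protocol.  This note documents the models, the defaults and why they
are what they are, and the limits of what the synthetic studies can
show.

## The synthetic recording generator

Real leaf-surface voltage recordings are low-amplitude, low-frequency,
nonstationary, and heavily contaminated by sensor noise.  Treatment
level shifts the waveform's centre and alters its local fluctuations;
recording position (leaf level in the canopy x longitudinal region
along the leaf) modulates how cleanly those treatment effects appear.
The generator reproduces exactly this structure as a sum of five
components, all in millivolts:

| component | default | role |
|---|---|---|
| per-plant offset | N(0, 0.2 mV), one draw per plant | background individual variability |
| treatment baseline shift | 0.01 mV/mM x concentration x position factor | waveform centre position |
| slow drift | RMS 0.3 mV, low-pass < 0.05 Hz | nonstationary main trend |
| local fluctuation | narrowband noise, base RMS 0.3 mV, centre 0.05 Hz; RMS scaled by (1 + 0.005/mM x c x pos), centre frequency scaled by (1 + 0.015/mM x c x pos) | the treatment-sensitive temporal pattern |
| sensor noise | white, SD 0.05 mV | measurement noise |

Drift and fluctuation are Butterworth-filtered white noise rescaled to a
target RMS (zero-phase filtering, 4th order; the fluctuation band is
centre x (1 ± 0.4)).

Why the treatment effect lives in the fluctuation *timescale*: the
preprocessing chain (below) wavelet-thresholds the recording and then
min-max-normalizes each 30 s window.  Thresholding at the universal
level removes essentially all broadband noise, and per-window
normalization removes location and scale.  A treatment effect encoded
purely as a baseline shift or as a noise-amplitude envelope is therefore
invisible to the classifier; what survives is the *shape* of the
waveform — how fast the local fluctuations run relative to the slow
drift.  Scaling the fluctuation centre frequency (and, secondarily, its
envelope) with treatment level gives the normalized windows a robust,
per-window-estimable class signature, which is the property the
recognition task needs the data to have.  The defaults were fixed once,
in design pilots, so that the five-gradient task at the best recording
position has the high separability that a ~90% five-class accuracy
implies; they are deliberately not exposed as per-test knobs.

Position effects are a single separability multiplier per position —
canopy-level factor {top 1.0, middle 0.45, bottom 0.25} times
longitudinal factor {basal 1.0, middle 0.35, apical 0.2} — applied to
both treatment gains.  The steps are deliberately large: classifier
accuracy saturates as a function of the frequency shift, so narrowly
spaced multipliers would compress the between-position accuracy
differences below training noise.  This gradient makes top-basal the
unique best position and keeps the weaker positions clearly below
saturation in the binary screening task, so the two-stage screen has a
recoverable ground truth.

Determinism: every recording derives its random stream from
(seed, plant, position, concentration) via `SeedSequence` spawn keys;
the per-plant offset derives from (seed, plant) only, so all recordings
of one plant in a study share it.  Identical inputs are byte-identical
across processes.

What the generator does *not* emulate: action potentials or other
event-like transients, electrode-contact artifacts, circadian trends,
inter-plant differences in treatment response (plants differ only by a
baseline offset), and any carry-over between sequential treatments.
Passing tests therefore show that the pipeline recovers the intended
structure from data *of this form* — not that it would perform at any
particular level on real recordings.

## Preprocessing

The chain is fixed: denoise the whole recording, cut fixed 30 s windows
(900 points at 30 Hz, trailing remainder dropped), min-max-normalize
each window with x' = (x - x_min)/(x_max - x_min), and reshape to a
30 x 30 matrix in row-major time order (each row is one second).

Wavelet denoising uses Daubechies-4, decomposition to
min(5, maximum level for the signal length), and soft shrinkage of all
detail coefficients at the universal threshold sigma * sqrt(2 ln N),
with sigma = MAD(finest detail coefficients)/0.6745.  This is the
standard configuration for low-SNR nonstationary biosignals; family,
level, threshold mode and a threshold scale factor are all exposed in
`DenoiseConfig` (threshold scale 0 gives perfect reconstruction, which
the tests exploit).  Denoising runs on the whole recording rather than
per window because the noise estimate needs length and 900-point
windows would cap the decomposition depth; normalization runs per
window because its extrema are defined within the sample.

A constant window makes the normalization denominator zero; that is an
error by default (it indicates a dead electrode or a degenerate
simulation), with an opt-in policy mapping such windows to all zeros.

## Datasets and splits

Three families, built from preprocessed window samples:

* longitudinal screening: one binary (0 vs 100 mM) dataset per region,
  pooling 3 plants x 3 leaf levels — 4320 samples each at full scale;
* hierarchy screening: one binary dataset per canopy level inside the
  previously selected region (one representative leaf per plant) —
  1440 samples each;
* five-gradient: one 5-class dataset at the selected position — 3600
  samples, 720 per class.

Splits are 80/20 at the window level, stratified by class and
deterministic under a seed; with the full-scale counts this forces
3456/864, 1152/288 and 2880/720 (576/144 per class) exactly.  Window-
level splitting means train and test share plants and recordings; the
results compare positions and models under one protocol and are not
plant-independent generalization estimates.  A plant-held-out split is
a possible extension but is out of scope here.

## LRPNet

Input is one 1 x 30 x 30 normalized window.  The network is a pointwise
(1x1) embedding to 16 channels; one PoolFormer block; five
depthwise-separable residual blocks with channel schedule
32-64-96-128-128 (stride 1 throughout, spatial size preserved); global
average pooling; and a linear softmax head.  The full 5-class model has
65,816 trainable parameters.

* PoolFormer block: pre-norm MetaFormer layout with batch normalization;
  token mixer `avgpool_3x3(x) - x` (stride 1, same padding, border
  averages renormalized); channel MLP of two 1x1 convolutions with
  expansion 4 and ReLU.  One block only.
* Residual block: depthwise 3x3 -> pointwise 1x1 -> BN -> ECA gate,
  with an identity shortcut when channels match and a 1x1 + BN
  projection otherwise; ReLU after the addition.  ECA is global average
  pooling per channel, a bias-free 1-D convolution across channels
  (adaptive kernel: nearest odd to |log2(C)/2 + 1/2|), and a sigmoid
  gate.
* The PoolFormer block and the ECA gates toggle independently, giving
  the 2 x 2 ablation grid under one code path.

The network, its exact gradients, and Adam are implemented directly in
numpy (with numba-compiled kernels for the bandwidth-bound layers); the
test suite checks every layer against central finite differences.
Weights use fan-out-scaled He initialization; all randomness flows
through a seeded generator, so fits are bit-reproducible.

One implementation detail matters for short training runs: batch-norm
running statistics updated with the usual exponential momentum are far
from the activation statistics after only a few dozen optimizer steps,
which wrecks eval-mode predictions.  After training, the classifier
recalibrates all running statistics with one cumulative-average sweep
over the training set (the same correction used when averaging weights
in stochastic weight averaging).

## Training and evaluation protocol

Defaults follow the study protocol: Adam, learning rate 1e-4, batch
size 30, 200 epochs, cross-entropy loss, no scheduler, weight decay,
early stopping, or augmentation.  Each configuration is trained
`n_runs` times (default 5; ablation preset 20) with seeds seed+0..n-1
on one fixed split, and metrics are reported as mean ± sample SD.

Metrics are accuracy, macro precision, macro recall and Cohen's kappa.
Macro averaging is the natural choice because every dataset is class
balanced.  Kappa is standard Cohen's kappa from the confusion-matrix
marginals; it cannot exceed accuracy when chance agreement is positive,
and the suite asserts that bound.

Screening is stepwise: the three longitudinal datasets are compared
first, then the three hierarchy datasets within the winning region.
The winner maximizes mean test accuracy; ties break by mean kappa, then
by lower mean final training loss, then lexicographically.  The
training-loss tie-break is deliberate: on small test sets accuracy and
kappa are coarsely discrete and exact ties are common, while the final
training loss is continuous and tracks class separability, so the
alphabetical fallback essentially never decides.

## Reduced problem sizes

The full-scale protocol (2 h recordings, 200 epochs, five runs) is the
package default.  The test suite and the acceptance script run the
learning-based studies at reduced scale, chosen as the smallest sizes
at which the studied effects are comfortably recoverable: 5 min
recordings (10 windows per recording), learning rate 3e-3 with batch
size 8-10 (small batches give more optimizer steps per sample and are
also cheapest per sample on one CPU), 5 single-run epochs for the
longitudinal screen, 8 epochs averaged over two runs for the
hierarchy screen (its small test sets make a single run too coarse),
20 epochs for the five-gradient task, and 1-2 runs per configuration.  The dataset-arithmetic checks always
run at the full 2 h scale, where the design counts are forced exactly.

## Known limitations

* The generator's treatment effect is stationary within a recording;
  real responses evolve after gel application.
* Only three plants, as in the emulated design — plant effects cannot
  be estimated, only absorbed.
* The screening decision is a relative comparison under one preprocess
  + classifier; a different preprocessing (e.g. keeping absolute
  amplitude) could rank positions differently.
* Kappa is reported as standard Cohen's kappa; under class balance it
  tracks accuracy closely.
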