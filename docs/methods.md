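# Methods

## Problem

Simultaneous PET/MRI of the pediatric brain has no direct measure of photon
attenuation: unlike PET/CT there is no transmission image, and the skull of
a child — thin, low-density, rapidly calcifying over the first years of
life — defeats adult atlases and vendor fat/water maps that simply omit
bone. This package implements and compares, on synthetic head phantoms with
a known ground-truth CT, the two families of MR-based attenuation
correction (AC) that work from ultrashort-echo-time (UTE) imaging:

* **Segmentation AC** (`petmrac.resolute`): classify UTE voxels into
  air / soft tissue / candidate bone and give bone a continuous pseudo-HU
  through a sigmoid mapping of its R2* value, calibrated against reference
  CTs of *other* subjects (2-fold subject-level cross-validation).
* **CNN AC** (`petmrac.deepute`): a 3D U-net-style encoder-decoder
  regresses the CT in Hounsfield units directly from 16-slice windows of
  (echo 1, echo 2, R2*), trained with subject-level k-fold cross-validation
  and applied with dense overlap-averaged sliding-window inference.

Both are scored against the CT-derived mu-map through the quantities a
neuro-oncology reader uses: background uptake B, biological tumor volume
(BTV, uptake strictly above 1.6 B), T_MEAN/B and T_MAX/B, tumor-contour
Jaccard, per-exam clinical acceptance limits, and cohort log-scale
agreement statistics.

## Phantoms (`petmrac.phantom`)

A phantom is a concentric-ellipsoid head: scalp shell (5 mm), skull shell
of configurable thickness, brain, optional internal air (nasal, mastoid,
post-surgical pocket), and a spherical tumor inside the brain. Seven age
classes set the skull defaults, from 2 mm / 400 HU peak in early infancy to
6 mm / 1300 HU at adolescence — plausible values encoding the rapid growth
of skull thickness and mineral density, not a calibrated growth curve.

Signals:

* **Bone density field.** Each bone voxel carries a smooth mineral-density
  fraction f in [0.3, 1] (Gaussian-filtered white noise, anatomy-seeded so
  repeat exams share a skull). CT value = f x peak HU; R2* = 400 + 800 f
  s^-1. This makes the R2*-HU relation monotone and continuous — the
  structure segmentation AC calibrates — instead of a degenerate
  single-valued "bone".
* **UTE echoes.** S(TE) = S0 exp(-TE R2*) at TE = 0.07 / 2.46 ms, soft
  tissue S0 = 100 with R2* around 20-30 s^-1, bone S0 = 80. Additive
  Gaussian noise with sd = noise_sigma x 100 on both echoes (magnitudes
  clipped at zero; the Rician floor is ignored at the SNR used), default
  noise_sigma = 0.02. CT noise scales with the same knob (sd = 400 x
  noise_sigma HU).
* **Activity.** Brain background ~1 a.u. with mild smooth heterogeneity;
  tumor peaks at exactly ratio x background (default 2.5) with a
  center-to-rim gradient; scalp 0.25, bone 0.05. An optional extratumoral
  hot spot is covered by the exclusion mask. The background ROI is a 12 mm
  box mirrored across the midline from the tumor.

What the phantoms deliberately do not model: MR artifacts (B0, motion,
susceptibility at real air/tissue interfaces), metal implants, anatomical
atlas realism, dose/weight SUV normalization (ratios are scale-invariant).
Passing tests therefore demonstrate correctness of the *machinery* and the
relative behaviour of the AC methods under controlled conditions — not
clinical performance. In particular the phantoms' air interfaces are far
cleaner than a real UTE scan, which flatters segmentation AC: the noise
that motivates CNN AC on patients is largely absent here.

## Scalar transforms (`petmrac.mrac`)

* R2* = ln(S1/S2)/(TE2-TE1); voxels with either echo at/below a signal
  floor (1e-6 of the max), or negative estimates, are set to 0; clamp at
  3000 s^-1. Clamp-to-zero (rather than masking) was chosen for negative
  estimates so downstream maps stay finite.
* HU -> mu at 511 keV is the standard bilinear curve: water 0.096 cm^-1,
  slope 9.6e-5 below 0 HU and 5.1e-5 cm^-1/HU above, both configurable.
  Vendor conversion curves are proprietary; the ratios of interest depend
  only weakly on the exact bone slope.
* Tissue classes for scoring: air < -500 HU, bone > 300 HU, soft between.
* FOV stitching composes a primary map inside a mask with a fallback map
  outside, as clinics do where CT coverage ends.

## Segmentation AC details

Air requires *both* echoes below the floor (5% of the median in-head
first-echo signal) — dense bone legitimately loses its second echo, and
treating "either echo dark" as air reproduces exactly the air/bone
confusion the method exists to avoid. Candidate bone is restricted to an
outer-head band (15 mm, standing in for the anatomical regional masks used
on patients, which need template registration that geometric phantoms do
not) and thresholded at R2* > 300 s^-1. A fixed threshold is used rather
than one derived from the calibrated sigmoid: the sigmoid is fitted on
bone voxels only (CT > 300 HU), so its lower asymptote carries no
information about where soft tissue ends. The sigmoid HU(r) = L +
(U-L)/(1+exp(-k(r-r0))) is fitted by nonlinear least squares
(initialization L=0, U=95th-percentile HU, r0=median r, k=1/IQR(r); at
least 100 bone samples required).

The bone-less baseline assigns soft-tissue HU (30) to everything in the
head that is not air, emulating fat/water vendor AC.

## CNN AC details

Architecture per resolution level: two (conv 3x3x3 -> batch-norm -> ReLU ->
dropout) blocks, downsampling by a stride-2 convolution block (no max
pooling), transposed-convolution upsampling, skip connections by channel
concatenation, 1x1x1 linear output head. Dropout rises linearly 0.1 -> 0.3
through the encoder and mirrors back down through the decoder. He-normal
initialization, Adam, MSE loss, batch size 2. The full-scale configuration
(depth 4, base 16 channels, 192-voxel planes, lr 1e-4, 100 epochs) is
reachable by config; tests and the study driver run a scaled-down
configuration (depth 2, base 8 channels, 32-voxel planes, lr 3e-3 with x0.3
step decay at 60%/85% of epochs, every 2nd window, Polyak-averaged weights
at evaluation) sized for a single CPU.

Implementation: no deep-learning framework is used — convolutions, batch
norm, dropout, transposed convolutions and Adam are implemented in NumPy
with hand-written backpropagation (`petmrac.nn`), evaluated as one small
GEMM per kernel offset. Training is exactly reproducible from the seed.

Numerical choices:

* Targets are regressed as HU/1000 and rescaled at prediction. Averaging
  commutes with the affine rescaling, so overlap-averaged inference is
  still an average "in HU"; plain-HU targets would need O(10^5) optimizer
  steps just to move the output head across the air-to-bone range.
* The output bias starts at the mean training target (standard regression
  head initialization), so early epochs refine structure rather than chase
  the global offset.
* Windows slide with stride 1 and no slice padding; a volume with S slices
  yields S-15 windows and each voxel's prediction is the mean over all
  covering windows (coverage min(s+1, S-15+1, S-s, 16)).
* Channel normalization is per-case robust (median/IQR) per channel.

## PET simulation (`petmrac.petsim`)

A 2D parallel-beam model per axial slice: emission sinogram = Radon
transform of activity (voxel-size scaled) times exp(-line integral of the
*true* mu-map); correction multiplies by exp(+line integral of the chosen
mu-map) in sinogram space (the clinical ACF); reconstruction is
ramp-filtered back-projection, negatives clamped. Optional Poisson noise at
a configurable count level. This replaces fully-3D iterative
reconstruction with scatter/randoms modelling; it preserves the mechanism
under study — a biased mu-map biases reconstructed uptake ratios — at
desk-top cost. Matched-AC reconstruction recovers a 64^2 disc phantom to
<2% mean error in the brain with 180 angles.

## Clinical metrics and agreement (`petmrac.clinical`, `petmrac.agreement`)

BTV uses strict ">" at 1.6 B ("above" the threshold); voxels in the
exclusion mask never count; no connected-component selection is applied
(the whole suprathreshold volume counts — the reference auto-contour tool's
internals are not public, and the exclusion mask already removes known
extratumoral structures). An empty delineation yields a flagged record
excluded from ratio summaries. Acceptance limits: T_MEAN/B +-0.05, T_MAX/B
+-0.1, or 5% relative; BTV +-2 mL or 10% — a metric passes on either arm,
reflecting that large or very avid tumors tolerate larger absolute change.

Agreement works on d = ln(test) - ln(ref) (the metrics are ratio-scaled and
approximately log-normal): mean, t-based 95% CI and p-value on *subject
means* (each subject weighted once — the repeated-measures correction for
follow-up exams), limits of agreement mean +- 1.96 SD with SD from a
one-way variance-components decomposition (between-subject sigma_b^2 via
method of moments, clamped at 0, plus within-subject MSW). With one exam
per subject everything reduces exactly to the ordinary sample statistics.
All outputs are exponentiated and reported as (e^x - 1) x 100%. Constant
differences (SD below 1e-12 relative) are treated as degenerate: p = 1,
zero-width limits.

## Study driver and problem sizes

`run_study` chains phantoms -> mu-maps (CT, bone-less, segmentation AC with
2-fold calibration, CNN AC with subject-level k-fold) -> PET simulation
under the true mu-map -> reconstruction per method -> metrics, cohort
filter (reference BTV > 1 mL), acceptance flags, agreement tables — all
written as deterministically formatted CSV. A single study seed fans out to
named per-stage substreams, so any stage can be reproduced in isolation.

Three scales exist: micro (32^3 at 3.0 mm — what the test suite and the
reproduction script run), desk (96^3 at 2.0 mm) and full (192^3 at 1.6 mm,
the acquisition matrix). The micro scale was chosen so that the whole
pipeline, CNN training included, runs on one CPU in minutes; its geometry
keeps every structure (skull shell >= 1 voxel, tumor > 1 mL) resolvable.

## Known limitations

* The phantom world is kind to segmentation AC (clean air interfaces,
  perfectly co-registered echoes, exactly informative R2*), so the margin
  by which CNN AC outperforms it on real patients is compressed here.
  Training throughput is the binding constraint: at the replicate budget
  the held-out battery can afford on one CPU (~400 optimizer steps), the
  CNN's bone overlap and mu-map error still trail the segmentation method
  and the bone-less baseline; trained roughly ten times longer on the same
  data, the same network overtakes both (bone Jaccard above, mu-map MAE
  below). The battery therefore reports where the ordering stands at its
  stated budget rather than the CNN's ceiling.
* The 2D simulator ignores scatter, randoms, PSF and axial cross-talk.
* The sigmoid parameterization of the R2*-HU mapping is one admissible
  choice; the original method's exact parameterization and fit weights are
  not public.
* BTV counts all suprathreshold voxels rather than one connected
  component; with the exclusion mask applied the difference is nil on
  phantoms but could matter on noisy real data.
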