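# Methods

This note documents the models implemented in `chronolight`, the defaults
and why they were chosen, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Standard observer and α-opic colorimetry

All colorimetry runs on one bundled 1-nm table (380–780 nm,
`src/chronolight/data/observer_1nm.csv`, generated by
`tools/build_observer_tables.py`):

* CIE 1931 2° colour-matching functions, the scotopic efficiency function
  V′(λ) and the relative spectral power distribution of illuminant D65,
  transcribed from the standard published 5-nm tables and interpolated with
  shape-preserving PCHIP. Verification anchors: the D65 chromaticity
  computed from these tables is (0.3127, 0.3290) to four decimals, and the
  rhodopic daylight constant lands within 0.01 % of its published value.
* Cone (L, M, S) and melanopic action spectra are **model-generated
  approximations** of the standardised α-opic sensitivities: a Govardovskii
  A1 pigment template (α + β band) with axial self-screening, a smooth
  parametric lens-transmittance model and, for the cones, a Gaussian
  macular-pigment model, converted from quantal to energy units and
  peak-normalised. One scalar per curve (self-screening density for L and
  M at literature peak wavelengths; peak wavelength for S and melanopsin)
  is calibrated so that the α-opic irradiance of D65 per photopic lux
  equals the published daylight efficacy constant of that channel
  (1.62890 / 1.45582 / 0.81731 / 1.44972 / 1.32621 mW m⁻² lx⁻¹). The
  rhodopic channel is V′ itself.

Consequence: every D65-referred integral quantity — equivalent daylight
illuminance/luminance, α-opic irradiance of daylight at a given
illuminance — is anchored to the standard values, while the local shape of
the cone/melanopic curves may deviate a few percent from the official
tabulations. Narrow-band stimuli evaluated near those deviations inherit
that error; broadband (device-primary) work is insensitive to it.

Integration is trapezoidal on the 1-nm grid; the photopic constant is
683.002 lm W⁻¹; spectra are densities per nm and file readers interpolate
but never rescale. Chromaticity of an all-zero spectrum is reported as
undefined (`None`) rather than (0, 0). Weber contrast is
100·(mod − bg)/bg per channel and raises on a zero background channel,
naming the channel.

## Silent-substitution solver

A device is a set of primary spectra at maximum drive, linear in drive
weight, with `levels` discrete drive steps (256 for 8-bit control). Since
every α-opic value is linear in the weights:

* **Background**: minimise the squared *relative* error of the five
  α-opic values against D65 scaled to the target illuminance, subject to
  0 ≤ w ≤ 1 — a bounded linear least-squares problem solved globally with
  `scipy.optimize.lsq_linear`. Requests beyond the device gamut raise,
  reporting the maximum achievable illuminance.
* **Modulation**: the Weber contrasts against the fixed background are
  affine in w, so minimising Σ(achieved − target)² over the constrained
  channels (S, L, M individually set to the shared L+M value, melanopsin
  fixed at 0 %; rods always free) is again bounded linear least squares.
  A tiny ridge (weight 10⁻⁶·‖A‖) pulls the solution toward the background
  weights, so that when the exact solutions form an affine set the solver
  returns the minimal drive excursion — in particular an all-zero target
  returns the background itself. `converged` reports whether the residual
  objective is numerically zero; with fewer primaries than constraints the
  best least-squares solution is returned flagged `converged=False`.

No multi-start machinery is used: the problem is convex, so a single
bounded least-squares solve is globally optimal and deterministic. This
replaces the more common multi-start local optimisation without loss.

Quantization rounds half-up to the nearest device level and re-evaluates
all contrasts at the realised weights; solutions carry both nominal
(pre-quantization) and realised contrast vectors, mirroring the
planned-versus-validated distinction made when calibrating real hardware.

On the synthetic validation device (five Gaussian primaries at
430/480/500/550/630 nm, FWHM 20 nm, peak spectral irradiance
10 mW m⁻² nm⁻¹) the D65 background at 93.5 lux is inside the gamut with
residual < 10⁻⁸ and the ±25 % substitution solutions silence melanopsin to
< 10⁻⁶ % nominal and ≲ 0.2 % after 8-bit quantization.

## Exposure protocol

The exposure lasts 60 min starting 30 min after habitual bedtime (HBT).
Flicker conditions alternate 30 s of 1-Hz unipolar sinusoidal excursions
with 30 s of constant background; each 1-s cycle starts and ends at the
background and peaks at the modulation spectrum at 0.5 s
(w(t) = w_bg + (w_mod − w_bg)(1 − cos 2πt)/2). The phase convention (start
at background) is a choice; "unipolar sinusoidal" fixes everything else.
Mean drive over a full on/off pair is w_bg + (w_mod − w_bg)/4.

The evening schedule holds saliva/KSS/PVT/comfort ticks every 30 min from
−300 to +90 min relative to HBT (14 ticks), resting-EEG blocks (KDT) at
+27, +60 and +87 min (the printed assessment times are used verbatim even
though the last is 3 min before exposure end), lights off at +120 min with
a 6-h sleep opportunity, and five morning saliva/KSS samples every 30 min
from wake-up. Both evenings use the same schedule. Default timeline
sampling rate 100 Hz, configurable.

## DLMO estimation

The melatonin onset model is continuous and piecewise linear–parabolic:
baseline a + b·t before the switch t₀, plus c·(t − t₀)², c ≥ 0, after it.
For each candidate t₀ on a 1-min grid the remaining parameters solve a
linear least-squares system (with c < 0 clamped to the boundary model);
the t₀ with minimal RSS wins, ties broken toward the earliest candidate —
"the first moment the data are consistent with an onset", which also
recovers on-grid noiseless switches exactly. The baseline slope b is
estimated by default; a flat-baseline option exists.

**Area of interest.** The threshold (default 5 pg ml⁻¹) delimits the onset
region: the fit uses all samples up to and including the first *two*
exceeding the threshold. No supra-threshold sample can therefore fall in
the baseline segment, and the full-secretion part of the curve — including
any exposure-window suppression — never influences the fit. Two
supra-threshold anchors are kept because a single one leaves the
switch/curvature pair under-identified, biasing the grid search early by
~6 min at realistic noise; with two anchors the bias is below 1 min while
noiseless recovery and suppression insensitivity are unchanged. With
half-hourly sampling, a profile whose onset is followed by only one
sub-threshold sample is intrinsically identified only up to the preceding
sampling interval.

A fit is labelled `no_rise` when the fitted rise at the last sample is
within twice the baseline residual SD (plus a numerical floor); phase
shifts (t₀ evening 2 − t₀ evening 1, positive = delay) are defined only
when both fits are `ok`. Concentrations below the assay limit of
quantification (0.9 pg ml⁻¹) are used as reported, not truncated.
At least five usable samples are required, at least two of them before
any candidate switch.

## Outcome metrics

* **PVT**: trials < 100 ms are anticipations and discarded; summaries are
  the median and the means of the fastest/slowest deciles of valid trials
  (rank-based membership, ⌈n/10⌉ trials per decile; deciles undefined
  below 10 valid trials; a session with no valid trial cannot be
  summarised).
* **Visual comfort**: arithmetic mean of the four 1–5 items (pleasantness,
  brightness, glare, colour temperature), raw by default with a
  reverse-coding switch (whether any item should be reverse-scored is not
  specified by the source protocol).
* **Band power**: non-overlapping 2-s bins, Hann taper, 0.5-Hz resolution
  (`scipy.signal.welch` with `noverlap=0`, variance scaling); band power
  sums the bins inside the band, edges inclusive. Powers over disjoint
  bands add; totals match the signal variance up to taper leakage.
  Alpha (8–12 Hz) / theta (4–7 Hz) ratio is computed from electrode-mean
  powers over P3, Pz, P4, O1, Oz, O2; the theta/alpha reciprocal is stored
  alongside since the source protocol names both directions.
* **Sleep**: 30-s AASM epochs, N1 counts as sleep. Sleep-onset latency is
  the time from lights off to the first run of ≥ 20 consecutive non-wake
  epochs (10 min). Cycles: NREM episode ≥ 15 min ending at a REM episode
  ≥ 5 min, first REM episode exempt from the minimum; when REM latency
  from sleep onset is < 30 min the NREM parts of the first two cycles are
  combined into one (the merged cycle's REM part is the second REM
  episode). Sleep efficiency is non-wake epochs over epochs in bed, with
  a screening flag below 70 %.
* **SWA profile**: the NREM and REM parts of the first cycle are each cut
  into ten equal-duration deciles; each decile's value is the mean
  0.5–4.5 Hz power across 2-s bins and frontal electrodes F3, Fz, F4
  (20 values per record).

## Bayes factors

* **JZS paired-t BF**: BF₁₀ integrates the Cauchy-prior (scale √2/2 by
  default) mixture over the effect size; the one-dimensional g-integral is
  evaluated by adaptive quadrature on a compactified axis (relative error
  ~10⁻¹⁰, checked against a dense-grid oracle to 10⁻⁶ and against an
  independent implementation). A fixed 80-node Gauss–Legendre path serves
  the vectorised simulator at ~10⁻⁸ agreement.
* **Linear-model BF** (ANOVA-like, for condition effects with random
  participant and gender factors): categorical terms enter through
  centred orthonormal sum-to-zero contrasts, each factor carrying its own
  g with a scaled-inverse-χ²(1, r²) prior — r = 0.5 for tested fixed
  effects, r = 1 for random factors, both configurable. Conditional on g
  the marginal likelihood is closed-form (intercept flat, σ² Jeffreys,
  coefficients normal); the g's are integrated by fixed-seed Monte Carlo
  from the prior (default 10⁵ draws, chunk-vectorised Cholesky), with a
  BFGS+Laplace alternative labelled in the result's `method` tag. Nested
  comparisons share the closed form, so missing cells are handled by the
  long-format likelihood without dropping participants. Monte-Carlo error
  is reported as the relative SE of the weight mean. On balanced
  two-condition data the model agrees with the JZS paired BF within ~20 %
  (a documented approximation check, not an identity: the random-factor
  prior differs from implicit pairing).
* **Interpretation bands**: anecdotal (1–3), moderate (3–10), strong
  (10–30), very strong (30–100), extreme (> 100), symmetric in BF₁₀ and
  1/BF₁₀; exactly 1 is "equivocal".
* **Sequential design**: per replicate, participant-level paired
  differences ~ Normal(d, 1); from n = 4, after each added participant the
  paired JZS BF is evaluated and sampling stops at BF₁₀ ≥ 10 (evidence for
  H1) or ≤ 1/10 (evidence for H0); replicates reaching n = 16 are
  classified by the final BF, values strictly between the boundaries
  counting as inconclusive. With the default prior scale the H0 boundary
  is unreachable at n ≤ 16 for a paired test, so the H0 share is 0; at
  d = 0.8 the simulator yields ≈ 58 % evidence-for-H1 with 10⁴ replicates
  (the design-analysis settings behind the published planning figure of
  62 % — test family, prior scale, counting rule — are not printed, so
  moderate differences are expected; the ±8-point acceptance band covers
  this).

## Synthetic study generator

`StudyConfig` defaults are the study conditions: 16 participants (8 + 8
balanced sexes) × 3 conditions (background, blue-dim, yellow-bright) × 2
evenings; per-condition mean evening-2 phase delays 52.0 / 41.94 / 33.8
min; PVT median targets 384.4 / 399.8 / 395.5 ms; KSS latent means
6.19 / 5.47 / 5.56. Values the study does not pin were chosen once as
field-plausible: participant-level evening-1 DLMO ~ N(−120, 30) min
relative to HBT with 5-min visit jitter, between-participant phase-shift
SD 25 min, melatonin baseline U(1, 3) pg ml⁻¹ with rise coefficient
U(0.002, 0.006) pg ml⁻¹ min⁻², multiplicative lognormal assay noise
(σ = 0.15), a 40 % condition-independent suppression dip across the
+30…+90 min exposure window with 10-min cosine ramps (switchable to
condition-specific factors for power studies), ex-Gaussian reaction times
(σ = 30 ms, τ = 60 ms, location solved numerically from the target median,
participant offset SD 25 ms), thresholded-normal KSS and comfort items,
KDT EEG as 10-Hz alpha + 5.5-Hz theta oscillations in broadband noise at
500 Hz, semi-Markov staged nights (REM latency ~ N(70, 15) min,
configurable down to the < 30-min merge regime) and frontal sleep EEG with
exponentially decaying delta amplitude (τ = 45 min) at 128 Hz. Evening 1
and 2 share participant-level curve parameters, giving the paired
structure the analysis assumes.

What the generator does **not** emulate: assay-specific error structure
beyond lognormal noise, time-on-task and lapse dynamics within a PVT
session, EEG artifacts/nonstationarity beyond the built oscillators,
inter-stage transition physiology beyond dwell sampling, and any
condition-order or expectation effects. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
structure, not robustness to every property of real recordings.

Ground truth (true onsets, delays, band powers, stage boundaries) is
stored alongside the tables; `write_dataset` emits the CSV/NPZ files the
analysis modules read, with a SHA-256 manifest.

## Pipeline

`RunConfig` carries the seed, stage toggles, thresholds (AOI 5 pg ml⁻¹,
PVT validity 100 ms, 20-epoch sleep-onset run) and Bayes settings;
validation returns the complete error list. Stages run in dependency
order (simulate/load → DLMO → outcomes → Bayes); a failure raises a typed
error naming the stage with the partial report attached. Identical config
and seed give byte-identical reports, and each stage matches its
standalone computation exactly.

## Problem sizes used by the test suite

Unit tests run reduced configurations (4–6 participants, shortened EEG,
2 000–4 000 Monte-Carlo draws); the acceptance checks use the full stated
sizes — 10⁴ sequential-design replicates, 100 (t, n) quadrature-oracle
pairs, 1 000 random hypnograms for the latency oracle, a 3 × 3 (t₀, c)
noise-recovery grid at 60 replicates per cell, and 200 complete
melatonin-only synthetic studies for the phase-delay recovery — chosen so
the whole suite completes in a few minutes on one CPU.

## Known limitations

* The bundled cone/melanopic action spectra are calibrated approximations
  (see above), not the official tabulations; applications needing
  sub-percent accuracy for narrow-band lights should substitute measured
  tables (any CSV with the same columns can be dropped in).
* No individualised observers (age-dependent pre-receptoral filtering),
  no 10° observer, no mesopic photometry.
* The solver models hardware as linear and noiseless; gamma calibration
  and spectral drift of real devices are out of scope.
* The linear-model BF integrates random factors under default priors by
  Monte Carlo; very large designs may need the Laplace path, which is an
  approximation.
* Hypnograms are inputs: no sleep staging is performed.
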