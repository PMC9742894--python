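# Methods

This note records the models, conventions and numerical choices behind
`oxipheno`, and what the synthetic-data tests do and do not establish about
real recordings.

## Signal model and cleaning

An oximetry trace is a regularly sampled %SpO₂ series with an aligned
boolean validity mask; every statistic downstream uses valid samples only.
Cleaning marks samples outside the physiologic window [50, 100]% (including
device-dropout zeros) invalid, linearly interpolates invalid runs of at
most `max_gap_s` (default 30 s, bridging transient probe losses), and
leaves longer runs invalid. Interpolation never alters a sample that was
already valid and in range. The exact artifact rules of any given device or
cohort differ; both the window and the gap limit are configuration.

Resampling (used for the non-linear features at 0.2 Hz) is block averaging:
each output sample is the mean of the valid input samples in its window,
and windows with no valid samples are invalid. Averaging rather than
decimation suppresses measurement noise at the lower rate.

Sleep-stage restriction invalidates samples outside the requested stage
set; per-hour denominators then use the selected-stage time rather than
total sleep time (TST). TST is the non-WAKE epoch count times the epoch
length (30 s epochs by default).

## Desaturation characteristics

Event detection works against a running local baseline — the maximum of
the valid samples over the preceding 100 s. Candidate events are
*threshold-independent excursions*: an excursion opens when SpO₂ falls
more than the resaturation margin (1%) below the local baseline (the event
start is placed at the last pre-fall sample, so a square fall still has its
start strictly before its nadir), and closes on recovery to within the
margin. Depth is baseline minus nadir. ODI at threshold t counts excursions
of depth ≥ t (per hour of sleep), which makes ODI monotone non-increasing
in t by construction rather than by accident of the scanning order.
Excursions shorter than 10 s (noise spikes) or longer than 600 s (baseline
drift) are discarded; all four parameters are configuration.

Hypoxic burden is the respiratory-event-anchored desaturation area per
hour of sleep. The SpO₂ signal is ensemble-averaged across events, aligned
on each event's end, over ±240 s. Because desaturation follows the event
(circulatory delay), the nadir of the mean response is searched after the
alignment point; the patient-specific window runs from the last pre-nadir
maximum to the first post-nadir maximum of the mean response — the extents
of the average fall and recovery. Taking the maxima *closest* to the nadir
matters: on flat ensembles the ties must resolve toward the nadir, or the
window silently swallows the neighbouring event's desaturation. Per event,
the baseline is the maximum valid SpO₂ in the 100 s before the event end,
and the area is the trapezoidal integral of max(0, baseline − SpO₂) over
the window on the native 1 Hz grid, in %·min. The burden is the summed
area divided by TST hours, so adding event-free recording time changes the
value only through the denominator. The closed form 15 events × 4% × 1 min
in 1 h TST = 60 %·min/h is reproduced to within trapezoid edge effects
(< 2%).

Whether ODI should count only event-linked desaturations is genuinely
ambiguous in practice; this implementation counts all desaturations (the
detector takes no event list), and event-linkage enters only through the
hypoxic burden, which is anchored on the respiratory events by definition.

## Time-series distribution features

Moments of the valid-sample distribution: mean; sample SD (ddof 1);
skewness and kurtosis as population-formula standardized central moments
(no small-sample correction — overnight n is in the tens of thousands).
Kurtosis is non-excess (Gaussian → 3). With zero SD the shape moments are
undefined and reported missing, never zero. Median uses midpoint
interpolation on ties; the nadir is the minimum valid sample.

TX is 100 × (valid sample time with SpO₂ ≤ X) / (valid sample time), for
X ∈ {80, 82, …, 94}. The threshold is inclusive ("≤ X"), configurable to
strict. Using valid-sample time in the denominator keeps artifacts from
inflating either side of the ratio.

## Spectral features

The PSD is a Welch estimate: 2048 s Hann-tapered segments, 50% overlap,
per-segment mean detrending, density scaling. Invalid samples are bridged
by linear interpolation before the transform (their fraction is recorded
with the estimate); at least one hour of valid signal is required. The
integral of the estimate reproduces the signal variance within a few
percent on broadband signals (Parseval check in the tests).

Two bands are summarised: the full band 0–0.1 Hz, and the
periodic-desaturation ("OSA") band. The latter is the frequency range of
physiologically plausible periodic desaturations, 15–180 events per hour,
i.e. 0.00417–0.05 Hz; both band edges are configuration. Per band, the
in-band bin powers are treated as a sample: their mean, SD, skewness and
kurtosis are reported in (%SpO₂)² units, plus the spectral entropy
−Σ pᵢ ln pᵢ of the normalized in-band power distribution (natural log;
zero bins contribute zero; invariant to rescaling the whole spectrum; 0
for a single-bin spectrum and ln N for a flat one).

## Non-linear features

Both are computed on the 0.2 Hz block-averaged signal, on the valid-sample
sequence (artifact gaps collapsed).

Sample entropy SampEn(m, r) = −ln(A/B), where B counts pairs of length-m
templates within Chebyshev distance tol and A the same at length m+1,
self-matches excluded. Defaults m = 1, r = 0.25 with tol = r × SD of the
resampled signal (the dominant convention in oximetry-entropy work); an
absolute-r mode is available. A constant signal gives 0 (every template
matches); if no templates match, the value is undefined and reported
missing. One consequence of SD-scaling worth knowing: on synthetic nights,
adding desaturations *raises* the signal SD and hence the tolerance, which
can lower SampEn relative to an event-free night — the "more events, less
regular, higher entropy" intuition holds cleanly under a fixed absolute
tolerance, and that is how the corresponding property is tested.

The central tendency measure forms Poincaré points (dᵢ, dᵢ₊₁) of the first
differences and reports the fraction with Euclidean norm strictly below
ρ = 1 %SpO₂. It is monotone non-decreasing in ρ and, like SampEn,
invariant to adding a constant to the signal.

## Feature assembly

`extract_all` produces exactly 31 named features in four families
(5 desaturation / 14 time-series / 10 spectral / 2 non-linear) for a
requested stratum (total sleep, NREM, REM). Family-level failures — an
empty stratum, a trace too short for the PSD — propagate as missing flags
with recorded reasons, never as silent zeros. Standardization to z-scores
uses non-missing values only and retains the (mean, SD) scaling record so
hazard ratios read "per one SD increase"; a zero-variance feature is an
error by default, or droppable in pipeline contexts where e.g. T80 is
legitimately all-zero in a mild cohort.

## Association protocol

Inclusion requires AHI ≥ 5 (OSA present), a predominantly obstructive
event profile (central fraction < 0.5), an observed outcome, and no event
before the 2-year landmark; participants whose follow-up ends before the
landmark contribute nothing. The risk clock restarts at the landmark.
Exclusions are tallied by reason, with one reason per participant in a
fixed precedence order, so the sample-selection flow is auditable.

Each feature gets its own Cox proportional-hazards model — the
standardized feature plus age, BMI, race (Caucasian/other), smoking
(never/ever) and, in non-sex-stratified models, sex. One model per feature
rather than a joint fit: the patterns are strongly mutually correlated and
nearly collinear with AHI (Spearman ρ ≳ 0.9 for many), so a joint model
would be uninterpretable. Ties in follow-up time use Efron's
approximation (the `lifelines` implementation). Non-convergence and
separation are flagged on the result row, not raised. Covariates constant
within a stratum (e.g. sex within the men-only model) are dropped
automatically.

Within each family and stratum, p-values are Benjamini–Hochberg adjusted
(step-up, adjusted p capped at 1) and flagged significant at FDR q = 0.05.
The significance threshold is therefore data-dependent — computed from the
family's p-values, not a fixed constant. The AHI comparison model runs
through the identical path but stays outside the FDR families.

Group descriptives use pooled-variance independent t-tests (Welch
available) and Spearman rank correlation with midrank ties.

## Synthetic data

The generator emulates what the analysis assumes about real cohorts:

- **Nights.** 1 Hz SpO₂ at a 96% baseline. Respiratory events are placed
  with a *fixed* realized count, round(rate × duration), at random
  non-overlapping positions (Dirichlet-distributed gaps): a night's
  realized event rate equals its configured rate, which is what the
  detector-recovery guarantees quantify; depths, durations and positions
  remain random. Each event triggers a desaturation a fixed 10 s
  circulatory lag after its end: linear fall (25 s) to a depth drawn from
  N(depth_mean, depth_sd), linear recovery (15 s). Event/desaturation
  placement is aligned to integer seconds so the 1 Hz grid samples the
  nadir exactly. Gaussian measurement noise (0.2%) and zero-reading
  dropout artifacts (45 s, 0.2/h) are added; a 30 s-epoch hypnogram
  carries a configurable REM fraction in consolidated periods. Rates that
  would overflow the night shrink the cycle durations proportionally with
  physiologic floors — severe apnea runs on shorter cycles.
- **Cohorts.** Covariates match a community sleep cohort: age
  63.5 ± 10.5 y, BMI 28.8 ± 5.3, 88.3% Caucasian, 52% ever-smokers, 51.8%
  female. Severity (AHI) is gamma-distributed with mean ≈ 21 and SD ≈ 15,
  truncated to 5–60 events/h, so roughly half the cohort is mild.
- **Survival.** Exponential (constant-baseline) event times with
  log-hazard = log h₀ + Σ β_f z_f + covariate terms, administrative
  censoring at 12 y, and a 2-year landmark (pre-landmark events flag the
  participant "prevalent", mirroring exclusion of unreported baseline
  disease). The exponential choice is the simplest model consistent with
  proportional hazards, and Cox estimation is invariant to the baseline
  anyway; memorylessness also makes landmark conditioning exact. The
  default h₀ = 0.011/person-year puts the cohort's cumulative incidence
  near 17% over the follow-up horizon. For large replicate studies (Cox
  calibration at n = 2000 × 100 replicates), standardized feature scores
  come from a severity factor model (loading 0.8) instead of waveform
  synthesis — the survival generator is identical in both modes.

What the synthetic tests establish: the detector recovers constructed
events exactly; analytic closed forms hold; the Cox stage is unbiased
(< 5% on the HR) and its CIs are calibrated (93–97% null coverage); FDR
flags match the literal step-up rule; the pipeline is bit-deterministic
under a fixed seed. What they do not establish: behaviour under real-world
morphologies the generator lacks — periodic breathing, baseline drift,
heart-rate coupling, stage-dependent event clustering, device quantization
— and any clinical claim about which patterns predict CVD in people.

## Problem sizes and determinism

Default study sizes keep the full battery comfortably interactive: the
worked example uses n = 80 participants with 2-h nights; the end-to-end
determinism check uses n = 200 with 4-h nights; Cox calibration uses 100
replicate cohorts of n = 2000 in the reduced form. All randomness flows
from explicit integer seeds through `numpy.random.Generator`; a pipeline
run persists its resolved configuration and scaling record next to its
outputs, and re-running from the same seed reproduces every table
bit-identically.

## Known limitations

- The EDF reader needs the optional `mne` dependency and assumes a single
  oximetry channel among common label spellings.
- The hypoxic-burden window derivation assumes the ensemble-mean response
  has a meaningful nadir; with very few events the window degenerates
  toward the full ±240 s span.
- Breslow tie handling is not offered (Efron only, via lifelines).
- NREM/REM stratified spectral features need ≥ 1 h of valid in-stage
  signal and are reported missing otherwise.
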