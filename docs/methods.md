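# Methods

This note documents the models, estimators and numerical choices behind
`rhbreath`: what the synthetic recordings emulate, how breaths are
segmented and volumes derived, how the device-agreement statistics are
defined, and where the design was genuinely open.

## The measurement model

A humidity sensor in a face mask sees breathing as a quasi-periodic %RH
waveform. Inside the mask the air never returns to room humidity: normal
breathing oscillates between a humid trough floor (inhalation) and a level
at or near water-vapour saturation (exhalation). The moisture carried out
per breath scales with the exhaled air volume, so the area under the
baseline-subtracted %RH curve over one breath is treated as proportional
to that breath's volume. The proportionality constant is not knowable from
the humidity signal alone; it is estimated per recording by regressing the
humidity areas on the volumes reported by the reference flow device.

## Synthetic recordings (`simulate.py`)

`simulate_subject` emulates a 15-minute seated protocol: normal breathing
at ~17.6 breaths/min with one deep inhale–exhale event every 30 s, recorded
simultaneously by the humidity channel (default 5 kHz) and a reference flow
channel (default 1 kHz).

**Waveform.** Each breath cycle is a raised-cosine pulse — half-cosine
rise from the start trough to the peak, an optional flat plateau at the
peak (exhalation saturation), half-cosine fall to the next trough. The
shape is smooth (continuous first derivative, piecewise-continuous second
derivative), which the curvature-based deep-breath boundary refinement
requires.

**Levels.** `envelope_mean_rh_pct` (89) and `envelope_sd_rh_pct` (7.8) are
the target mean and SD of the whole oscillating trace. For a raised cosine
of amplitude A the trace SD is A/(2√2), so the generator derives a trough
floor `mean − √2·sd ≈ 78 %RH` and a nominal peak `mean + √2·sd ≈ 100 %RH`
(capped at `exhale_saturation_rh_pct`). Normal exhalations therefore sit
at or just below saturation — which is what a sensor close to the mouth
measures — and the per-breath peak jitter is a separate, small parameter
(`peak_jitter_rh_pct`, 0.5 %RH). An explicit `baseline_rh_pct` overrides
the derived floor.

**Deep breaths.** A deep event spans two adjacent cycles sharing a deep
trough. The deep inhalation flushes drier air through the mask, so the
falling limb of the first cycle descends `deep_amplitude_factor` (default
2.0) normal amplitudes below the peak — down to ~56 %RH at the defaults —
and the second cycle is the deep exhalation rising back to saturation.
The deep excursion is therefore carried by the *trough*, not the peak:
with the peak pinned near 100 %RH by saturation there is no headroom
above, and this geometry is also what makes the event's maximum reflect
the inspiratory reserve and its minimum the expiratory reserve. It keeps
amplitude-based detection cleanly separable (deep cycles have ~2× the
peak-to-trough excursion of any normal cycle).

**Timing.** Per-cycle periods are 60/rr with rr drawn from a normal
distribution truncated at ±3 SD (`rr_mean_bpm`, `rr_sd_bpm`; SD default
1.0 breaths/min within subject). Deep events trigger each time the
schedule clock passes a multiple of `deep_breath_period_s`, giving exactly
⌊duration/period⌋ = 30 events in 900 s.

**Noise and drift.** Additive Gaussian sensor noise (0.02 %RH, the
sensor-class noise floor) and a slow linear drift (0.05 %RH/min, compatible
with a ±0.5 %RH/year stability rating plus thermal settling) are applied to
the deterministic waveform, then the trace is clipped to the physical
[0, 100] %RH range.

**Ground truth.** The true area of each cycle is the rectangle-rule
integral of the *noiseless* waveform above the trough floor (clamped at
zero), computed at the native rate; the true volume is `gain × area` with
`volume_gain_l_per_rhs` (default 0.012 L per %RH·s, chosen so a normal
tidal breath lands near 0.5 L). The flow channel is a per-cycle sinusoid
scaled so its inhaled (positive) integral equals that cycle's true volume,
plus independent Gaussian noise; integrating it reproduces the truth by
construction, which is exactly the role of a gold-standard reference.
True IRV/ERV are the volumes of the two deep-event cycles; VC = IRV + ERV
equals the deep-breathing area (DBA) exactly because the two limbs
partition the closed event interval.

**What the generator does not emulate.** Sensor quantisation, temperature
and pressure cross-sensitivity, mask leaks, motion artifacts, posture
changes, and the physiological coupling between rate and depth. Breath
anomalies exist only as the two injectable kinds (`saccade`, a mid-cycle
oscillation; `missing_recovery`, a suppressed return to the trough floor).
Passing tests on these recordings shows the *pipeline arithmetic* is
correct under the stated protocol, not that a physical sensor meets the
same error bounds.

**Populations.** `simulate_population` draws per-subject parameters from
truncated normal distributions; the default cohort varies `rr_mean_bpm`
(17.6 ± 1.7) and `volume_gain_l_per_rhs` (0.012 ± 0.002) across 7
subjects. Each subject's RNG stream derives from `(seed, subject_index)`,
so cohorts are reproducible element-wise.

## Segmentation (`segment.py`)

Both channels are resampled to a common 100 Hz analysis grid (breathing
content is below ~1 Hz, so 100 Hz is generous; it also removes the 5 kHz
vs 1 kHz disparity between devices). Downsampling uses polyphase FIR
anti-aliasing with odd-reflection edge padding (keeps DC and trends exact
at the boundaries); upsampling is linear. Signals are then smoothed with a
4th-order zero-phase Butterworth low-pass at 2 Hz — wide enough to keep
deep-breath morphology, tight enough that the double-differenced signal is
usable at the sensor noise level.

Extrema come from prominence-based peak picking (default prominence
1 %RH, minimum separation 1 s — which caps detectable RR at 60
breaths/min; plateau ties resolve to the first plateau sample), followed
by an alternation pass that collapses same-type runs to their most extreme
member. A breath cycle is the half-open interval between consecutive
minima with the enclosed maximum as peak; its amplitude is peak minus the
lower bounding trough.

**Deep-breath detection.** A cycle is a deep candidate when its amplitude
exceeds 1.5× the rolling median amplitude over 10 cycles (the median
resists the deep breaths' own influence on the threshold). Consecutive
candidates are paired in order into (deep-inhale, deep-exhale) events; an
unpaired candidate becomes a single-cycle event split at its peak. Event
boundaries are refined to the nearest sign change of the central second
difference within 0.15 s of the trough. The tight window matters: it
corrects noise-blurred trough localisation but prevents the boundary from
sliding a quarter-period away to the mid-limb inflection that every smooth
pulse possesses, which would systematically truncate the event's area.

**Respiratory rate.** RR per non-overlapping, left-aligned 60 s window is
`count × 60 / window`, counting minima by default (maxima via a flag; on
any signal with alternating extrema the two differ by at most endpoint
effects). Extremum times are refined to sub-sample precision with a local
least-squares parabola (±0.2 s), which stabilises window assignment of
breaths falling near window edges. The final partial window is dropped.

## Volumes (`volume.py`)

All volumetric parameters use the rectangle method — the left-endpoint
Riemann sum `Σ max(f(x_i) − baseline, 0)·Δt` — whose error on these smooth
pulses is second order in Δt (verified by the halving test). The clamp at
zero keeps areas non-negative and makes deep events integrable above the
same floor as normal breaths.

The integration baseline defaults to the **median of the signal values at
the detected minima**: the normal trough floor. A global low percentile is
offered as an alternative but is not the default, because the deep-inhale
troughs dip ~22 %RH below the floor and drag a 5th percentile several %RH
under it, which corrupts every tidal area by tens of percent.

TV is the area of each normal cycle; IRV and ERV are the areas of the deep
event's inhale and exhale limbs (refined boundaries, split at the shared
trough); VC = IRV + ERV exactly, and DBA — the area over the closed event
— equals their sum by the additivity of integration. The triangle method
(shoelace area of the trough–peak–trough vertices) exists only for the
method comparison; it sees three samples instead of the full pulse, so it
is blind to plateau-length variation and badly biased on deep cycles,
which is why its correlation with the true volumes is consistently lower.

Calibration to litres is an affine least-squares fit of normal-cycle
humidity areas against reference volumes of the time-matched cycles
(monotone nearest-neighbour matching within half a breath period). The
offset absorbs baseline-estimation bias; the gain must be positive, and
constant areas raise a singular-fit error. After calibration VC is
re-derived as IRV + ERV so the identity stays exact.

## Agreement statistics (`agreement.py`)

**Bland–Altman.** Differences are `a − b` (unit mode) or
`100(a − b)/pair mean` (percent mode), optionally after dividing each pair
by its subject's mean level. Bias is the mean difference; the limits of
agreement are bias ± 1.96·SD (sample SD, n−1). Two further limit modes are
provided: `log` (limits computed on log-differences and mapped back, which
yields the asymmetric limits appropriate for positive skewed data) and
`mixed` (random subject intercept fitted by maximum likelihood with
statsmodels; the subject variance component is kept only when the mixed
model improves AIC by more than 2 points over the pooled-normal model,
otherwise it is fixed to zero). The simple normal-theory estimator is the
default.

**One-way ANOVA.** The standard between/within decomposition with the P
value from the upper tail of the F distribution. Degenerate inputs are
handled explicitly: all-identical data give F = 0, P = 1; zero
within-group variance with non-zero between-group variance gives P = 0
with a degeneracy flag. `anova_from_summary` rebuilds MS, F and P from a
printed SS/df decomposition, which makes published summary tables
checkable without the raw data. (Note that when a printed table is not
internally consistent, the reconstruction reports the self-consistent
values implied by the printed SS and df, which need not equal every
printed MS/F/P entry.)

**Box summaries** use linear-interpolation quartiles (numpy default,
type 7) with whiskers at the most extreme points within 1.5·IQR of the
quartiles. P values are displayed to two decimals in rendered summaries;
full precision is retained in the JSON.

## Study orchestration (`study.py`)

`RespiratoryStudy(config).fit()` runs, per subject: simulate (or read
CSVs) → resample to the grid → smooth → segment → detect deep events →
areas → calibration → volumes, on the humidity channel; and independently
segments the cumulative integral of the flow channel (a volume trace whose
per-cycle excursions are the reference volumes) for the reference cycles
and RR. Deep events are identified on the humidity channel — the protocol
defines when deep breaths happen — and the reference DBA is the summed
volume excursion of the reference cycles overlapping the event window.
Pooled across subjects, the study reports Bland–Altman (DBA and RR),
one-way ANOVA per parameter with device as the grouping factor, RMSE and
Pearson correlation, box summaries and group means. Pooling windows and
events across subjects treats them as independent observations per device;
this mirrors the usual practice in small validation studies and is noted
here as a caveat rather than corrected, since the mixed-limits mode covers
the subject structure where it matters.

All randomness flows from the single study seed; identical config + seed
reproduces `report.json` byte for byte (floats serialised via repr,
keys sorted).

`null_rejection_rate` calibrates the ANOVA under the null: replicate
studies whose two channels share ground truth but carry independent
noise. Replicates are scaled down (2 subjects × 180 s at 500/250 Hz) so a
100-replicate run takes seconds; the comparison logic is the full
pipeline. The observed rejection rate sits at or below the nominal level —
below it, in fact, because the two channels share the breath-to-breath
variability, which makes the test conservative.

## Numerical choices and edge cases

- 0-based sample indices everywhere; sample i at `start + i/rate`;
  half-open `[start, end)` intervals for cycles and areas.
- CSV timestamps must be strictly increasing and uniform to 0.5% jitter;
  rates are inferred from the median spacing, and window counts tolerate
  ~1e-9 relative rounding so file round trips do not lose a window.
- Telemetry frames decode as 32-bit IEEE-754, big-endian by default
  (network order; a flag selects little-endian). Non-finite payloads are
  decoded faithfully and flagged with a warning.
- Ties in plateau extrema go to the first sample; ties in second-derivative
  sign changes to the earlier index.
- Empty segmentations, absent deep events, constant inputs and singular
  fits raise or degrade explicitly (see the docstrings) rather than
  producing silent NaNs.

## Problem sizes used in the shipped checks

The packaged validation suite runs the default cohort (7 subjects ×
15 min at 5 kHz/1 kHz) for parameter recovery and the end-to-end
equivalence checks, 100 scaled-down replicates for the null calibration,
and reduced recordings (2–3 min at 500/250 Hz) for the unit tests. These
sizes were chosen so the whole suite gives stable statistics in well under
a minute of simulation per check.

## Known limitations

- The %RH→litres link is linear by construction in the simulator and by
  assumption in the calibration; real sensors saturate and hysterese, so a
  field calibration would need a richer model.
- The reference channel's deep events are read out at humidity-detected
  event windows; a fully independent deep detection on the reference would
  require a volume-separable deep-breath model, which saturation of the
  humidity peak makes impossible on the humidity side and pointless on the
  reference side.
- Residual volume is not measurable from this signal and is out of scope.
- Uncalibrated areas are reported in %RH·s and never presented as litres.
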