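# Methods

This note records the models, conventions, and numerical choices behind each
stage of the pipeline, the design decisions that were genuinely open, and what
the synthetic generators do and do not emulate.

## Record handling

Records are MIT-format `.hea`/`.dat` pairs; only single-file, format-16
(16-bit little-endian, sample-interleaved) records with explicit per-lead
gain and units are supported, which is exactly what the package writes.
Amplitudes are held in mV internally; µV and V inputs are converted, records
without unit metadata are rejected rather than guessed. The wall-clock start
`t0` must be explicit — it is never inferred — because window extraction is
defined on the record clock.

The standardized analysis window is 02:00:00–02:30:00 local record clock,
chosen to compare patients under comparable (sleeping) conditions; it is
fully configurable. Partial overlap of at least 20 minutes is accepted with
an explicit incomplete-window flag, because DC and PRD are validated for
recordings of 20 minutes or more; shorter overlap is rejected. Sampling
rates other than 250 Hz are accepted; all sample-index arithmetic uses the
header rate.

## Beat detection and RR validity

The R-peak detector is deterministic: 8–25 Hz zero-phase Butterworth
bandpass, squared, 120 ms moving average, peaks above 0.25× the 99.5th
percentile of the envelope with a 200 ms refractory period, refined to the
raw-amplitude extremum within ±50 ms. A lead qualifies only if the median
envelope at detected peaks exceeds 8× the overall median envelope (QRS energy
must dominate the baseline); flat or noisy leads fall through to the next
lead. On clean synthetic ECGs localization is within ±2 samples of the true
QRS extremum.

RR intervals are `rr[i] = (r[i+1] − r[i])·1000/fs`, timestamped by the
terminating beat. Validity follows standard Holter practice: intervals
outside [300, 2000] ms, intervals differing more than 20% from the preceding
valid interval, and intervals adjacent to a non-normal beat are invalid.
Ectopy is labelled by a morphology-free prematurity rule: an interval below
80% of the local median followed by a compensatory interval above it marks
the intervening beat. All thresholds are keyword arguments.

AF screening is an RR-irregularity surrogate with a documented, testable
rule (the clinically validated detector it stands in for is proprietary to
its authors): over sliding 60-beat windows, a window is flagged when the
normalized RMSSD of the median-filtered series exceeds 0.10 **and** more
than 25% of successive differences exceed 50 ms; the record is AF when more
than half the windows are flagged. Screening runs on raw intervals — the
validity filter would otherwise mask the very irregularity being sought.
Fewer than 60 intervals yield an indeterminate result, not an error.

## Deceleration capacity

PRSA anchors are positions `i` with `mean(rr[i..i+T−1]) > mean(rr[i−T..i−1])`
over valid intervals, with T = 4 beats (the smoothing span recommended for
noisy monitor-derived series). Anchors whose mean rate change exceeds 5% are
excluded as artifacts — the convention of the original DC literature; the
bound is configurable. Anchors are aligned and averaged over ±L beats
(default L = 20; only the central offsets feed DC, the rest serve
diagnostics), discarding anchors without a full margin or with any invalid
interval inside the window — conservative discarding, never interpolation.

DC is the scale-2 Haar coefficient at the curve centre,
`DC = (x[0] + x[1] − x[−1] − x[−2]) / 4` in ms, with offset k = 0 the anchor
interval itself. Fewer than 50 surviving anchors (about what 30 minutes of
sinus rhythm yields) flags the value `low_anchor_count`; a series with no
usable anchors yields an explicit `undefined` quality, never a silent zero.
Acceleration capacity is available through the same code path by flipping
the anchor inequality, as an uncommitted by-product.

Two properties worth noting: DC scales linearly with the RR series and is
invariant under a constant RR offset *for a fixed anchor set*; the relative
5% artifact bound legitimately changes the anchor set under an offset, so the
offset invariance is exact only with the bound disabled.

## Periodic repolarization dynamics

**Orthogonal leads.** Twelve-lead records are converted with the Kors
regression matrix (from leads I, II, V1–V6); three quasi-orthogonal monitor
leads map through an identity transform with per-lead polarity; an explicit
3×n matrix is also accepted. Fewer than three leads raise a dedicated
signal that routes scoring onto the DC-only path.

**Angle frame** (fixed by convention, since only the angle names are
standard): azimuth = atan2(z, x), elevation = angle from the x–z plane toward
y, both in degrees; the vector amplitude is √(x²+y²+z²).

**T-wave delineation** is a deterministic surrogate validated against the
generator's ground truth: search window
[R + 0.25·1000·√RR_s, R + 0.55·1000·√RR_s] ms (square-root rate adaptation),
clipped 20 ms before the next R, refined to the contiguous region around the
in-window amplitude maximum where the amplitude stays above 25% of that
maximum. Non-normal beats and beats after an invalid interval are skipped.

**T° and dT°.** The per-beat repolarization direction is the
amplitude-weighted mean azimuth and elevation over the window; the unit
vector is rebuilt from the averaged angles. Weighted *angle* averaging is
exact for a constant within-beat direction (which the generator produces) and
adequate away from the ±180° azimuth wrap; directions near the wrap are a
known limitation. dT° is the angle `arccos(u_i · u_{i+1})` between successive
unit vectors — unit vectors, not amplitude-weighted ones, because the
quantity is an angle. Beats with an all-zero window are dropped.

**Wavelet quantification.** The unevenly sampled dT° series is linearly
interpolated onto a 4 Hz grid, mean-detrended, and passed through an analytic
Morlet filter bank: mother wavelet ψ(t) = (πB)^(−1/2)·e^{2πit}·e^{−t²/B} with
B = 0.5, i.e. a Gaussian frequency response exp(−π²B(f/f_c − 1)²) per centre
frequency, 12 centre frequencies tiling [0.01, 0.1] Hz log-uniformly. PRD is
the mean squared coefficient magnitude (deg²) over time and scales, excluding
each scale's cone of influence (two envelope e-folding times at either edge);
scales whose cone covers the whole series contribute nothing. Series shorter
than 60 s or 30 angles are flagged, not scored.

Two numerical choices here deserve their rationale:

- *The filter bank is implemented directly in the frequency domain* rather
  than through a generic CWT routine. Tabulated-wavelet convolution CWTs
  carry a numerical sidelobe floor around −35 dB, which is far too high for
  this method's contract that out-of-band T-axis modulation must not register
  in the ≤ 0.1 Hz band; the closed-form Gaussian response has a stopband
  exact to machine precision. A generic CWT (PyWavelets) is retained in the
  test suite as an independent cross-check of passband behaviour.
- *The 4 Hz grid* (not 2 Hz) matters because linear interpolation leaves
  images of beat-frequency content just below twice the beat rate; with a
  2 Hz grid the image of a rectified 0.53 Hz component sampled at 1.33 Hz
  beats folds to 0.13 Hz — directly onto the band edge. At 4 Hz all such
  images stay far out of band for any plausible heart rate.

A genuine physical limitation, distinct from both: the dT° of a *rigidly
rotating* T axis is a rectified signal. Its fundamental sits at twice the
rotation frequency, and beat-interval variability modulates its envelope,
demodulating fast rotation into genuine low-frequency angle power. Band
selectivity of the analyzer is therefore assessed on metronomic-beat
fixtures; on jittered-beat fixtures part of the measured in-band power truly
belongs to the angle series.

PRD can be computed on AF recordings (the T-wave gating makes no sinus
assumption); the result then carries an `af` flag so consumers can treat it
as a sensitivity analysis rather than a routine value.

## HRV battery

Time domain on valid ("normal") intervals only: SDNN (population SD), RMSSD
(adjacent valid pairs), triangular index with 1/128 s bins requiring at least
5 minutes of data. Frequency domain: cubic-spline resampling of the NN
tachogram at 4 Hz, linear detrend, Welch periodogram (segments up to 256 s,
50% overlap), band powers integrated over VLF 0.0033–0.04, LF 0.04–0.15,
HF 0.15–0.40 Hz. A Lomb–Scargle estimator is available for heavily gapped
series; its absolute scaling is approximate and it is intended for relative
band comparisons. Short-recording SDNN is reported as computed; 24-hour SDNN
semantics are out of scope.

## The score

`CAF = round[10·exp(β_PRD·PRD + β_DC·DC)]`, clamped to [0, 100], after
capping PRD at 30 deg² and DC into [0, 4.5] ms. The DC upper cap encodes
"DC ≥ 4.5 ms is normal" as saturation of benefit; a raw mode ([0, ∞)) is
available because the alternative reading is defensible. Rounding is
half-away-from-zero (the published rule is unstated); the cohort cutoff is
the lower median, so it is always an attained integer score (published
constant 11).

When PRD is unavailable the default fallback applies the univariable DC
coefficient in the same exponential template,
`round[10·exp(β_DC,uni·DC)]`, following the methods-text description of the
fallback; the figure-caption formula `round[10·(C·β_DC + β_DC·DC)]` with
C = 4.5 — which has no exponential and goes negative before clamping — is
implemented verbatim behind `fallback="caption-literal"` for reproduction
studies. The two published descriptions conflict; neither is silently
"corrected".

The originally fitted coefficients were never published.
`reference_coefficients()` therefore ships the unique (β_PRD, β_DC) pair that
maps the published survivor/non-survivor marker medians (PRD 7.2/12.9 deg²,
DC 4.1/1.6 ms) onto the published score medians (11 and 14 units):
β_PRD = 0.02966 per deg², β_DC = −0.02884 per ms. The univariable fallback
coefficient is set to −0.10 per ms, a typical univariable DC log-hazard
(hazard ratio ≈ 0.90 per ms). These are calibration constants for simulation
and end-to-end exercises, clearly labelled `table-calibrated`; real
deployments should fit `derive_score_coefficients()` on a training cohort.
Note a structural consequence of the published fallback: with a negative DC
coefficient and DC capped at 0, the DC-only exponential score can never
exceed 10 and therefore never reaches the 11-unit high-risk cutoff.

## Survival statistics

The endpoint is 30-day intrahospital mortality: deaths carry their day,
everyone else — including patients discharged alive earlier — is censored at
day 30. Every subject therefore has known 30-day status, and the
reclassification metrics are complete-case at the horizon.

- **Cox models** are fitted with lifelines (Efron tie handling, the standard
  choice with many ties at integer days). Training-style coefficient
  derivation fits the multivariable {PRD, DC} model plus the univariable DC
  model for the fallback path.
- **Kaplan–Meier** is implemented in-package so the Greenwood standard error
  is a first-class output; confidence intervals are computed on the
  log(−log) scale and back-transformed, clipped to [0, 1]. Subjects censored
  at an event time count as at risk for it. The curve and its CI are
  cross-checked against lifelines in the test suite; log-rank comes from
  lifelines.
- **ROC/Youden**: trapezoidal AUC; the optimal threshold is the midpoint
  between the adjacent score values that the best cut separates, so toy
  examples report the intuitive "between 2 and 3" threshold.
- **Reclassification** (IDI, continuous NRI, median improvement): linear
  predictors are converted to 30-day risks by anchoring on the cohort
  Kaplan–Meier survival, `risk_i = 1 − S(t0)^{exp(lp_i − mean lp)}`;
  pre-computed risks are accepted directly. IDI is the event/non-event mean
  risk separation of the augmented minus the base model; continuous NRI is
  the signed concordance of risk changes; median improvement is the change
  in median risk separation. Percentile bootstrap CIs, default 1000
  replicates with a fixed seed.
- **Risk tiers** hard-code the published decision-tree thresholds
  (SAPS3 56/69/89, CAF 11) as a total partition: low < 56; increased for
  56–68 or (≥ 69 with CAF < 11); high for 69–88 with CAF ≥ 11; very high for
  ≥ 89 with CAF ≥ 11. The published figure omits an explicit ≥ 89 & CAF < 11
  branch; that region falls into the "≥ 69 with CAF < 11" arm, keeping the
  partition total. The alternative published tier names (very
  low/low/intermediate/high) are exposed as aliases; no semantic difference
  is assumed.
- **Sample size** follows the events-per-variable rule:
  `min_events = n_params·EPV`, `min_n = ceil(min_events / event_rate)`.

## Synthetic generators

All generators are pure functions of config + seed.

- **RR series**: mean RR 800 ms with respiratory modulation (20 ms at
  0.25 Hz), a low-frequency component (10 ms at 0.1 Hz), transient 3-beat
  deceleration bursts (2/min, 30 ms) and 5 ms Gaussian noise, evaluated at
  the actual cumulative beat times. These defaults sketch a stable sinus ICU
  patient; they are not a fitted physiological model.
- **ECG**: sum-of-Gaussians P-QRS-T dipole projected onto three orthogonal
  leads; the T-wave direction is rigidly rotated about a fixed axis
  perpendicular to the resting T axis by `amp·sin(2πft)`, which makes the
  true angle between successive beats exactly `|Δθ|` and exportable in
  closed form. Beat spacing carries respiratory modulation (25 ms) and 10 ms
  noise by default; an `af_like` mode draws intervals uniformly from
  [400, 1200] ms. Not emulated: realistic QRS morphology variation, noise
  colour, electrode artefacts, U waves — so passing tests demonstrate
  algorithmic correctness on idealized geometry, not robustness to clinical
  signal quality.
- **Cohorts**: PRD lognormal (median 7.7 deg², matching the published IQR),
  DC normal (4.0 ± 3.8 ms), 30-day exponential survival with hazard
  `λ0·exp(β_PRD·PRD_capped + β_DC·DC_capped)` and administrative censoring
  at day 30; SAPS3 is a noisy linear coupling to the linear predictor. The
  default coefficients are the table-calibrated reference values, under
  which the simulated score median lands on the published 11-unit cutoff and
  the event rate near the published validation mortality. Covariate effects
  act through the *capped* markers, mirroring how the score consumes them,
  so hazard-recovery tests regress on the capped columns.

## Problem sizes in the test and acceptance runs

Oracle-equivalence checks use 100 random RR series up to 2000 beats; band
response uses 300 s synthetic ECGs; parameter-recovery suites use 200
replicates of cohorts of 600–2000 patients; the reclassification demo cohort
is 1057 patients. These sizes give stable Monte-Carlo estimates while the
full suite completes in well under a minute per heavy battery.

## Known limitations

- The AF screen and the T-wave delineator are documented surrogates behind
  the published interfaces, not reimplementations of the cited proprietary
  algorithms; cohort exclusion policy on "other arrhythmia" is left to the
  caller.
- The absolute PRD scale depends on the wavelet normalization; only
  relative/monotone behaviour is contracted, and values are not numerically
  interchangeable with other PRD implementations.
- Weighted angle averaging degrades near the azimuth ±180° wrap.
- Rectification demodulation (above) means strong high-frequency T-axis
  rotation plus irregular beats can contribute genuine low-frequency dT°
  power.
- Daylight-saving or missing clock metadata are not handled; `t0` is
  required and taken at face value.
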