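# Methods

## Scope and model

`cerebtfa` quantifies dynamic cerebral autoregulation from paired
recordings of mean arterial pressure (MAP, mmHg) and transcranial-Doppler
middle cerebral artery blood flow velocity (MCAv, cm/s). The underlying
model is a single-input, single-output linear system excited by
spontaneous MAP oscillations (Mayer waves near 0.1 Hz, respiratory
fluctuations at 0.20–0.30 Hz, slow drifts below 0.07 Hz). Welch
auto-/cross-spectral estimation yields, per frequency,

- **gain** `|S_xy| / S_xx` (cm·s⁻¹·mmHg⁻¹): how strongly pressure
  oscillations are transmitted into flow velocity;
- **normalised gain** `gain · mean(MAP) / mean(MCAv)` (%MCAv per %MAP);
- **phase** `arg(S_xy)` (rad), positive when MCAv leads MAP — a larger
  lead means a faster-acting autoregulatory response;
- **squared coherence** `|S_xy|² / (S_xx · S_yy)` in [0, 1], the
  linearity/SNR gauge that decides whether gain and phase are trusted.

These are averaged over three bands: VLF [0.02, 0.07), LF [0.07, 0.20)
and HF [0.20, 0.30] Hz. LF is the primary autoregulation band; the
interpretation convention is that decreased (normalised) gain and/or an
increased phase lead indicate enhanced autoregulation, reported per
metric and never fused into one score.

Assumptions inherited from this framework: the MAP→MCAv relation is
approximately linear and time-invariant over the analysis window, MCAv
is a valid CBF surrogate (constant vessel diameter and insonation
angle), and CO₂ is held constant so vasomotor tone is not confounded.

## Analysis parameters

| parameter | default | units | rationale |
|---|---|---|---|
| analysis window | 600 | s | trailing 10 min of each intervention, after steady state |
| analysis rate | 10 | Hz | standard resampling target for beat-scale hemodynamics |
| Welch segment | 1200 | samples | 120 s segments: resolves 0.02 Hz with 9 segments per window |
| segment overlap | 60 | s | 50 % overlap with Hann tapering |
| taper | Hann | — | leakage control |
| bands | 0.02–0.07–0.20–0.30 | Hz | VLF / LF / HF convention |
| coherence threshold | 0.4 | — | estimates below it are flagged invalid (≥ rule) |
| mean window | 240 | s | trailing 4 min channel means for reported values and COVR |

Resampling uses a zero-phase (forward–backward) 8th-order Butterworth
low-pass with cutoff at 0.4 × the target Nyquist (2 Hz for the 10 Hz
target) followed by decimation — zero-phase because phase is the
headline quantity. Non-integer rate ratios interpolate the filtered,
hence band-limited, signal with a cubic spline. Upsampling is refused
rather than silently interpolated, and recordings with gaps are rejected
at ingest: imputation would bias phase invisibly.

Welch segments are mean-removed only (no linear detrend), the standard
choice. The "60 s overlap" with 1200-point segments at 10 Hz is 600
samples, i.e. 50 %. Band aggregation averages the per-bin derived
quantities (gain, phase, coherence) across bins, the mainstream practice
in this field; recomputing them from band-averaged spectra is available
via `band_average(..., method="band_spectra")`. Band powers (`MAP_sp`,
`MCAv_sp`) integrate the PSD over the band (density × bin width), giving
mmHg² and cm²·s⁻². Phase is the principal value of the cross-spectrum
argument with no unwrapping — below 0.30 Hz physiological phase stays
well inside (−π, π]. Bin inclusion uses half-open intervals [f_lo, f_hi)
with the HF band closed at 0.30 Hz, so shared edges are never counted
twice. Validity is judged on the band-averaged coherence, mirroring the
per-subject LF exclusion practice, not by masking individual bins. With
a single Welch segment coherence is identically 1 and therefore reported
as undefined (NaN) with a warning.

## Oxygen content and vasoreactivity

Arterial oxygen content: `CaO2 [mM] = SaO2 · Hb [mM] + 0.01 · PaO2 [kPa]`
(haemoglobin-bound plus dissolved oxygen). Cerebral oxygen
vasoreactivity (COVR) is the percent change in MCAv per kPa change in
PaO₂ (or per mM CaO₂ in the content-based variant), computed from
trailing 4-minute means against the same-condition normoxic reference,
and separately for hyperoxic and hypoxic challenges because the
PaO₂–CBF relation is nonlinear. The pipeline stores the signed slope
ΔMCAv% / Δx — unambiguous for downstream arithmetic — and renders the
conventional magnitude-with-direction phrasing ("x % increase in MCAv
per kPa decrease in PaO₂") only in reports. Group COVR is the median of
per-subject slopes, never a ratio of group medians.

## Cohort statistics

Paired contrasts (each intervention vs its same-condition normoxia;
each intervention baseline vs post-endotoxin) use Wilcoxon's signed-rank
test. Zero differences are dropped before ranking (Wilcoxon's original
convention), ties receive mid-ranks, and for n ≤ 20 the p-value is exact
over all 2ⁿ sign assignments, computed by dynamic programming over
doubled mid-rank sums — exact even with ties, where classical
table-based exact tests fall back to approximations. Larger samples use
the normal approximation with tie and continuity corrections. Holm's
step-down correction is applied within each family of comparisons
(within-condition and across-condition families, per metric per band;
family structure is configurable and logged). Summaries are median with
interquartile range; quartiles interpolate linearly between order
statistics.

Subjects whose LF band coherence falls below 0.4 in any recording are
excluded from the autoregulation summaries and comparisons, logged with
the offending recording and coherence value, and retained for COVR,
where the spectral criterion is irrelevant.

## Synthetic-data generator

No raw recordings from endotoxaemia studies are publicly available, so
the generator provides ground-truth-known input for every downstream
stage:

- **MAP**: setpoint 88 mmHg plus sinusoids at 0.04 Hz (1.5 mmHg),
  0.10 Hz (3.0 mmHg) and 0.25 Hz (1.5 mmHg) plus white noise
  (SD 1.5 mmHg) — the minimal structure putting power in all three
  bands. The Mayer-wave amplitude puts the LF band power at
  ≈ 4.5 mmHg², the order of magnitude reported for resting volunteers;
  no quantitative MAP spectrum exists to fit against.
- **MCAv**: MAP passed through a configurable linear transfer model —
  identity, scalar gain, pure delay, or a frequency template
  interpolated linearly between (f, gain, phase) nodes — applied by
  frequency-domain multiplication (conjugate-symmetric via the real
  FFT), so the realised response equals the model exactly and is
  checkable. Independent Gaussian noise is added to the output channel
  only, which gives the closed-form band coherence
  `S_signal / (S_signal + S_noise)` used as an analytic oracle. The
  default output noise SD of 0.8 cm/s yields band coherences of
  ≈ 0.85–0.90, typical of good-quality recordings.
- **Cohorts**: the LF phase lead rises from 0.58 rad (baseline) to
  0.82 rad (post-endotoxin) at constant gain 1.26 cm·s⁻¹·mmHg⁻¹, with a
  shared per-subject offset (SD 0.08 rad) and per-recording jitter
  (SD 0.04 rad) — moderate, plausible scatter chosen once; MCAv
  setpoints 72 / 69 / 79 cm/s for normoxia / hyperoxia / hypoxia;
  blood-gas panels drawn around per-intervention targets (PaO₂
  13.2 / 28.5 / 7.5 kPa, SaO₂ 0.98 / 1.00 / 0.90, Hb 8.44 mM, giving a
  normoxic CaO₂ near 8.4 mM). Recordings default to 1200 s
  (20-minute interventions); because the generator is stationary, the
  trailing-window extraction makes a 600 s simulation statistically
  equivalent, and replicate-heavy validation runs use that length.
- **Determinism**: one root seed sequence spawns every per-cell stream;
  a fixed seed reproduces the cohort bit for bit, and ground-truth
  parameters are stored beside the data (`ground_truth.json`) so
  recovery tests never re-derive them.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: pulsatile per-beat waveforms,
baroreflex and CO₂-reactivity feedback, nonlinear or hysteretic
autoregulation, non-stationarity, movement artefacts, and measurement
dropouts. Recovery of the generator's parameters shows the estimator
chain is correct, not that real cerebral autoregulation is linear.

## Numerical choices and degenerate inputs

- Bins with zero MAP power yield NaN (undefined) gain/phase, never
  infinities; bands containing no bins raise an error naming the
  frequency resolution.
- A band coherence exactly at the threshold is valid (≥ comparison).
- All-zero paired differences raise a degenerate-sample error rather
  than returning p = 1.
- Exact Wilcoxon doubles the smaller tail and caps at 1; mid-ranks make
  the doubled-rank DP integral.
- Equality tolerance for the qualitative direction verdict is 1e-12 in
  the metric's own units (configurable); median summaries feed it, and
  verdicts are withheld with a reason when either side fails the
  coherence criterion.
- Simulation-heavy checks (type-I calibration, replicate recovery
  rates) use 10-subject, 600 s cohorts and replicate seeds drawn from a
  parent generator, which keeps replicates statistically independent;
  arithmetic seed sequences produced measurably correlated replicates.

## Known limitations

- Coherence estimates from 9 Welch segments carry a small positive bias
  (≈ (1−γ²)²/9), visible when validating the closed-form coherence
  oracle; tolerance 0.05 absorbs it.
- The frequency-template filter acts circularly on the whole record;
  wrap-around effects are negligible at 600–1200 s but would matter for
  very short records.
- The normalised-gain definition (gain × mean MAP / mean MCAv) is the
  common percent-per-percent convention; other groups normalise
  differently, so absolute comparisons across software require care.
- The linear mixed model occasionally used for vital-sign time courses
  in this literature is out of scope; the pipeline reports
  Wilcoxon/Holm only.
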