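# Methods

`sophase` quantifies the spatial organization of spindle–slow-oscillation
(SO) coupling in NREM sleep scalp EEG: at each electrode the SO phase at
which sleep spindles occur is summarized, and the advance of that preferred
phase along the anterior–posterior (AP) electrode axis — *phase precession*
— is fit with circular-linear regression. This note documents the model, the
numerical conventions, the synthetic-data generator used in place of
clinical recordings, and the known limitations.

## Signal model and pipeline

The analysis operates on 128 Hz, 0.1–50 Hz bandpassed EEG (zero-phase
4th-order Butterworth cascades throughout; recordings sampled below 128 Hz
are refused rather than upsampled). Analysis is restricted to artifact-free
N2/N3 sleep: a 30-s-epoch hypnogram gates stages, and 5-s windows are
rejected per channel when any of three criteria holds — |v| > 400 µV,
window SD < 0.01 µV, or the SD of the window's 30–50 Hz bandpassed signal
exceeding 3× the SD of the whole recording's 30–50 Hz bandpassed signal.
Criteria are applied per channel (a config switch extends rejection across
channels); the trailing partial window is rejected conservatively; the
criterion-3 denominator uses the full standardized recording, not only
N2/N3. Recording polarity is asserted by configuration
(`assume_polarity_ok`), standing in for a visual check of eye-blink
deflections.

**Montages.** Three re-referencing schemes are supported: common average
(mean over the included channels subtracted per sample), referential
(subtraction of a named channel such as a neck electrode), and longitudinal
bipolar (anterior-minus-posterior neighbor pairs along the standard chains
Fp1–F3–C3–P3–O1, the right homolog, and Fz–Cz–Pz). Bipolar derived channels
are assigned the midpoint of their two electrodes' AP positions (1.5, 2.5,
3.5, 4.5), keeping the slope's per-unit scale commensurable across montages.

**Spindle detection.** Complex Morlet wavelet power, center frequencies
11–16 Hz in 0.5 Hz steps, averaged across frequencies and smoothed with a
100 ms moving average. The primary detector z-scores the smoothed power over
usable samples and keeps maximal runs with z > 2 spanning ≥ 300 ms whose
within-run maximum exceeds 3; the alternative detector thresholds the same
smoothed power at a fixed 4.5× its mean over usable samples, with the same
duration rule and no z-scoring. Runs separated by < 100 ms are merged before
duration testing; a 3 s duration cap guards pathological inputs; events
touching any unusable sample are discarded; the event peak is the argmax of
the smoothed detection signal. The wavelet width is 4 cycles: its temporal
FWHM (~0.12 s at 13 Hz) is kept well below the 300 ms duration criterion so
that measured event durations reflect the burst rather than the wavelet's
own support — with wider wavelets a strong 0.2 s burst smears into a
qualifying ≥ 300 ms run. Duration is measured between the first and last
supra-threshold sample (a run must span ⌈0.3·fs⌉+1 samples).

Two behaviors of z-thresholded detection are worth stating plainly. First,
at a 2σ run threshold, 1/f background noise produces occasional qualifying
runs (~0.5 false events per 2 minutes per channel in simulation); detection
counts on noise-only signal are not exactly zero. Second, which of the two
detectors is "more stringent" depends on the signal: on sparse,
near-threshold events — the regime of real overnight EEG — the fixed
4.5×-mean bar admits fewer events than the z criteria, but on dense
strong-burst signal the z-detector's σ self-inflates and the ordering can
flip.

**Slow-wave detection.** On the zero-phase 0.5–4 Hz filtered signal,
candidate events are negative half-waves between consecutive down-going and
up-going zero crossings 0.25–1.0 s apart (0.5–2 Hz waves); a candidate is
kept when its Hilbert-envelope maximum exceeds the 75th percentile of the
absolute filtered signal over the channel's usable samples. The rectified
(amplitude) percentile is the convention under which the detector's analytic
contracts hold: on a pure sinusoid the threshold (~0.92× amplitude at the
75th percentile of |sin|) sits below the envelope, so every half-wave of a
homogeneous oscillation qualifies, while in a mixture of large and small
waves only the large ones pass.

**SO phase.** The instantaneous SO phase is the argument of the analytic
(Hilbert) signal of the zero-phase 0.5–2 Hz filtered channel; phase 0 falls
at positive SO peaks, ±π at troughs, −π/2 at up-going zero crossings. The
analytic signal is computed independently on each contiguous usable segment
(no interpolation across artifacts or wake), and samples within 2 s of a
segment edge are excluded as unreliable. One phase sample is read per
spindle, at the spindle peak.

**Slow-wave gating (sensitivity mode).** When phases are restricted to
spindles co-occurring with detected slow waves, co-occurrence means the
spindle peak falls within the SW's negative half-wave extended by one
half-wave duration on each side — the full slow-wave cycle around the
detected trough, including the adjacent positive peaks where spindles
preferentially occur. Restricting to the negative half-wave itself
(`sw_margin_half_waves=0`) amputates every channel's phase distribution to
the trough-facing arc; in simulation this truncation systematically reverses
the fitted slope (+0.47 for an imposed −0.9), so it is not the default.
Gated phases are read from the same 0.5–2 Hz Hilbert phase (a config key
allows the 0.5–4 Hz SW-filtered phase instead).

## Circular statistics and the precession fit

Per channel, the mean phase is arg(Σe^{iφ}) and the resultant length
R̄ = |Σe^{iφ}|/n; non-uniformity is tested with the Rayleigh statistic
Z = nR̄², using the standard small-sample series
p = e^{−Z}[1 + (2Z−Z²)/(4n) − (24Z−132Z²+76Z³−9Z⁴)/(288n²)] (a Monte-Carlo
null simulation is available as an alternative method). The mean phase is
reported as undefined (NaN) when the resultant vanishes.

**Position axis.** The 13 parasagittal 10-20 electrodes are grouped into
five AP rows — {Fp1,Fp2}→1, {F3,Fz,F4}→2, {C3,Cz,C4}→3, {P3,Pz,P4}→4,
{O1,O2}→5. Under standard 10-20 placement the rows sit at the cumulative
10-30-50-70-90% marks of the nasion–inion distance, so one position unit
spans 20% of that distance.

**Slope (Kempter-style circular-linear regression).** The slope â maximizes
the mean resultant length of the phase residuals,
R(a) = (1/n)|Σ_j exp(i(φ_j − a·x_j))|, equivalent to minimizing the summed
circular distances between the data and the line φ = φ₀ + a·x; the offset is
φ₀ = arg Σ_j exp(i(φ_j − â·x_j)). The search scans a coarse 10⁻² rad/unit
grid over ±π rad/unit (configurable; a boundary fit raises a warning),
breaks exact ties toward the smallest |a| (favoring the null of no
precession), then refines within one grid step by bounded scalar
optimization (tolerance 10⁻⁷). Matching an exhaustive 10⁻³ grid search is
part of the test suite.

**Strength (circular-linear correlation).** With r_cx = corr(cos φ, x),
r_sx = corr(sin φ, x), r_cs = corr(cos φ, sin φ):
R = √[(r_cx² + r_sx² − 2·r_cx·r_sx·r_cs)/(1 − r_cs²)], and n·R² is referred
to a χ²(2) distribution for the p-value. R is non-negative by construction;
the sign of the relationship is carried exclusively by the slope. A fit is
significant when p < 0.05 and the slope is non-zero.

**Two levels of analysis.** The group-level fit pools one (position, mean
phase) point per subject-channel, restricted to channels with a significant
Rayleigh test (p < 0.05), unweighted; both electrodes of a row contribute
separate points at the same x. The subject-level fit uses the raw phase of
every coupling event with no Rayleigh gating (floor of 10 samples,
configurable); its R is expectedly lower because raw phases spread around
the line that the mean phases sit on. Phase-position plots duplicate every
point at φ and φ + 2π so circular values near the wrap read sensibly on a
linear axis.

## Cohort statistics

Per-subject metrics (slope, R, significance) are joined to age, sex, and
recording group and analyzed with OLS: metric ~ predictor + total phase
count + group, with reference levels F (sex) and EMU (group). The count
covariate absorbs the wide variation in coupling-event counts between
subjects. When the slope is the outcome, only significant fits enter. The
reported model R is the multiple correlation √R² of the adjusted model.
Significance proportions in the youngest vs oldest age quartile (sample
quantiles, linear interpolation; boundaries inclusive) are compared with a
2×2 Pearson chi-square without continuity correction.

## Synthetic-data generator

Overnight clinical EEG cohorts are rarely public, so the package ships two
seeded generators that impose the statistical structure the pipeline
estimates, making every stage testable by parameter recovery.

The **phase-level generator** draws, for each channel at position x,
von Mises phases with mean φ₀ + a·x and concentration κ (`numpy.inf` is the
documented noiseless sentinel: phases exactly at the mean). Defaults: slope
−0.9 rad/unit, φ₀ = 2.7 (placing the central row's preferred phase near 0,
the SO peak), κ = 2, 150 events/channel, the 13 parasagittal channels.

The **signal-level generator** synthesizes each channel as an SO cosine
(default 0.8 Hz, 75 µV) plus 1/f (pink) background noise (default 15 µV SD;
white noise optional) plus Hann-windowed spindle bursts (default 13 Hz,
25 µV, 1.0 s) whose centers are placed, by rejection sampling over SO
cycles, at times where the channel's own SO phase equals a von Mises draw
around that channel's preferred phase; within-channel overlap is forbidden,
and the feasible event rate is capped at one event per two SO cycles
(exceeding it raises a generation error). Default event rate 4/min; a 45-min
recording at 128 Hz is the standard test condition. Artifact segments
(high-voltage square pulses > 400 µV, flat stretches, 30–50 Hz myogenic
bursts) are injected on request, the hypnogram marks the span N2/N3, and the
ground truth (per-event intervals, injected phases, per-channel preferred
phases) is returned and serializable to JSON alongside EDF signals and a CSV
hypnogram.

Two generator choices deserve emphasis:

* **Partial inter-channel SO coherence.** Each channel's SO carries a random
  phase offset and a small (±3%) frequency jitter, both seeded and
  switchable off. A perfectly identical SO on all channels would be
  annihilated exactly by the common-average montage and cancel in bipolar
  derivations, making those montages untestable; partially coherent SO — the
  realistic regime — leaves all montages estimable. Ground-truth coupling is
  always defined against the channel's own local SO phase, so this choice
  does not touch the phase-position model.
* **Uniform SO topography.** SO amplitude and phase structure carry no
  systematic AP gradient (offsets are random, not position-ordered). One
  consequence: a contaminated reference electrode (a neck-style channel
  carrying posterior SO) adds a fixed, random, zero-mean-across-channels
  phase rotation per channel when subtracted — it degrades the
  circular-linear R but does not systematically flatten the slope. A
  systematic slope attenuation under a posterior reference, as seen in real
  data, requires SO phase topography that the generator deliberately does
  not model.

What passing tests on this synthetic data do **not** show: robustness to
real sleep macroarchitecture (cycles, arousals, REM), to spindle density or
SO amplitude gradients across the scalp, to traveling-wave SO phase
topography, or to realistic artifact morphologies. The generator validates
the estimator chain, not the neurophysiology.

## Numerical conventions and degenerate inputs

Phases are wrapped to (−π, π]. All filters are zero-phase (forward-backward)
4th-order Butterworth cascades. Resampling uses polyphase filtering on the
rational rate ratio. Zero-variance usable signal raises a degenerate-signal
error (z-scores undefined); all-identical positions raise an
unidentifiable-slope error; fits below the sample floor, group fits with
fewer than 3 Rayleigh-surviving points or fewer than 2 subjects, and empty
phase sets raise insufficient-data errors; a rank-deficient cohort design
raises a collinearity error. Recordings shorter than one 5-s window yield an
empty artifact mask with a warning. All randomness flows from explicit
integer seeds; identical configuration and seed reproduce outputs
bit-identically.

## Known limitations

* **Peak-time phase jitter.** The SO phase is read at the spindle peak,
  defined as the argmax of the 100-ms-smoothed wavelet power. On synthetic
  bursts in 1/f noise the argmax wanders ~40–60 ms RMS across the flat top
  of the burst envelope, which at 0.8 Hz translates to ~0.2–0.3 rad RMS of
  per-event phase error against the injected targets — an order of magnitude
  above the ~0.06 rad RMS fidelity of the phase extraction itself. The
  error is zero-mean, so slope and offset estimates are unaffected beyond
  variance; per-event phase readings are not trustworthy below ~0.3 rad.
* **Detector false positives.** At the 2σ run threshold the primary detector
  fires occasionally on 1/f noise alone (see above); downstream statistics
  tolerate this because spurious phases are uniform.
* **Problem sizes.** The standard verification sizes are a 45-min 13-channel
  recording for end-to-end recovery, 200 simulated subjects (150
  phases/position) for phase-level recovery, and 1000 replicates for
  Rayleigh calibration; these were chosen as the smallest sizes at which the
  Monte-Carlo bands in the test suite are decisive.
* The cohort module fits fixed-effects OLS only; longitudinal or
  mixed-effects structures are out of scope, as are scalp topographic
  interpolation, left-right analyses, sleep staging, and source modeling.
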