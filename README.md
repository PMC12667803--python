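# sophase

Spindle–slow-oscillation coupling and anterior-posterior **phase precession**
analysis for NREM-sleep scalp EEG.

Sleep spindles (brief 11–16 Hz bursts) preferentially occur at particular
phases of the slow oscillation (SO, 0.5–2 Hz), and that preferred phase is
not uniform across the scalp: it advances systematically from anterior to
posterior electrode positions. `sophase` implements the full analysis chain
that quantifies this organization — preprocessing and montage re-referencing
of multichannel EEG, artifact and sleep-stage masking, wavelet-based spindle
detection, slow-wave detection, Hilbert SO-phase extraction at spindle
peaks, Rayleigh-gated circular statistics, and circular-linear regression of
phase on electrode position — together with a seeded synthetic-EEG generator
so that every stage is verifiable by parameter recovery without any clinical
data.

It is intended for sleep-EEG researchers who want a reproducible,
config-driven pipeline from EDF + hypnogram to precession fits, and for
methodologists who want the circular-linear machinery (Kempter-style slope
fit, Berens-style circular-linear correlation) as tested library functions.

## The model

The 13 parasagittal 10-20 electrodes are grouped into five anterior-posterior
rows ({Fp1,Fp2}→1, {F3,Fz,F4}→2, {C3,Cz,C4}→3, {P3,Pz,P4}→4, {O1,O2}→5);
adjacent rows are one *position unit* apart, 20% of the nasion–inion
distance. For phases φⱼ at positions xⱼ, the precession line φ = φ₀ + a·x is
fit by maximizing the mean resultant length of the residuals,

    R(a) = (1/n) · | Σⱼ exp(i(φⱼ − a·xⱼ)) | ,        φ₀ = arg Σⱼ exp(i(φⱼ − â·xⱼ)),

equivalent to minimizing the summed circular distances between the data and
the line. Strength and significance come from the circular-linear
correlation R (built from the Pearson correlations of cos φ and sin φ with
x), with n·R² referred to χ²(2). A fit is significant at p < 0.05 with a
non-zero slope; the slope carries the sign (R is non-negative by
construction). Group-level fits pool per-subject channel mean phases gated
by the Rayleigh test; subject-level fits use all raw event phases ungated.

## Worked example

Simulate a 10-minute, 13-channel recording with an imposed coupling slope of
−0.9 rad/unit (the generator default) and push it through the full pipeline:

```python
from sophase.pipeline import RunConfig, run_subject
from sophase.precession import slope_to_degrees

cfg = RunConfig(subject_id="demo", synth={"duration": 600.0}, seed=7,
                montage="as_recorded")
res = run_subject(cfg, write=False)
fit = res["fit"]
print(f"spindles detected : {len(res['spindles'])}")
print(f"phase samples     : {fit.n}")
print(f"slope             : {fit.slope_a:+.3f} rad/unit "
      f"({slope_to_degrees(fit.slope_a):+.1f} deg/unit)")
print(f"circular-linear R : {fit.corr_R:.3f}")
print(f"p-value           : {fit.p_value:.3g}")
print(f"significant       : {fit.significant}")
```

prints

```
spindles detected : 514
phase samples     : 514
slope             : -0.886 rad/unit (-50.8 deg/unit)
circular-linear R : 0.711
p-value           : 3.21e-57
significant       : True
```

The detector found the 514 injected spindle bursts; the fitted slope
recovers the imposed −0.9 rad (≈ −51°) of SO-phase advance per electrode
row, and the relationship is highly significant — each row posterior, the
spindles sit about 51° earlier on the SO cycle.

The same analysis is available from the shell. `sophase simulate` writes an
EDF, hypnogram CSV and ground-truth JSON; `sophase fit` runs the pipeline
from a YAML config (and can render the doubled phase-position plot);
`sophase sensitivity` sweeps montage × detector × phase-source variants;
`sophase cohort` runs the demographic regressions and the age-quartile
chi-square on a cohort CSV.

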