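# flyrhythm

Circadian rhythm analysis for *Drosophila* behavioral screens: locomotor
rhythmicity and free-running period by χ² periodogram, behavioral phase
(eduction profiles, light-pulse phase shifts, evening phase under
temperature cycles, anticipation scores), damped-cosinor period estimation
for luciferase reporters, batch-stratified RNAi-screen hit-calling, and
2^−ΔΔCt qPCR quantification — plus synthetic-data generators with known
ground truth for every stage, so the whole pipeline is testable without any
external download.

It is written for chronobiologists running activity-monitor screens: people
who need per-fly periods and rhythmicity calls from Trikinetics-style
monitor files, screen-wide hit lists that respect RNAi-collection and driver
batch effects, and phase quantification that is deterministic rather than
read off a plot by eye.

## The core statistics

**Rhythmicity / period.** For a trial period of P analysis bins, the window
is folded into P phase columns (means M_c over n_c values, grand mean M̄):

    Qp(P) = N · Σ_c n_c (M_c − M̄)² / Σ_i (x_i − M̄)²,

compared against the χ²(P−1) quantile at 1−α. The peak of Qp above the
significance line gives the period; *power* (excess at the peak) and *width*
(supra-threshold span in hours) define rhythmicity: power > 20 and
width > 1.5 h, strict.

**Phase.** Profiles are folded average days; the phase marker is the argmax
of a 4 h centred circular moving average. Light-pulse shift =
peak(unpulsed) − peak(pulsed), positive = advance; evening phase relative to
an internal control is negative when advanced. Anticipation scores: percent
of ZT17.5–23.5 activity inside ZT20.5–23.5 (morning), of ZT5.5–11.5 inside
ZT8.5–11.5 (evening).

**Luciferase.** y(t) = M + A·e^(−γt)·cos(2π(t−φ)/τ), multi-start nonlinear
least squares over the first 48 h of constant darkness.

**Screen.** Lines stratified by collection × driver (TRiP / VDRC / 40D-KK,
the latter never pooled); a hit deviates from its stratum mean by more than
2 stratum SD, strictly.

**qPCR.** Livak comparative Ct with reference-gene normalization, calibrator
referencing, optional group-mean rescaling, and standard-curve efficiency QC
(E = 10^(−1/slope) − 1).

See `docs/methods.md` for assumptions, defaults, and known limitations.

## Worked example

```python
import flyrhythm as fr

control = fr.simulate_locomotor_cohort(
    fr.LocomotorScenario(n_flies=16, tau_h=24.8, amplitude=0.8,
                         genotype="driver_control", seed=101))
knockdown = fr.simulate_locomotor_cohort(
    fr.LocomotorScenario(n_flies=16, tau_h=23.6, amplitude=0.8,
                         genotype="knockdown", seed=102))

results = [fr.chi_squared_periodogram(rec) for rec in control + knockdown]
print(fr.summarize_genotypes(results).round(2).to_string(index=False))
```

prints

```
      genotype  n  pct_rhythmic  period_mean  period_sem  power_mean  power_sem
driver_control 16         100.0        24.75        0.03      264.74       4.22
     knockdown 16         100.0        23.60        0.02      254.81       8.19
```

Each cohort free-runs at its programmed period (24.8 h vs 23.6 h — a slow
driver control against a fast knockdown); the periodogram recovers both to
within the 0.1 h grid, every fly clears the power/width rhythmicity
criteria, and the knockdown runs ~1.2 h faster — the kind of period
shortening a screen flags. A single fly's call looks like:

```python
r = results[0]
r.peak_period, round(r.power, 1), r.width, r.rhythmic
# (24.7, 285.0, 2.3, True)
```

The same flow works from the shell on monitor files or tidy CSVs:

```sh
flyrhythm simulate --scenario scenario.yaml --out activity.csv
flyrhythm periodogram activity.csv --per-fly per_fly.csv --summary summary.csv
flyrhythm screen-hits records.csv --hits-out hits.csv
```

The numbered scripts under `analysis/` run the full study workflow —
simulate cohorts, estimate periods, call screen hits, quantify phase,
fit luciferase traces, quantify qPCR — each printing what it found and
writing tables under `results/`.

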