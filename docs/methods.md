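# Methods

`flyrhythm` implements the quantitative workflow of a Drosophila circadian
RNAi screen: rhythmicity and free-running period from beam-break activity,
behavioral phase under light pulses and temperature cycles, molecular-rhythm
period from luciferase reporters, batch-stratified hit-calling, and relative
transcript quantification from qPCR — together with synthetic-data
generators that carry known ground truth for every stage.

## Rhythmicity and period: the χ² periodogram

For a trial period of P analysis bins, all N window bins are folded into P
circadian phase columns. With column means M_c over the n_c values landing
in column c and grand mean M̄,

    Qp(P) = N · Σ_c n_c (M_c − M̄)² / Σ_i (x_i − M̄)².

Under the no-rhythm null this one-way fold-and-variance statistic is
approximately χ² with P − 1 degrees of freedom, so each trial period carries
a significance line at the 1 − α quantile (α = 0.05 by default). The trial
grid is 18–30 h in 0.1 h steps; raw counts are first aggregated to 0.1 h
analysis bins so every grid period is an integer number of bins. Missing
bins (monitor-status errors) are excluded from the column means, the grand
mean and the denominator — never imputed.

Every bin enters at every trial period, with unequal column counts
(n_c ∈ {K, K+1}). The alternative — truncating to K complete cycles — was
implemented and rejected: with a 5-day window it hands trial periods that
divide the window length up to one extra cycle of data, and because Qp
scales with the amount of data used, that produces a deterministic
one-grid-step bias toward those periods (e.g. every fly of a τ = 24.1 h
cohort peaking at 24.0 h).

The **peak** is the global maximum of Qp − sig_line over the grid, **power**
is that excess at the peak, and **width** is the contiguous grid span around
the peak where Qp exceeds the line (number of supra-threshold grid points ×
0.1 h). A fly is **rhythmic** when power > 20 and width > 1.5 h, both strict
inequalities. These power/width definitions are conventions: the screen
software whose criteria they mirror does not publish its internals, so the
thresholds are validated by calibration — amplitude-0 (Poisson) flies are
called rhythmic well under 5% of the time, and the joint power/width
criterion is conservative because broad noise excursions above the line are
rare.

Genotype summaries report n, % rhythmic, and period/power mean ± SEM over
rhythmic flies, matching screen-table structure.

## Behavioral phase

**Eduction** folds selected protocol days at the cycle length (24 h) and
averages per phase bin over flies × days, SEM over per-fly profiles; all
flies are included regardless of rhythmicity. Profiles are indexed by
left-edge bin time; ZT0 is lights-on, and under a temperature cycle the
cryophase→thermophase transition; CT0 is the projected lights-on of the last
entrained day.

**Peak phase** is the argmax of a centred circular moving average (default
4 h; even windows widened by one bin to stay centred), with ties resolved to
the earliest time in the search window. Flat profiles carry an
undefined-phase flag.

**Light-pulse shifts** are peak(unpulsed) − peak(pulsed) on group-averaged
smoothed profiles over the same post-pulse DD days, mapped circularly into
(−12, +12]; positive = advance. **Evening phase under temperature cycles**
is peak(test) − peak(internal control) with the search restricted to cycle
hours 6–18 (inside the thermophase, avoiding transition startle); negative =
advanced. **Anticipation scores**: morning = percent of ZT17.5–23.5 activity
inside ZT20.5–23.5; evening = percent of ZT5.5–11.5 activity inside
ZT8.5–11.5; window edges snap to bin edges and a uniform profile scores
exactly 50%.

## Luciferase periods: damped cosinor

Traces are fitted over the first 48 h of constant darkness (reporter
oscillations damp quickly) with

    y(t) = M + A·e^(−γt)·cos(2π(t − φ)/τ),

by multi-start nonlinear least squares: τ initialised on a 0.5 h grid over
[18, 30] h, γ ∈ {0, 0.02, 0.05}/h, with (M, A, φ) from a linear sub-fit at
each start; the best starts are refined by a trust-region solver.
Internally the oscillation uses in-phase/quadrature coefficients, so A ≥ 0
and φ ∈ [0, τ) are canonical by construction. The mesor does not damp and no
baseline trend is removed by default (a linear detrend is available); fits
are flagged non-converged on flat traces or when τ lands on a bound.
Genotype period is the mean over converged wells (one well = one trace).

## Screen hit-calling

Lines are stratified by RNAi collection × driver: TRiP, VDRC (GD and non-40D
KK pooled), and 40D-KK as its own stratum — never pooled, because the 40D
landing-site insertion lengthens period non-specifically with the PDF-neuron
driver. Stratum mean and SD are computed over line-level mean periods
(sample SD, n−1); a line is a hit when its mean deviates from the stratum
mean by more than 2 SD, strictly, in either direction. Lines whose flies
were all arrhythmic are reported as rhythmicity candidates, not period hits.
Under a pure normal null the expected pass rate is 2Φ(−2) ≈ 4.55%; injected
outliers inflate their stratum's SD and so deflate it — the cutoff is
deliberately self-masking, as the hand-arithmetic example in the tests
shows.

## qPCR quantification

Technical replicates are averaged on the Ct scale; ΔCt = mean target Ct −
mean reference Ct (RpL32 by default) per sample; ΔΔCt references a
calibrator sample; relative expression is 2^−ΔΔCt. An optional post-hoc
rescaling divides each target's series by the mean over a named group (e.g.
all knockdown timepoints) so control and knockdown share one scale.
Replicate dispersion above 0.5 cycles is flagged. Standard-curve efficiency,
E = 10^(−1/slope) − 1 from the least-squares line of Ct vs log₁₀ input, is a
QC report (pass for E ∈ [0.9, 1.1]), not a Pfaffl-style correction.

## Synthetic data: what it emulates, and what it does not

Activity is an inhomogeneous Poisson process. The circadian rate template is
two wrapped-Gaussian bumps on the circular day — morning (ZT0) and evening
(ZT11), evening-dominant (morning weight 0.5, since free-running morning
activity is low-amplitude and an equal-height pair would make the
activity-peak marker ambiguous), default width 2 h FWHM, modulation depth
(amplitude) 0–1 over a baseline of 2 counts/min. Entrained days follow the
24 h zeitgeber with ×0.4 night/cryophase suppression and 2-bin startle
bursts at transitions; DD days free-run at the fly's τ, with an optional
phase offset at release emulating a light-pulse shift. Arrhythmic flies have
zero modulation depth but normal baseline (they are not dead). Temperature
cycles (12:12, 29/20 °C) run in darkness.

Screen records draw per-fly periods around base 24.1 h with the observed
batch structure (TRiP −0.3 h vs VDRC; +0.8 h driver lengthening; +0.6 h for
40D-KK lines under the PDF driver), a per-line background spread
(SD 0.4 h) shared across a line's flies and drivers, and per-fly noise
(SD 0.5 h, 8 flies/cross). An injected hit *places* a line at its programmed
displacement (the effect replaces the background draw), so ground truth is
blurred only by fly sampling. Luciferase traces are exact damped cosines
plus Gaussian noise; qPCR tables encode fold changes as Ct differences
against a noiseless-mean reference.

Not emulated: mechanistic clock dynamics (transcription–translation loops),
temperature compensation, activity-bout ultradian structure, death/escape
artifacts, plate spatial effects, or amplification-efficiency differences
between primer pairs. Passing recovery tests therefore shows the estimators
are correct and calibrated for Poisson-noise, template-shaped data — not
that they are robust to every pathology of real monitor data.

## Experiment scenarios used by the analyses and acceptance run

- Period recovery: 16-fly DD cohorts, amplitude 0.8, 5 DD days, τ ∈
  {23.6, 24.1, 24.8, 26.0} h (the genotype periods of the screen
  follow-up); median |τ̂ − τ| ≤ 0.1 h (the grid step) with ≥ 90% rhythmic.
- Null calibration: 200 amplitude-0 flies; 1000-line single-stratum screens
  for the 2-SD pass rate, plus a 1000-line screen with 10 hits at ±3 set-SD.
- Light-pulse shift: 32 flies/group (two pooled 16-fly runs) over 6 DD days,
  with a 4 h-FWHM evening bout: a 2 h bout under a 4 h moving average leaves
  a flat-topped plateau whose argmax wanders by ±0.3 h, while DD has no
  masking so the broader bout costs nothing.
- Temperature-cycle phase: 32 flies/group, TC days 7–10, evening peaks at
  ZT10 (control) and ZT7.5 (knockdown). Peaks are placed inside the
  thermophase because a bump abutting the cryophase onset is truncated by
  masking and the moving-average argmax drags it up to ~1 h early —
  a known limitation of peak-phase estimation near masking transitions.
- Luciferase: 0.5 h sampling, 48 h window, γ = 0.02–0.03/h, 10% amplitude
  noise; median |τ̂ − τ| ≤ 0.3 h over 100 replicates.

## Numerical choices

Grid arithmetic rounds trial periods to 10 decimals and requires each to be
an integer number of analysis bins. A constant or empty analysis window
returns a flagged non-rhythmic result, never a crash; zero anticipation
denominators and flat smoothed profiles carry undefined flags. Circular
differences map into (−cycle/2, +cycle/2], keeping +12 h for exact
half-cycle oppositions. Cosinor refinement uses trust-region least squares
with 1e-14 tolerances from the 8 best grid starts; the returned RSS never
exceeds any initialisation's. Result tables render floats with Python's
shortest lossless representation so CSV round-trips are exact.

## Known limitations

- Peak-phase estimates are biased near masking transitions (above); phase
  work should keep peaks inside the unmasked half-cycle or treat results
  near transitions as qualitative.
- Periodogram peak localisation is limited by the 0.1 h grid and, for broad
  waveforms over few cycles, by plateau width; five DD days resolve ~0.1 h.
- The 2-SD rule is self-masking under heavy hit contamination and performs
  no multiple-testing correction — by design, as a screen triage rule.
- Stratum SDs are computed over line means; with very few flies per cross
  the sampling noise inflates them.
- ANOVA/post-hoc comparisons of group differences are out of scope and left
  to standard statistical packages.
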