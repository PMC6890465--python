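"""Synthetic datasets with known ground truth for every pipeline stage.

Four generators emulate the data the analysis modules consume:

* :func:`simulate_locomotor_cohort` — per-fly beam-break counts from an
  inhomogeneous Poisson process.  The circadian rate template is the sum of
  two wrapped-Gaussian bumps (morning and evening) on the circular day,
  giving the crepuscular profile typical of *Drosophila*.  Entrained days
  (LD, or a temperature cycle run in darkness) follow the 24 h zeitgeber with
  multiplicative night/cryophase suppression and 2-bin startle bursts at the
  transitions; in constant darkness each fly free-runs at its own period.
  Arrhythmic flies have zero modulation depth (they keep moving — they are
  not dead).
* :func:`simulate_luciferase_series` — an exponentially damped cosine plus
  Gaussian noise.
* :func:`simulate_screen_dataset` — line-level period screens with the batch
  structure seen in RNAi collections: a wild-type base period of 24.1 h,
  TRiP lines 0.3 h shorter than VDRC, a dominant +0.8 h driver lengthening,
  a +0.6 h 40D-insertion effect with the PDF-neuron driver, plus injected
  hits of known effect size.
* :func:`simulate_qpcr_plate` — triplicate Ct values whose target/reference
  differences encode programmed fold changes.

All generators are deterministic under a fixed seed and attach their ground
truth to the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ActivityRecording, label_protocol

__all__ = [
    "LocomotorScenario",
    "ScreenScenario",
    "simulate_locomotor_cohort",
    "simulate_luciferase_series",
    "simulate_screen_dataset",
    "simulate_qpcr_plate",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class LocomotorScenario:
    """Ground-truth description of one simulated locomotor cohort.

    The default protocol is 3 days of 12:12 LD entrainment followed by 5 days
    of DD; setting ``tc_days`` inserts a 12:12 thermophase/cryophase
    temperature cycle (29/20 °C, run in darkness) after the LD block.
    ``phase_offset_h`` shifts the free-running phase at DD release (positive
    = advance), which is how a light-pulse-shifted cohort is emulated.
    """

    n_flies: int = 16
    tau_h: float = 24.0
    amplitude: float = 0.8  # modulation depth in [0, 1]
    morning_peak_h: float = 0.0
    evening_peak_h: float = 11.0
    morning_weight: float = 0.5  # morning bump height relative to evening
    peak_fwhm_h: float = 2.0
    baseline_rate: float = 2.0  # counts per raw bin
    arrhythmic_fraction: float = 0.0
    masking_night_factor: float = 0.4
    masking_startle: float = 3.0  # startle burst, × baseline, 2 bins
    ld_days: int = 3
    tc_days: int = 0
    dd_days: int = 5
    entrain_period_h: float = 24.0
    tc_warm_c: float = 29.0
    tc_cool_c: float = 20.0
    phase_offset_h: float = 0.0
    bin_length_min: float = 1.0
    genotype: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.amplitude <= 1:
            raise ValueError("amplitude must lie in [0, 1]")
        if not 0 <= self.arrhythmic_fraction <= 1:
            raise ValueError("arrhythmic fraction must lie in [0, 1]")
        if not 18 <= self.tau_h <= 32:
            raise ValueError("tau must lie in [18, 32] h")
        if self.n_flies < 1 or self.baseline_rate <= 0:
            raise ValueError("need >= 1 fly and a positive baseline rate")


def _bimodal_template(scenario: LocomotorScenario):
    """Peak-normalised two-bump circadian template on [0, 24)."""
    sigma = scenario.peak_fwhm_h / _FWHM_TO_SIGMA

    weights = (
        (scenario.morning_peak_h, scenario.morning_weight),
        (scenario.evening_peak_h, 1.0),
    )

    def bumps(phi):
        out = np.zeros_like(phi, dtype=float)
        for mu, w in weights:
            d = np.abs((phi - mu + 12.0) % 24.0 - 12.0)
            out += w * np.exp(-0.5 * (d / sigma) ** 2)
        return out

    peak = bumps(np.arange(0, 24, 0.005)).max()

    def template(phi):
        return bumps(phi) / peak

    return template


def simulate_locomotor_cohort(scenario: LocomotorScenario) -> list[ActivityRecording]:
    """Simulate one cohort; each recording's ``meta`` holds its truth."""
    rng = np.random.default_rng(scenario.seed)
    template = _bimodal_template(scenario)
    bin_h = scenario.bin_length_min / 60.0
    bins_per_day = int(round(24.0 / bin_h))
    phases = []
    if scenario.ld_days:
        phases.append(("LD", scenario.ld_days))
    if scenario.tc_days:
        phases.append(("TC", scenario.tc_days))
    if scenario.dd_days:
        phases.append(("DD", scenario.dd_days))
    n_days = scenario.ld_days + scenario.tc_days + scenario.dd_days
    n_bins = n_days * bins_per_day
    t = (np.arange(n_bins) + 0.5) * bin_h  # rate evaluated at bin centres

    day = np.arange(n_bins) // bins_per_day + 1
    is_ld = day <= scenario.ld_days
    is_tc = (day > scenario.ld_days) & (day <= scenario.ld_days + scenario.tc_days)
    is_dd = ~is_ld & ~is_tc
    zt = t % scenario.entrain_period_h
    daytime = zt < scenario.entrain_period_h / 2.0

    light = is_ld & daytime
    temperature = np.full(n_bins, 25.0)
    temperature[is_tc & daytime] = scenario.tc_warm_c
    temperature[is_tc & ~daytime] = scenario.tc_cool_c

    # night / cryophase masking and transition startle apply on entrained days
    entrained = is_ld | is_tc
    suppress = entrained & ~daytime
    transition = np.zeros(n_bins, dtype=bool)
    switches = np.flatnonzero(np.diff(daytime.astype(int)) != 0) + 1
    for s in switches:
        if entrained[s]:
            transition[s : s + 2] = True

    t_release = (scenario.ld_days + scenario.tc_days) * 24.0
    n_arr = int(round(scenario.arrhythmic_fraction * scenario.n_flies))
    arrhythmic = np.zeros(scenario.n_flies, dtype=bool)
    arrhythmic[rng.permutation(scenario.n_flies)[:n_arr]] = True

    out = []
    for i in range(scenario.n_flies):
        amp = 0.0 if arrhythmic[i] else scenario.amplitude
        phi = np.where(
            is_dd,
            ((t - t_release) * 24.0 / scenario.tau_h + scenario.phase_offset_h) % 24.0,
            zt * 24.0 / scenario.entrain_period_h,
        )
        rate = scenario.baseline_rate * (1.0 + amp * template(phi))
        rate = np.where(suppress, rate * scenario.masking_night_factor, rate)
        rate = np.where(
            transition, rate + scenario.masking_startle * scenario.baseline_rate, rate
        )
        counts = rng.poisson(rate)
        rec = ActivityRecording(
            fly_id=f"{scenario.genotype}:{i + 1:03d}",
            genotype=scenario.genotype,
            bin_length_min=scenario.bin_length_min,
            counts=counts,
            light=light,
            temperature=temperature,
            meta=dict(
                tau_h=scenario.tau_h,
                amplitude=amp,
                arrhythmic=bool(arrhythmic[i]),
                phase_offset_h=scenario.phase_offset_h,
                evening_peak_h=scenario.evening_peak_h,
                morning_peak_h=scenario.morning_peak_h,
            ),
        )
        label_protocol(rec, phases)
        out.append(rec)
    return out


def simulate_luciferase_series(
    tau_h: float = 24.0,
    damping: float = 0.02,
    mesor: float = 100.0,
    amplitude: float = 30.0,
    acrophase_h: float = 6.0,
    noise_sd: float = 0.0,
    sampling_min: float = 30.0,
    duration_h: float = 48.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Damped cosine ``mesor + amplitude*exp(-damping*t)*cos(2pi(t-phi)/tau)``
    plus Gaussian noise.  Returns ``(time_h, signal, truth)``."""
    if tau_h <= 0:
        raise ValueError("tau must be positive")
    if damping < 0:
        raise ValueError("damping must be non-negative")
    if duration_h < 2 * tau_h:
        raise ValueError("duration must cover at least two periods")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 1e-9, sampling_min / 60.0)
    y = mesor + amplitude * np.exp(-damping * t) * np.cos(
        2 * np.pi * (t - acrophase_h) / tau_h
    )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    truth = dict(
        tau_h=tau_h,
        damping=damping,
        mesor=mesor,
        amplitude=amplitude,
        acrophase_h=acrophase_h,
        noise_sd=noise_sd,
    )
    return t, y, truth


@dataclass
class ScreenScenario:
    """Batch-structured synthetic period screen with injected hits.

    Per-fly periods are ``base + collection offset + driver offset
    (+ 40D offset where applicable) + line background N(0, line_sd)
    + hit effect + N(0, per_fly_sd)``; the line background is shared by all
    flies and drivers of a line, emulating the line-to-line genetic spread
    that makes screen histograms much wider than the SEM of one cross.
    ``injected_hits`` maps line ids (``"<collection>-NNNN"``) to period
    effects in hours, applied with every driver.  An injected effect *places*
    the line at that displacement from the stratum mean: it replaces the
    line's background draw, so only fly-sampling noise blurs the known
    ground-truth position.
    """

    n_lines: dict = field(
        default_factory=lambda: {
            "TRiP": 60,
            "VDRC-GD": 60,
            "VDRC-KK": 60,
            "VDRC-KK-40D": 20,
        }
    )
    base_period_h: float = 24.1
    collection_offsets: dict = field(
        default_factory=lambda: {
            "TRiP": -0.3,
            "VDRC-GD": 0.0,
            "VDRC-KK": 0.0,
            "VDRC-KK-40D": 0.0,
        }
    )
    driver_offsets: dict = field(
        default_factory=lambda: {"TD2": 0.8, "PD2": 0.8, "+": 0.0}
    )
    offset_40d: dict = field(
        default_factory=lambda: {"TD2": 0.0, "PD2": 0.6, "+": 0.0}
    )
    drivers: tuple = ("TD2", "PD2")
    injected_hits: dict = field(default_factory=dict)
    per_fly_sd: float = 0.5
    line_sd: float = 0.4
    flies_per_cross: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flies_per_cross < 1:
            raise ValueError("need at least one fly per cross")
        if self.per_fly_sd < 0 or self.line_sd < 0:
            raise ValueError("SDs must be non-negative")

    def line_ids(self, collection: str) -> list[str]:
        return [f"{collection}-{i:04d}" for i in range(1, self.n_lines[collection] + 1)]

    def set_sd(self) -> float:
        """SD of null line means: line background plus fly-sampling noise."""
        return float(
            np.hypot(self.line_sd, self.per_fly_sd / np.sqrt(self.flies_per_cross))
        )


def simulate_screen_dataset(
    scenario: ScreenScenario,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Line × driver screen records plus the truth table of injected hits.

    Returns ``(records, truth)``; ``records`` follows the screen-module
    schema, ``truth`` holds ``line_id, collection, delta_tau, is_hit``.
    """
    rng = np.random.default_rng(scenario.seed)
    unknown = set(scenario.injected_hits) - {
        lid for coll in scenario.n_lines for lid in scenario.line_ids(coll)
    }
    if unknown:
        raise ValueError(f"injected hits reference unknown lines: {sorted(unknown)}")
    rec_rows, truth_rows = [], []
    for coll in scenario.n_lines:
        for lid in scenario.line_ids(coll):
            dtau = float(scenario.injected_hits.get(lid, 0.0))
            background = rng.normal(0.0, scenario.line_sd) if scenario.line_sd else 0.0
            if dtau != 0.0:
                background = 0.0  # the injected effect is the line's displacement
            truth_rows.append(
                dict(line_id=lid, collection=coll, delta_tau=dtau, is_hit=dtau != 0.0)
            )
            for driver in scenario.drivers:
                mu = (
                    scenario.base_period_h
                    + scenario.collection_offsets[coll]
                    + scenario.driver_offsets[driver]
                    + (scenario.offset_40d[driver] if coll == "VDRC-KK-40D" else 0.0)
                    + background
                    + dtau
                )
                periods = mu + rng.normal(0.0, scenario.per_fly_sd, scenario.flies_per_cross)
                rec_rows.append(
                    dict(
                        line_id=lid,
                        gene=lid,
                        collection=coll,
                        driver=driver,
                        n_total=scenario.flies_per_cross,
                        n_rhythmic=scenario.flies_per_cross,
                        mean_period=float(periods.mean()),
                        sem=float(periods.std(ddof=1) / np.sqrt(periods.size))
                        if periods.size > 1
                        else float("nan"),
                        mean_power=float("nan"),
                    )
                )
    return pd.DataFrame(rec_rows), pd.DataFrame(truth_rows)


def simulate_qpcr_plate(
    fold_changes: dict,
    ct_noise_sd: float = 0.0,
    reference_ct: float = 15.0,
    target_base_ct: float = 22.0,
    n_replicates: int = 3,
    reference_target: str = "RpL32",
    calibrator_sample: str = "calibrator",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy Ct table encoding programmed fold changes.

    ``fold_changes`` maps ``(target, timepoint)`` to the expression ratio
    relative to the calibrator; each combination becomes one sample
    ``"<target>@CT<timepoint>"`` with ``n_replicates`` target and reference
    Cts, and one calibrator sample per target carries ratio 1.  Returns
    ``(ct_table, truth)``.
    """
    if any(r <= 0 for r in fold_changes.values()):
        raise ValueError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []

    def add_sample(sample, timepoint, target, ratio):
        truth_rows.append(
            dict(sample=sample, timepoint=timepoint, target=target, ratio=ratio)
        )
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            rows.append(
                dict(
                    sample=sample,
                    timepoint=timepoint,
                    target=target,
                    replicate=rep,
                    ct=target_base_ct - np.log2(ratio) + noise,
                )
            )
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
            rows.append(
                dict(
                    sample=sample,
                    timepoint=timepoint,
                    target=reference_target,
                    replicate=rep,
                    ct=reference_ct + noise,
                )
            )

    targets = sorted({tg for tg, _ in fold_changes})
    for target in targets:
        add_sample(calibrator_sample, "cal", target, 1.0)
    for (target, timepoint), ratio in fold_changes.items():
        add_sample(f"{target}@CT{timepoint}", timepoint, target, float(ratio))
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
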