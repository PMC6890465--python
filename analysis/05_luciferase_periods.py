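"""Damped-cosinor period estimation of reporter bioluminescence.

Emulates a plate of control wells (tau 24.9 h) and knockdown wells
(tau 23.6 h, i.e. ~1.3 h shorter) with rapidly damping oscillations and 10%
measurement noise, fits each well over the first two days of constant
darkness, and summarizes genotype periods over converged wells.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from flyrhythm import fit_damped_cosinor, simulate_luciferase_series, summarize_wells

OUT = Path(__file__).resolve().parents[1] / "results"

PLATE = {"control": (24.9, 12, 500), "knockdown": (23.6, 12, 600)}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows, summaries = [], []
    for genotype, (tau, n_wells, seed0) in PLATE.items():
        fits = {}
        for w in range(n_wells):
            t, y, _ = simulate_luciferase_series(
                tau_h=tau, damping=0.03, mesor=120.0, amplitude=40.0,
                noise_sd=4.0, duration_h=72.0, seed=seed0 + w,
            )
            fit = fit_damped_cosinor(t, y, window_h=48.0)
            fits[f"{genotype}:{w + 1:02d}"] = fit
            rows.append(
                dict(genotype=genotype, well=w + 1, tau_true=tau,
                     period=fit.period, damping=fit.damping,
                     amplitude=fit.amplitude, converged=fit.converged)
            )
        s = summarize_wells(fits)
        s.insert(0, "genotype", genotype)
        s["tau_true"] = tau
        summaries.append(s)
    per_well = pd.DataFrame(rows)
    summary = pd.concat(summaries, ignore_index=True)
    per_well.to_csv(OUT / "luciferase_per_well.csv", index=False)
    summary.to_csv(OUT / "luciferase_summary.csv", index=False)
    print(summary.round(3).to_string(index=False))
    diff = (
        summary.set_index("genotype").loc["control", "period_mean"]
        - summary.set_index("genotype").loc["knockdown", "period_mean"]
    )
    print(
        f"\nknockdown wells run {diff:.2f} h faster than control wells "
        "(programmed 1.3 h), from two days of damping oscillations."
    )
    worst = (per_well["period"] - per_well["tau_true"]).abs().max()
    print(f"largest single-well period error: {worst:.2f} h at 10% noise")


if __name__ == "__main__":
    main()
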