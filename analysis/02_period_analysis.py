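"""Free-running period and rhythmicity of the simulated cohorts.

Runs the chi-squared periodogram on each genotype's DD days and reports the
screen-style summary (n, % rhythmic, period mean +/- SEM, power mean +/- SEM),
comparing recovered periods against the programmed ground truth.
"""

from pathlib import Path

import pandas as pd

from flyrhythm import (
    LocomotorScenario,
    chi_squared_periodogram,
    simulate_locomotor_cohort,
    summarize_genotypes,
    write_results_table,
)

OUT = Path(__file__).resolve().parents[1] / "results"

GENOTYPES = {
    "TD2_control": dict(tau_h=24.8, seed=101),
    "TD2_PsiRNAiKK": dict(tau_h=23.6, seed=102),
    "PD2_PsiRNAiKK": dict(tau_h=24.7, seed=103),
    "w1118": dict(tau_h=24.1, seed=104),
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    results = []
    for name, params in GENOTYPES.items():
        cohort = simulate_locomotor_cohort(
            LocomotorScenario(
                n_flies=16, amplitude=0.8, arrhythmic_fraction=0.15,
                genotype=name, **params,
            )
        )
        results += [chi_squared_periodogram(rec) for rec in cohort]
    write_results_table(results, OUT / "periodogram_per_fly.csv")
    summary = summarize_genotypes(results)
    summary["tau_true_h"] = [GENOTYPES[g]["tau_h"] for g in summary["genotype"]]
    summary["period_err_h"] = summary["period_mean"] - summary["tau_true_h"]
    summary.to_csv(OUT / "periodogram_summary.csv", index=False)
    with pd.option_context("display.width", 120):
        print(summary.round(3).to_string(index=False))
    worst = summary["period_err_h"].abs().max()
    print(
        f"\nlargest genotype-mean period error: {worst:.3f} h; "
        "arrhythmic-simulated flies are excluded from period averages by the "
        "power/width call, mirroring screen practice."
    )


if __name__ == "__main__":
    main()
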