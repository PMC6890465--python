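"""Batch-stratified 2-SD hit-calling on a full synthetic screen.

Simulates a screen with the real batch structure (TRiP 0.3 h shorter than
VDRC, +0.8 h driver lengthening, +0.6 h 40D effect under the PDF driver) and
12 injected hits of +/-3 set-SD, then calls hits per collection x driver
stratum and scores recovery and false positives against the truth table.
Also writes the 0.1 h period histogram per stratum.
"""

from pathlib import Path

from flyrhythm import ScreenScenario, call_hits, compute_cutoffs, period_histogram, simulate_screen_dataset

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    base = ScreenScenario(seed=2019)
    d = 3 * base.set_sd()
    hits = {
        "TRiP-0007": d, "TRiP-0031": -d,
        "VDRC-GD-0005": d, "VDRC-GD-0042": -d,
        "VDRC-KK-0011": d, "VDRC-KK-0049": d,
        "VDRC-KK-40D-0003": -d, "VDRC-KK-40D-0015": d,
        "TRiP-0055": d, "VDRC-GD-0020": d,
        "VDRC-KK-0033": -d, "VDRC-KK-40D-0019": d,
    }
    scenario = ScreenScenario(injected_hits=hits, seed=2019)
    records, truth = simulate_screen_dataset(scenario)
    cutoffs = compute_cutoffs(records)
    calls = call_hits(records, cutoffs)
    records.to_csv(OUT / "screen_records.csv", index=False)
    cutoffs.to_csv(OUT / "screen_cutoffs.csv", index=False)
    calls.to_csv(OUT / "screen_hits.csv", index=False)
    period_histogram(records).to_csv(OUT / "screen_histogram_01h.csv", index=False)

    print(cutoffs.round(3).to_string(index=False))
    merged = calls.merge(truth, on="line_id")
    hit_lines = merged[merged["is_hit"]]
    recovered = hit_lines.groupby("line_id")["passes"].any()
    fp = merged[~merged["is_hit"]]["passes"].mean()
    print(
        f"\ninjected hits recovered (any driver): {int(recovered.sum())}/"
        f"{recovered.size}; false-positive rate among nulls {100 * fp:.2f}%."
    )
    print(
        "the null rate sits below the two-sided 2-SD expectation (4.55%) "
        "because the injected outliers inflate their strata's SDs - the same "
        "self-masking the hand-arithmetic cutoff example demonstrates; the "
        "pure-null calibration is isolated in the acceptance run."
    )
    print(
        "note the TRiP strata sit ~0.3 h below VDRC and the 40D-KK x PD2 "
        "stratum ~0.6 h above VDRC x PD2, so pooling them would distort "
        "every cutoff - the reason for stratified calling."
    )


if __name__ == "__main__":
    main()
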