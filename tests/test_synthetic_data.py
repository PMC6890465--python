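"""Generators: determinism, closed-form identities, construction checks."""

import numpy as np
import pytest

from flyrhythm import (
    LocomotorScenario,
    ScreenScenario,
    delta_delta_ct,
    fit_damped_cosinor,
    simulate_locomotor_cohort,
    simulate_luciferase_series,
    simulate_qpcr_plate,
    simulate_screen_dataset,
)


def test_locomotor_determinism_and_integrality():
    sc = LocomotorScenario(n_flies=4, seed=42)
    a = simulate_locomotor_cohort(sc)
    b = simulate_locomotor_cohort(sc)
    for ra, rb in zip(a, b):
        np.testing.assert_array_equal(ra.counts, rb.counts)
        assert ra.counts.dtype.kind == "i" and (ra.counts >= 0).all()


def test_amplitude_zero_is_homogeneous_poisson():
    sc = LocomotorScenario(n_flies=6, amplitude=0.0, ld_days=0, dd_days=5, seed=1)
    cohort = simulate_locomotor_cohort(sc)
    pooled = np.concatenate([r.counts for r in cohort])
    assert pooled.mean() == pytest.approx(sc.baseline_rate, rel=0.02)
    # index of dispersion ~ 1 for Poisson
    assert pooled.var() / pooled.mean() == pytest.approx(1.0, rel=0.05)


def test_arrhythmic_fraction_zeroes_modulation_only():
    sc = LocomotorScenario(n_flies=10, arrhythmic_fraction=0.3, seed=5)
    cohort = simulate_locomotor_cohort(sc)
    flags = [r.meta["arrhythmic"] for r in cohort]
    assert sum(flags) == 3
    arr = [r for r in cohort if r.meta["arrhythmic"]][0]
    assert arr.meta["amplitude"] == 0.0
    assert arr.counts.sum() > 0  # arrhythmic, not dead


def test_scenario_validation():
    with pytest.raises(ValueError):
        LocomotorScenario(amplitude=1.5)
    with pytest.raises(ValueError):
        LocomotorScenario(tau_h=10.0)
    with pytest.raises(ValueError):
        LocomotorScenario(arrhythmic_fraction=-0.1)


def test_luciferase_exact_cosine_and_envelope():
    t, y, truth = simulate_luciferase_series(
        tau_h=24.0, damping=0.0, mesor=50.0, amplitude=10.0, acrophase_h=0.0,
        noise_sd=0.0, sampling_min=30.0, duration_h=48.0,
    )
    expected = 50.0 + 10.0 * np.cos(2 * np.pi * t / 24.0)
    np.testing.assert_allclose(y, expected, atol=1e-12)

    # envelope at 48 h: amplitude * exp(-0.03*48) = amplitude * e^-1.44
    t, y, _ = simulate_luciferase_series(
        damping=0.03, acrophase_h=0.0, noise_sd=0.0, duration_h=48.0
    )
    assert y[t == 48.0][0] - 100.0 == pytest.approx(30.0 * np.exp(-1.44), rel=1e-12)


def test_luciferase_validation():
    with pytest.raises(ValueError):
        simulate_luciferase_series(tau_h=-1.0)
    with pytest.raises(ValueError):
        simulate_luciferase_series(duration_h=30.0)  # < 2 periods


def test_screen_offsets_deterministic_when_sd_vanishes():
    sc = ScreenScenario(per_fly_sd=1e-12, line_sd=0.0, seed=0)
    records, truth = simulate_screen_dataset(sc)
    by = records.set_index(["collection", "driver", "line_id"])["mean_period"].sort_index()
    assert by.loc[("TRiP", "TD2")].unique() == pytest.approx(24.1 - 0.3 + 0.8)
    assert by.loc[("VDRC-GD", "PD2")].unique() == pytest.approx(24.1 + 0.8)
    assert by.loc[("VDRC-KK-40D", "PD2")].unique() == pytest.approx(24.1 + 0.8 + 0.6)
    assert by.loc[("VDRC-KK-40D", "TD2")].unique() == pytest.approx(24.1 + 0.8)
    assert not truth["is_hit"].any()


def test_screen_collection_background_difference_matches_construction():
    sc = ScreenScenario(per_fly_sd=0.3, seed=3)
    records, _ = simulate_screen_dataset(sc)
    td2 = records[records["driver"] == "TD2"]
    trip = td2[td2["collection"] == "TRiP"]["mean_period"]
    vdrc = td2[td2["collection"].isin(["VDRC-GD", "VDRC-KK"])]["mean_period"]
    sem = np.hypot(trip.sem(), vdrc.sem())
    assert trip.mean() - vdrc.mean() == pytest.approx(-0.3, abs=4 * sem)


def test_screen_injected_hits_recorded_in_truth():
    sc = ScreenScenario(injected_hits={"TRiP-0001": 3.0}, seed=1)
    _, truth = simulate_screen_dataset(sc)
    assert truth.set_index("line_id").loc["TRiP-0001", "is_hit"]
    with pytest.raises(ValueError, match="unknown lines"):
        simulate_screen_dataset(ScreenScenario(injected_hits={"nope-1": 1.0}))


def test_qpcr_plate_identities_with_zero_noise():
    table, truth = simulate_qpcr_plate({("tim-cold", 15): 2.0}, ct_noise_sd=0.0)
    rel = delta_delta_ct(table, calibrator="calibrator")
    sample = rel[rel["sample"] == "tim-cold@CT15"]
    # ratio 2 -> target Ct exactly one cycle below the calibrator's
    cal_ct = table[(table["sample"] == "calibrator") & (table["target"] == "tim-cold")]["ct"].mean()
    tgt_ct = table[(table["sample"] == "tim-cold@CT15") & (table["target"] == "tim-cold")]["ct"].mean()
    assert cal_ct - tgt_ct == pytest.approx(1.0)
    assert sample["rel_expr"].iloc[0] == pytest.approx(2.0)
    assert truth.shape[0] == 2  # calibrator + one sample


def test_qpcr_determinism_and_finite_cts():
    a, _ = simulate_qpcr_plate({("psi", 3): 0.25}, ct_noise_sd=0.3, seed=9)
    b, _ = simulate_qpcr_plate({("psi", 3): 0.25}, ct_noise_sd=0.3, seed=9)
    assert a.equals(b)
    assert np.isfinite(a["ct"]).all()
    with pytest.raises(ValueError, match="positive"):
        simulate_qpcr_plate({("psi", 3): -1.0})
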