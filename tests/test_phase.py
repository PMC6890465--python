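"""Eduction, peak phase, phase shifts, anticipation scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flyrhythm import (
    EductionProfile,
    LocomotorScenario,
    anticipation_scores,
    circular_difference,
    educe_profile,
    peak_phase,
    phase_shift,
    relative_evening_phase,
    simulate_locomotor_cohort,
    smooth_profile,
)

from conftest import make_recording


def profile_from(values, bin_h=0.1, cycle_h=24.0):
    values = np.asarray(values, dtype=float)
    return EductionProfile(cycle_h, bin_h, values, np.zeros_like(values), 1, ())


# ---------------------------------------------------------------------------
# eduction


def test_flat_single_fly_profile_is_constant_with_zero_sem():
    rec = make_recording(np.full(1200, 7), phases=[("DD", 5)])
    prof = educe_profile([rec], "DD")
    np.testing.assert_allclose(prof.mean, 7.0)
    np.testing.assert_allclose(prof.sem, 0.0)


def test_identical_flies_have_zero_sem():
    recs = [
        make_recording(np.tile(np.arange(240), 5), phases=[("DD", 5)], fly_id=f"f{i}")
        for i in range(2)
    ]
    prof = educe_profile(recs, "DD")
    np.testing.assert_allclose(prof.sem, 0.0, atol=1e-12)


def test_eduction_recovers_programmed_bimodal_peaks():
    sc = LocomotorScenario(
        n_flies=24, ld_days=4, dd_days=0, morning_peak_h=2.0, evening_peak_h=11.0, seed=8
    )
    cohort = simulate_locomotor_cohort(sc)
    prof = educe_profile(cohort, "LD")
    sm = smooth_profile(prof.mean, int(round(1.0 / prof.bin_h)))  # light smoothing
    morning = peak_phase(prof, smoothing_h=2.0, search_window=(0.5, 6.0)).peak_time
    evening = peak_phase(prof, smoothing_h=2.0, search_window=(6.0, 12.0)).peak_time
    assert morning == pytest.approx(2.0, abs=0.5)
    assert evening == pytest.approx(11.0, abs=0.5)
    assert sm.size == prof.mean.size


def test_empty_selection_is_an_error():
    rec = make_recording(np.full(1200, 3), phases=[("DD", 5)])
    with pytest.raises(ValueError, match="empty"):
        educe_profile([rec], "DD", days=[9])
    with pytest.raises(ValueError, match="no recordings"):
        educe_profile([], "DD")


# ---------------------------------------------------------------------------
# peak phase


def triangle(center, width=3.0, bin_h=0.1):
    t = np.arange(0, 24, bin_h)
    d = np.abs((t - center + 12) % 24 - 12)
    return np.maximum(0.0, 1 - d / width)


def test_triangular_bump_peak_found_at_center():
    prof = profile_from(triangle(11.0))
    est = peak_phase(prof)
    assert est.peak_time == pytest.approx(11.0)
    assert not est.tie and not est.undefined


def test_one_bin_spike_suppressed_by_smoothing():
    vals = triangle(11.0)
    spike = vals.copy()
    spike[30] += 5.0  # huge single-bin spike at ZT3
    assert peak_phase(profile_from(spike)).peak_time == pytest.approx(
        peak_phase(profile_from(vals)).peak_time, abs=0.2
    )


def test_two_equal_maxima_tie_resolves_to_earliest():
    vals = triangle(5.0) + triangle(17.0)
    est = peak_phase(profile_from(vals))
    assert est.peak_time == pytest.approx(5.0)
    assert est.tie


def test_flat_profile_has_undefined_phase():
    est = peak_phase(profile_from(np.full(240, 2.0)))
    assert est.undefined and np.isnan(est.peak_time)


def test_smoothing_idempotent_on_constants_and_mass_preserving():
    const = smooth_profile(np.full(240, 3.3), 40)
    np.testing.assert_allclose(const, 3.3)
    vals = triangle(7.0)
    np.testing.assert_allclose(smooth_profile(vals, 40).sum(), vals.sum(), rtol=1e-12)


@given(shift_bins=st.integers(min_value=0, max_value=239))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_circular_shift_equivariance(shift_bins):
    """Rolling the profile by k hours moves the peak by k (mod cycle)."""
    vals = triangle(11.0)
    rolled = np.roll(vals, shift_bins)
    a = peak_phase(profile_from(vals)).peak_time
    b = peak_phase(profile_from(rolled)).peak_time
    assert circular_difference(b, a) == pytest.approx(
        circular_difference(shift_bins * 0.1, 0.0), abs=1e-9
    )


# ---------------------------------------------------------------------------
# phase shift / relative phase


def test_phase_shift_of_identical_groups_is_exactly_zero():
    cohort = simulate_locomotor_cohort(LocomotorScenario(n_flies=4, seed=3))
    assert phase_shift(cohort, cohort) == 0.0


def test_light_pulse_advance_and_delay_recovered():
    base = dict(n_flies=16, ld_days=5, dd_days=6)
    unpulsed = simulate_locomotor_cohort(LocomotorScenario(**base, seed=11))
    advanced = simulate_locomotor_cohort(
        LocomotorScenario(**base, phase_offset_h=2.0, seed=12)
    )
    delayed = simulate_locomotor_cohort(
        LocomotorScenario(**base, phase_offset_h=-1.5, seed=13)
    )
    assert phase_shift(advanced, unpulsed) == pytest.approx(2.0, abs=0.25)
    assert phase_shift(delayed, unpulsed) == pytest.approx(-1.5, abs=0.25)


def test_relative_evening_phase_conventions():
    ctrl = profile_from(triangle(12.0))
    same = relative_evening_phase(ctrl, ctrl)
    assert same == 0.0
    advanced = profile_from(triangle(9.5))
    assert relative_evening_phase(advanced, ctrl) == pytest.approx(-2.5)
    # half-cycle offset maps into (-12, +12] with the positive sign kept
    a = profile_from(triangle(6.0, width=2.0))
    b = profile_from(triangle(18.0, width=2.0))
    d = circular_difference(
        peak_phase(a).peak_time, peak_phase(b).peak_time
    )
    assert d == pytest.approx(12.0)


def test_undefined_peaks_raise():
    flat = profile_from(np.full(240, 1.0))
    bump = profile_from(triangle(10.0))
    with pytest.raises(ValueError, match="undefined"):
        relative_evening_phase(flat, bump)


# ---------------------------------------------------------------------------
# anticipation


def test_uniform_activity_scores_fifty_percent():
    for bin_h in (0.1, 0.25, 0.5):
        prof = profile_from(np.full(int(24 / bin_h), 4.2), bin_h=bin_h)
        sc = anticipation_scores(prof)
        assert sc.morning == pytest.approx(50.0)
        assert sc.evening == pytest.approx(50.0)


def test_all_activity_in_late_window_scores_hundred():
    vals = np.zeros(240)
    t = np.arange(0, 24, 0.1)
    vals[(t >= 20.5) & (t < 23.5)] = 3.0
    sc = anticipation_scores(profile_from(vals))
    assert sc.morning == pytest.approx(100.0)


def test_linear_ramp_scores_seventy_five_percent():
    """Bin-averaged ramp rising from 0 across ZT17.5-23.5 -> 75% analytically."""
    t = np.arange(0, 24, 0.1)
    vals = np.where((t >= 17.5) & (t < 23.5), (t + 0.05) - 17.5, 0.0)
    sc = anticipation_scores(profile_from(vals))
    assert sc.morning == pytest.approx(75.0)


def test_zero_denominator_flags_undefined():
    sc = anticipation_scores(profile_from(np.zeros(240)))
    assert sc.undefined_morning and sc.undefined_evening
    assert np.isnan(sc.morning)


def test_scores_bounded(rng):
    for _ in range(20):
        vals = rng.random(240) * 10
        sc = anticipation_scores(profile_from(vals))
        assert 0.0 <= sc.morning <= 100.0
        assert 0.0 <= sc.evening <= 100.0
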