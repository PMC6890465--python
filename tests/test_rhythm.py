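"""Chi-squared periodogram: oracle equivalence, invariances, edge cases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from flyrhythm import RunConfig, call_rhythmicity, chi_squared_periodogram, summarize_genotypes
from flyrhythm.rhythm import PeriodogramResult

from conftest import make_recording


def brute_force_qp(x, n_cols):
    """Independent fold-and-variance computation of the periodogram statistic.

    Deliberately naive: explicit loops over cycles and phase columns.
    """
    x = [float(v) for v in x]
    columns = [[] for _ in range(n_cols)]
    for i, v in enumerate(x):
        columns[i % n_cols].append(v)
    grand = sum(x) / len(x)
    num = 0.0
    for vals in columns:
        mean_c = sum(vals) / len(vals)
        num += len(vals) * (mean_c - grand) ** 2
    num *= len(x)
    den = sum((v - grand) ** 2 for v in x)
    return num / den


def test_qp_matches_brute_force_on_random_instances(rng):
    """Qp agrees with an independent brute-force fold to < 1e-12 relative."""
    for _ in range(100):
        n = int(rng.integers(20, 201))
        x = rng.poisson(8.0, n).astype(float)
        if np.ptp(x) == 0:
            x[0] += 1
        hi = (n - 2) // 2
        for n_cols in rng.integers(4, hi + 1, size=3):
            n_cols = int(n_cols)
            period_h = round(n_cols * 0.1, 10)
            rec = make_recording(x, bin_length_min=6.0)
            cfg = RunConfig(
                period_min_h=period_h,
                period_max_h=round(period_h + 0.1, 10),
                period_step_h=0.1,
                analysis_bin_h=0.1,
            )
            res = chi_squared_periodogram(rec, cfg, window=None)
            expected = brute_force_qp(x, n_cols)
            assert res.qp[0] == pytest.approx(expected, rel=1e-12)


def test_peak_and_rhythmicity_on_noiseless_square_wave(square_wave_recording):
    res = chi_squared_periodogram(square_wave_recording)
    assert res.peak_period == pytest.approx(24.0)
    assert res.rhythmic
    assert res.power > 20 and res.width > 1.5


@given(scale=st.floats(min_value=0.1, max_value=50.0))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_qp_scale_invariance(scale):
    """Multiplying all counts by a constant leaves the Qp spectrum unchanged."""
    base = np.tile(np.r_[np.full(120, 9), np.full(120, 2)], 5)
    rec_a = make_recording(base, phases=[("DD", 5)])
    rec_b = make_recording(np.round(base * 7).astype(int), phases=[("DD", 5)])
    ra = chi_squared_periodogram(rec_a)
    rb = chi_squared_periodogram(rec_b)
    # integer scaling (×7) is exact; the hypothesis scale exercises floats below
    np.testing.assert_allclose(ra.qp, rb.qp, rtol=1e-10)
    x = np.tile(np.r_[np.full(120, 9.0), np.full(120, 2.0)], 5)
    assert brute_force_qp(x, 240) == pytest.approx(
        brute_force_qp(x * scale, 240), rel=1e-9
    )


def test_sig_line_monotone_in_period():
    """The chi-squared significance line is non-decreasing in trial period."""
    day = np.r_[np.full(120, 10), np.zeros(120)]
    rec = make_recording(np.tile(day, 5), phases=[("DD", 5)])
    res = chi_squared_periodogram(rec)
    assert np.all(np.diff(res.sig_line) >= 0)


def test_constant_window_returns_undefined_not_crash():
    rec = make_recording(np.full(1200, 4), phases=[("DD", 5)])
    res = chi_squared_periodogram(rec)
    assert res.undefined and not res.rhythmic
    assert np.isnan(res.peak_period)
    assert not call_rhythmicity(res)


def test_window_shorter_than_two_cycles_is_an_error():
    rec = make_recording(np.random.default_rng(0).poisson(5, 400), phases=[("DD", 2)])
    # 2 days = 48 h < 2 cycles of the 30 h longest trial period
    with pytest.raises(ValueError, match="2 cycles"):
        chi_squared_periodogram(rec)


def test_missing_bins_are_excluded_not_imputed():
    """Masking a stretch of bins must change n_bins_used, not crash or zero-fill."""
    day = np.r_[np.full(120, 10), np.zeros(120)]
    counts = np.tile(day, 5)
    missing = np.zeros(counts.size, dtype=bool)
    missing[300:360] = True
    rec = make_recording(counts, phases=[("DD", 5)], missing=missing)
    res = chi_squared_periodogram(rec)
    assert res.n_bins_used == counts.size - 60
    assert res.peak_period == pytest.approx(24.0)
    assert res.rhythmic


@pytest.mark.parametrize(
    "power,width,expected",
    [(25.0, 2.0, True), (20.0, 2.0, False), (50.0, 1.0, False), (20.0001, 1.5001, True)],
)
def test_rhythmicity_thresholds_are_strict(power, width, expected):
    res = PeriodogramResult(
        fly_id="f",
        genotype="g",
        trial_periods=np.array([24.0]),
        qp=np.array([100.0]),
        df=np.array([239.0]),
        sig_line=np.array([70.0]),
        peak_period=24.0,
        power=power,
        width=width,
        rhythmic=False,
        undefined=False,
        n_bins_used=1200,
        bin_h=0.1,
    )
    assert call_rhythmicity(res) is expected


def test_genotype_summary_structure(square_wave_recording):
    flat = make_recording(np.full(1200, 4), phases=[("DD", 5)], genotype="flat")
    results = [
        chi_squared_periodogram(square_wave_recording),
        chi_squared_periodogram(flat),
    ]
    df = summarize_genotypes(results)
    assert set(df.columns) >= {"genotype", "n", "pct_rhythmic", "period_mean", "period_sem"}
    row = df.set_index("genotype")
    assert row.loc["test", "pct_rhythmic"] == 100.0
    assert row.loc["flat", "pct_rhythmic"] == 0.0
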