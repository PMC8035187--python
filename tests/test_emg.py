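"""EMG measurement operations: rectification, averaging, baseline-to-peak
amplitudes, normalised metrics, RDD curves, and the H/M slope."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reflexmorph.emg import (
    RDDCurve,
    analyze_cohort,
    average_sweeps,
    find_threshold,
    hm_ratio,
    hm_slope,
    measure_amplitude,
    percent_response,
    raw_average,
    rdd_curve,
    rectify,
)
from reflexmorph.errors import (
    ConfigurationError,
    ThresholdNotFoundError,
    UndefinedMetricError,
)
from reflexmorph.protocol import EMGSweep, StimulusProtocol, WaveWindows
from reflexmorph.synthdata import make_emg_cohort, wave_template

from conftest import TEST_FS, make_group_preset


def _sweep(samples, fs=1000.0, c=2, t=5):
    samples = np.asarray(samples, dtype=float)
    return EMGSweep(samples, fs, c, t)


class TestRectify:
    def test_example(self):
        s = _sweep([0.0, 0.0, -1.0, 2.0, 0.0, 0.5, 0.0])
        assert np.array_equal(rectify(s).samples, [0.0, 0.0, 1.0, 2.0, 0.0, 0.5, 0.0])

    @given(st.lists(st.floats(-10, 10), min_size=6, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_idempotent_and_nonnegative(self, vals):
        s = _sweep(vals, c=1, t=4)
        once = rectify(s)
        twice = rectify(once)
        assert np.array_equal(once.samples, twice.samples)
        assert (once.samples >= 0).all()


class TestAverageSweeps:
    def test_single_sweep_is_own_rectification(self):
        s = _sweep([-1.0, 2.0, -3.0, 0.0, 1.0, -1.0])
        assert np.array_equal(average_sweeps([s]).samples, np.abs(s.samples))

    def test_pointwise_mean(self):
        a = _sweep([1.0] * 6)
        b = _sweep([3.0] * 6)
        assert np.array_equal(average_sweeps([a, b]).samples, [2.0] * 6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            average_sweeps([_sweep([1.0] * 6), _sweep([1.0] * 7)])

    def test_onset_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            average_sweeps([_sweep([1.0] * 6, c=1), _sweep([1.0] * 6, c=2)])

    def test_noise_suppression_matches_folded_normal(self, rng):
        """Rectified average of noisy template copies converges to the
        folded-normal mean E|s+n|; residual RMS scales like sigma/sqrt(n)."""
        from scipy.stats import norm

        fs, sigma, n_copies = 20_000.0, 0.1, 30
        template = 1.5 * wave_template(fs)
        base = np.zeros(400)
        base[100 : 100 + template.size] = template
        sweeps = [
            _sweep(base + rng.normal(0, sigma, base.size), fs=fs, c=50, t=300)
            for _ in range(n_copies)
        ]
        avg = average_sweeps(sweeps).samples
        s = np.abs(base)
        folded_mean = sigma * math.sqrt(2 / math.pi) * np.exp(-(base**2) / (2 * sigma**2)) \
            + base * (1 - 2 * norm.cdf(-np.abs(base) / sigma)) * np.sign(base + 1e-300)
        folded_mean = np.abs(folded_mean)
        rms = np.sqrt(np.mean((avg - folded_mean) ** 2))
        assert rms < 2 * sigma / math.sqrt(n_copies)


class TestMeasureAmplitude:
    def test_flat_zero_signal(self):
        s = _sweep(np.zeros(100), fs=1000.0, c=20, t=60)
        assert measure_amplitude(s, (0.0, 10.0), (-10.0, 0.0), 20) == 0.0

    def test_baseline_subtracted(self):
        samples = np.full(100, 0.1)
        samples[30] = 1.1
        s = _sweep(samples, fs=1000.0, c=20, t=60)
        assert measure_amplitude(s, (0.0, 20.0), (-10.0, 0.0), 20) == pytest.approx(1.0)

    def test_empty_window_rejected(self):
        s = _sweep(np.zeros(100), fs=1000.0, c=20, t=60)
        with pytest.raises(ConfigurationError):
            measure_amplitude(s, (5.0, 5.0), (-10.0, 0.0), 20)

    def test_generator_roundtrip_noise_free(self, protocol_10ms):
        """On a noise-free sweep the measured H amplitude equals the preset
        amplitude to 1e-6 relative."""
        preset = make_group_preset(percent_h=73.0, percent_m=55.0)
        cohort = make_emg_cohort(preset, protocol_10ms, 1, seed=0)
        sweep = rectify(cohort["a000"][10.0][0])
        w = WaveWindows()
        h_c = measure_amplitude(sweep, w.h_window_ms, w.baseline_window_ms, sweep.control_onset_idx)
        h_t = measure_amplitude(
            sweep, w.h_window_ms, w.baseline_window_ms, sweep.test_onset_idx,
            baseline_onset_idx=sweep.control_onset_idx,
        )
        assert h_c == pytest.approx(preset.h_amp_mv, rel=1e-6)
        assert h_t == pytest.approx(preset.h_amp_mv * 0.73, rel=1e-6)


class TestNormalisedMetrics:
    @pytest.mark.parametrize(
        "test,control,expect",
        [(0.798, 1.0, 79.8), (2.0, 2.0, 100.0), (0.0, 2.0, 0.0)],
    )
    def test_percent_response(self, test, control, expect):
        assert percent_response(test, control) == pytest.approx(expect)

    def test_percent_response_undefined(self):
        with pytest.raises(UndefinedMetricError):
            percent_response(1.0, 0.0)

    @pytest.mark.parametrize("h,m,expect", [(1.0, 1.0, 1.0), (1.32, 1.0, 1.32), (0.0, 2.0, 0.0)])
    def test_hm_ratio(self, h, m, expect):
        assert hm_ratio(h, m) == pytest.approx(expect)

    def test_hm_ratio_undefined(self):
        with pytest.raises(UndefinedMetricError):
            hm_ratio(1.0, 0.0)


def _threshold_series(fractions, fs=20_000.0, n_sweeps=10):
    """Synthetic single-pulse series with exact response fractions."""
    template = wave_template(fs)
    onset = 100
    series = {}
    for intensity, frac in fractions.items():
        sweeps = []
        n_resp = int(round(frac * n_sweeps))
        for k in range(n_sweeps):
            samples = np.zeros(600)
            if k < n_resp:
                start = onset + 20
                samples[start : start + template.size] = 1.0 * template
            sweeps.append(EMGSweep(samples, fs, onset, 599))
        series[intensity] = sweeps
    return series


class TestFindThreshold:
    def test_interpolated_example(self):
        series = _threshold_series({0.6: 0.0, 1.0: 0.5, 1.4: 1.0})
        res = find_threshold(series, 0.2)
        assert res.threshold_T == 1.0
        assert res.monotonic

    def test_all_responding_returns_lowest(self):
        series = _threshold_series({0.6: 1.0, 1.0: 1.0, 1.4: 1.0})
        assert find_threshold(series, 0.2).threshold_T == 0.6

    def test_not_found(self):
        series = _threshold_series({0.6: 0.0, 1.0: 0.2})
        with pytest.raises(ThresholdNotFoundError):
            find_threshold(series, 0.2)

    def test_nonmonotonic_flagged(self):
        series = _threshold_series({0.6: 0.3, 0.8: 0.1, 1.0: 0.8})
        res = find_threshold(series, 0.2)
        assert not res.monotonic
        assert res.threshold_T == 1.0


class TestRDDCurve:
    def _metrics(self, rows):
        return pd.DataFrame(rows, columns=["animal_id", "interval_ms", "percent_h",
                                           "percent_m", "hm_ratio"])

    def test_single_animal_sem_undefined(self):
        df = self._metrics([("a", 10.0, 50.0, 60.0, 1.0)])
        curve = rdd_curve(df)
        assert curve.table.loc[10.0, "percent_h_mean"] == 50.0
        assert np.isnan(curve.table.loc[10.0, "percent_h_sem"])

    def test_two_animal_mean_and_sem(self):
        df = self._metrics([("a", 10.0, 40.0, 60.0, 1.0), ("b", 10.0, 60.0, 60.0, 1.0)])
        curve = rdd_curve(df)
        assert curve.table.loc[10.0, "percent_h_mean"] == 50.0
        assert curve.table.loc[10.0, "percent_h_sem"] == pytest.approx(10.0)

    def test_missing_interval_logged(self):
        df = self._metrics(
            [("a", 10.0, 40.0, 60.0, 1.0), ("b", 10.0, 60.0, 60.0, 1.0),
             ("a", 100.0, 45.0, 55.0, 1.1)]
        )
        curve = rdd_curve(df)
        assert curve.exclusions == {100.0: ["b"]}
        assert curve.table.loc[100.0, "n_animals"] == 1


class TestHMSlope:
    def _curve(self, hm_by_iv):
        table = pd.DataFrame(
            {"interval_ms": list(hm_by_iv), "hm_ratio_mean": list(hm_by_iv.values())}
        ).set_index("interval_ms")
        return RDDCurve(group="g", table=table)

    def test_constant_ratio_slope_zero(self):
        assert hm_slope(self._curve({10.0: 1.1, 100.0: 1.1, 1000.0: 1.1})) == pytest.approx(0.0)

    def test_exact_log10_identity(self):
        c = self._curve({10.0: 1.0, 100.0: 2.0, 1000.0: 3.0})
        assert hm_slope(c, axis="log10") == pytest.approx(1.0)

    def test_too_few_intervals(self):
        with pytest.raises(ConfigurationError):
            hm_slope(self._curve({10.0: 1.0}))

    def test_invariant_under_amplitude_rescaling(self, protocol_10ms):
        """Scaling all waveform amplitudes leaves the ratio-based slope
        unchanged (to measurement precision)."""
        intervals = (10.0, 100.0, 1000.0)
        protocol = StimulusProtocol(interpulse_intervals_ms=intervals, sampling_rate_hz=TEST_FS)
        slopes = []
        for scale in (1.0, 3.0):
            preset = make_group_preset(
                percent_h=70.0, percent_m=55.0, intervals=intervals,
                m_amp_mv=2.0 * scale, h_amp_mv=1.6 * scale,
            )
            cohort = make_emg_cohort(preset, protocol, 2, seed=5)
            slopes.append(hm_slope(rdd_curve(analyze_cohort(cohort))))
        assert slopes[0] == pytest.approx(slopes[1], abs=1e-9)


class TestRecoveryInvariant:
    def test_large_cohort_recovery_all_intervals(self):
        """n=50 animals: recovered mean %H within 3 analytic SEs of the
        preset truth at every interval."""
        from reflexmorph.recovery import expected_se_emg

        preset = make_group_preset(
            percent_h=65.0, percent_m=55.0, intervals=(10.0, 100.0, 1000.0),
            noise_sd_mv=0.02, animal_sd_frac=0.25, m_animal_sd_frac=0.10,
        )
        protocol = StimulusProtocol(
            interpulse_intervals_ms=(10.0, 100.0, 1000.0), sampling_rate_hz=TEST_FS
        )
        metrics = analyze_cohort(make_emg_cohort(preset, protocol, 50, seed=17))
        for iv in protocol.interpulse_intervals_ms:
            est = metrics[metrics.interval_ms == iv].percent_h.mean()
            se = expected_se_emg(preset, "percent_h", iv, 50)
            assert abs(est - 65.0) < 3 * se
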