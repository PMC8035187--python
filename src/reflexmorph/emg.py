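"""Paired-pulse EMG quantification: M-wave and H-reflex amplitudes, rate-
dependent depression (RDD) metrics, and the H/M regression slope.

Measurement pipeline per animal and interpulse interval:

1. rectify every sweep (absolute value), then average pointwise;
2. measure the control-pulse and test-pulse M and H amplitudes
   baseline-to-peak on the rectified average, inside configurable windows
   relative to each stimulus onset (baseline taken before the control
   pulse);
3. %H-reflex = test H / control H x 100, %M-wave analogous; the H/M ratio
   uses the *test-pulse* amplitudes only.

At interpulse intervals short enough that the test-pulse windows overlap
the tail of the control response, the test epoch is instead cleaned by
subtracting a control-complex template (the raw average of a clean,
long-interval recording of the same animal) from the raw sweep average
before rectification.  Whether subtraction was applied is flagged in the
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ReflexMorphError, ThresholdNotFoundError, UndefinedMetricError
from .protocol import EMGSweep, WaveWindows

__all__ = [
    "rectify",
    "average_sweeps",
    "raw_average",
    "measure_amplitude",
    "percent_response",
    "hm_ratio",
    "find_threshold",
    "analyze_interval",
    "analyze_cohort",
    "rdd_curve",
    "hm_slope",
    "ReflexAmplitudes",
    "ReflexMetrics",
    "RDDCurve",
    "ThresholdResult",
]


def rectify(sweep: EMGSweep) -> EMGSweep:
    """Full-wave rectification: every sample replaced by its absolute value."""
    return sweep.copy_with(np.abs(sweep.samples))


def _check_compatible(sweeps: list[EMGSweep]) -> None:
    if not sweeps:
        raise ConfigurationError("need at least one sweep")
    first = sweeps[0]
    for s in sweeps[1:]:
        if s.samples.shape != first.samples.shape:
            raise ConfigurationError("sweeps differ in length")
        if (
            s.sampling_rate_hz != first.sampling_rate_hz
            or s.control_onset_idx != first.control_onset_idx
            or s.test_onset_idx != first.test_onset_idx
        ):
            raise ConfigurationError("sweeps differ in sampling rate or stimulus onsets")


def average_sweeps(sweeps: list[EMGSweep]) -> EMGSweep:
    """Rectify each sweep, then average pointwise.  Onsets are preserved."""
    _check_compatible(sweeps)
    stacked = np.abs(np.stack([s.samples for s in sweeps]))
    return sweeps[0].copy_with(stacked.mean(axis=0))


def raw_average(sweeps: list[EMGSweep]) -> EMGSweep:
    """Pointwise average without rectification (for template subtraction)."""
    _check_compatible(sweeps)
    stacked = np.stack([s.samples for s in sweeps])
    return sweeps[0].copy_with(stacked.mean(axis=0))


def _window_indices(
    sweep: EMGSweep, window_ms: tuple[float, float], onset_idx: int
) -> slice:
    fs = sweep.sampling_rate_hz
    lo = onset_idx + int(round(window_ms[0] * 1e-3 * fs))
    hi = onset_idx + int(round(window_ms[1] * 1e-3 * fs))
    lo, hi = max(lo, 0), min(hi, sweep.samples.size)
    if hi <= lo:
        raise ConfigurationError(f"window {window_ms} ms is empty within the record")
    return slice(lo, hi)


def measure_amplitude(
    averaged: EMGSweep,
    window_ms: tuple[float, float],
    baseline_window_ms: tuple[float, float],
    onset_idx: int,
    baseline_onset_idx: int | None = None,
) -> float:
    """Baseline-to-peak amplitude: max inside the window minus the baseline
    mean, floored at zero (amplitudes on rectified averages are nonnegative).
    """
    if baseline_onset_idx is None:
        baseline_onset_idx = onset_idx
    w = _window_indices(averaged, window_ms, onset_idx)
    b = _window_indices(averaged, baseline_window_ms, baseline_onset_idx)
    return max(0.0, float(averaged.samples[w].max() - averaged.samples[b].mean()))


def percent_response(test_amp: float, control_amp: float) -> float:
    """Test amplitude as a percentage of the control amplitude."""
    if control_amp <= 0:
        raise UndefinedMetricError("percent response undefined for control amplitude <= 0")
    return test_amp / control_amp * 100.0


def hm_ratio(h_test_mv: float, m_test_mv: float) -> float:
    """H-reflex over M-wave amplitude, both from the test pulse."""
    if m_test_mv <= 0:
        raise UndefinedMetricError("H/M ratio undefined for M amplitude <= 0")
    return h_test_mv / m_test_mv


@dataclass
class ReflexAmplitudes:
    """Baseline-to-peak amplitudes (mV) of one averaged recording."""

    m_control_mv: float
    h_control_mv: float
    m_test_mv: float
    h_test_mv: float
    template_subtracted: bool = False

    def __post_init__(self) -> None:
        for v in (self.m_control_mv, self.h_control_mv, self.m_test_mv, self.h_test_mv):
            if v < 0:
                raise ConfigurationError("rectified amplitudes must be >= 0")


@dataclass
class ReflexMetrics:
    interval_ms: float
    percent_h: float
    percent_m: float
    hm_ratio: float  # NaN when the test M-wave is absent


def control_template(sweeps: list[EMGSweep], length_ms: float = 15.0) -> np.ndarray:
    """Raw-average control-complex epoch, from the control onset onward.

    Meaningful only when the epoch is not contaminated by the test response,
    i.e. when the recording's interpulse interval exceeds ``length_ms``.
    """
    avg = raw_average(sweeps)
    fs = avg.sampling_rate_hz
    start = avg.control_onset_idx
    stop = min(start + int(round(length_ms * 1e-3 * fs)), avg.samples.size)
    return avg.samples[start:stop].copy()


def _truncate_window(
    window_ms: tuple[float, float], limit_ms: float
) -> tuple[float, float]:
    """Clip a control-pulse window so it cannot reach the test response.

    If clipping would empty the window (possible only at very short
    intervals) the full window is kept instead.
    """
    lo, hi = window_ms
    hi_clipped = min(hi, limit_ms)
    return (lo, hi_clipped) if hi_clipped > lo else window_ms


def _template_amplitude(
    template: np.ndarray,
    fs: float,
    window_ms: tuple[float, float],
    baseline_mv: float,
) -> float:
    trace = np.abs(template)
    lo = max(0, int(round(window_ms[0] * 1e-3 * fs)))
    hi = min(trace.size, int(round(window_ms[1] * 1e-3 * fs)))
    if hi <= lo:
        raise ConfigurationError(f"window {window_ms} ms lies outside the template")
    return max(0.0, float(trace[lo:hi].max() - baseline_mv))


def analyze_interval(
    sweeps: list[EMGSweep],
    windows: WaveWindows = WaveWindows(),
    template: np.ndarray | None = None,
) -> ReflexAmplitudes:
    """Measure control and test M/H amplitudes for one interval's sweeps.

    Control-pulse windows are truncated at the test-pulse M-window start so
    the (undepressed) control measurement never picks up the test response;
    below the overlap-threshold interval the control amplitudes come from
    the clean control template instead, when one is available.
    """
    rect_avg = average_sweeps(sweeps)
    c_on, t_on = rect_avg.control_onset_idx, rect_avg.test_onset_idx
    interval_ms = rect_avg.interval_ms
    subtract = interval_ms < windows.overlap_threshold_ms and template is not None

    if subtract:
        baseline = float(
            rect_avg.samples[_window_indices(rect_avg, windows.baseline_window_ms, c_on)].mean()
        )
        fs = rect_avg.sampling_rate_hz
        m_c = _template_amplitude(template, fs, windows.m_window_ms, baseline)
        h_c = _template_amplitude(template, fs, windows.h_window_ms, baseline)
    else:
        guard_ms = interval_ms + windows.m_window_ms[0]
        m_c = measure_amplitude(
            rect_avg, _truncate_window(windows.m_window_ms, guard_ms),
            windows.baseline_window_ms, c_on,
        )
        h_c = measure_amplitude(
            rect_avg, _truncate_window(windows.h_window_ms, guard_ms),
            windows.baseline_window_ms, c_on,
        )

    if subtract:
        cleaned = raw_average(sweeps)
        samples = cleaned.samples.copy()
        stop = min(c_on + template.size, samples.size)
        samples[c_on:stop] -= template[: stop - c_on]
        cleaned = cleaned.copy_with(np.abs(samples))
        m_t = measure_amplitude(
            cleaned, windows.m_window_ms, windows.baseline_window_ms, t_on, baseline_onset_idx=c_on
        )
        h_t = measure_amplitude(
            cleaned, windows.h_window_ms, windows.baseline_window_ms, t_on, baseline_onset_idx=c_on
        )
    else:
        m_t = measure_amplitude(
            rect_avg, windows.m_window_ms, windows.baseline_window_ms, t_on, baseline_onset_idx=c_on
        )
        h_t = measure_amplitude(
            rect_avg, windows.h_window_ms, windows.baseline_window_ms, t_on, baseline_onset_idx=c_on
        )
    return ReflexAmplitudes(m_c, h_c, m_t, h_t, template_subtracted=subtract)


def _metrics_from_amplitudes(interval_ms: float, amp: ReflexAmplitudes) -> ReflexMetrics:
    return ReflexMetrics(
        interval_ms=interval_ms,
        percent_h=percent_response(amp.h_test_mv, amp.h_control_mv),
        percent_m=percent_response(amp.m_test_mv, amp.m_control_mv),
        hm_ratio=hm_ratio(amp.h_test_mv, amp.m_test_mv) if amp.m_test_mv > 0 else float("nan"),
    )


def analyze_animal(
    recordings: dict[float, list[EMGSweep]],
    windows: WaveWindows = WaveWindows(),
) -> list[ReflexMetrics]:
    """Per-interval metrics for one animal's recordings.

    If any interval requires template subtraction, the control template is
    taken from the animal's longest clean-interval recording.
    """
    if not recordings:
        raise ConfigurationError("animal has no recordings")
    intervals = sorted(recordings)
    tmpl = None
    if intervals[0] < windows.overlap_threshold_ms:
        clean = [iv for iv in intervals if iv >= windows.overlap_threshold_ms]
        if clean:
            tmpl = control_template(recordings[clean[-1]])
    out = []
    for iv in intervals:
        amp = analyze_interval(recordings[iv], windows, template=tmpl)
        out.append(_metrics_from_amplitudes(iv, amp))
    return out


def analyze_cohort(
    cohort: dict[str, dict[float, list[EMGSweep]]],
    windows: WaveWindows = WaveWindows(),
) -> pd.DataFrame:
    """Per-animal, per-interval metrics table for a whole cohort."""
    rows = []
    for animal_id in sorted(cohort):
        for m in analyze_animal(cohort[animal_id], windows):
            rows.append(
                {
                    "animal_id": animal_id,
                    "interval_ms": m.interval_ms,
                    "percent_h": m.percent_h,
                    "percent_m": m.percent_m,
                    "hm_ratio": m.hm_ratio,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Threshold (T) determination
# --------------------------------------------------------------------------


@dataclass
class ThresholdResult:
    threshold_T: float
    response_fractions: dict[float, float]
    monotonic: bool


def find_threshold(
    series: dict[float, list[EMGSweep]],
    response_criterion_mv: float,
    windows: WaveWindows = WaveWindows(),
) -> ThresholdResult:
    """Smallest tested intensity with an M-response on >= 50% of sweeps.

    A sweep responds when its rectified M-window baseline-to-peak amplitude
    reaches the criterion.  A non-monotonic empirical response curve is
    flagged (``monotonic=False``), not treated as an error.
    """
    if len(series) < 2:
        raise ConfigurationError("need at least two tested intensities")
    fractions: dict[float, float] = {}
    for intensity in sorted(series):
        sweeps = series[intensity]
        if len(sweeps) < 10:
            raise ConfigurationError("need at least 10 sweeps per intensity")
        n_resp = 0
        for s in sweeps:
            r = rectify(s)
            amp = measure_amplitude(
                r, windows.m_window_ms, windows.baseline_window_ms, r.control_onset_idx
            )
            if amp >= response_criterion_mv:
                n_resp += 1
        fractions[float(intensity)] = n_resp / len(sweeps)
    vals = [fractions[i] for i in sorted(fractions)]
    monotonic = all(b >= a for a, b in zip(vals, vals[1:]))
    for intensity in sorted(fractions):
        if fractions[intensity] >= 0.5:
            return ThresholdResult(float(intensity), fractions, monotonic)
    raise ThresholdNotFoundError(
        f"no tested intensity reached a 50% response rate (max {max(vals):.2f})"
    )


# --------------------------------------------------------------------------
# Group RDD curves and the H/M slope
# --------------------------------------------------------------------------


@dataclass
class RDDCurve:
    """Per-interval group mean ± SEM of %H, %M and H/M, with group size."""

    group: str
    table: pd.DataFrame  # indexed by interval_ms
    exclusions: dict[float, list[str]] = field(default_factory=dict)


def _sem(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def rdd_curve(metrics, group: str = "") -> RDDCurve:
    """Aggregate per-animal metrics into a group RDD curve.

    ``metrics`` is either the DataFrame from :func:`analyze_cohort` or a
    nested mapping ``animal -> interval -> ReflexMetrics``.  Animals missing
    an interval are excluded for that interval and recorded in
    ``exclusions``.
    """
    if isinstance(metrics, dict):
        rows = []
        for animal_id, per_iv in metrics.items():
            for iv, m in per_iv.items():
                rows.append(
                    {
                        "animal_id": animal_id,
                        "interval_ms": float(iv),
                        "percent_h": m.percent_h,
                        "percent_m": m.percent_m,
                        "hm_ratio": m.hm_ratio,
                    }
                )
        df = pd.DataFrame(rows)
    else:
        df = metrics.copy()
    if df.empty:
        raise ConfigurationError("no metrics to aggregate")

    all_animals = set(df.animal_id)
    rows = []
    exclusions: dict[float, list[str]] = {}
    for iv, sub in df.groupby("interval_ms"):
        missing = sorted(all_animals - set(sub.animal_id))
        if missing:
            exclusions[float(iv)] = missing
        row = {"interval_ms": float(iv), "n_animals": len(sub)}
        for col in ("percent_h", "percent_m", "hm_ratio"):
            vals = sub[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(np.nanmean(vals))
            row[f"{col}_sem"] = _sem(vals)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("interval_ms").set_index("interval_ms")
    return RDDCurve(group=group, table=table, exclusions=exclusions)


def hm_slope(curve: RDDCurve, axis: str = "log10") -> float:
    """OLS slope of the mean H/M ratio against the interpulse interval.

    ``axis`` selects the abscissa transform: ``log10`` (default) regresses
    against log10(interval in ms), ``linear`` against the raw interval, and
    ``rank`` against the interval rank order.
    """
    t = curve.table
    y = t["hm_ratio_mean"].to_numpy(dtype=float)
    x = t.index.to_numpy(dtype=float)
    keep = ~np.isnan(y)
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ConfigurationError("H/M slope needs at least two intervals")
    if axis == "log10":
        x = np.log10(x)
    elif axis == "rank":
        x = np.argsort(np.argsort(x)).astype(float)
    elif axis != "linear":
        raise ConfigurationError("axis must be 'linear', 'log10' or 'rank'")
    if np.ptp(x) == 0:
        raise ConfigurationError("H/M slope undefined for a constant abscissa")
    return float(np.polyfit(x, y, 1)[0])
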