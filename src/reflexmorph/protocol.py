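"""Stimulation protocol and EMG sweep containers.

A paired-pulse recording delivers a control pulse followed by a test pulse at
a fixed interpulse interval.  Each stimulus evokes a direct muscle response
(M-wave, short latency) and a monosynaptic reflex response (H-reflex, longer
latency).  Sweeps are sampled voltage traces (mV) with the two stimulus
onsets annotated as sample indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

#: Default interpulse-interval grid (ms) used by shipped presets and studies.
DEFAULT_INTERVALS_MS: tuple[float, ...] = (5.0, 10.0, 50.0, 100.0, 150.0, 300.0, 500.0, 1000.0, 2000.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Paired-pulse stimulation schedule.

    Parameters
    ----------
    interpulse_intervals_ms
        Strictly increasing control-to-test delays.
    pulse_width_ms
        Square-pulse width; 0.2 ms in the standard preparation.
    trials_per_interval, sweeps_per_trial
        Sweeps are grouped in trials; amplitudes are measured on the
        rectified average of all sweeps of an interval.
    inter_sweep_period_s
        Pause between sweeps (one stimulus pair every 3 s by default).
    sampling_rate_hz
        Digitisation rate of the EMG channel.
    pre_stimulus_ms, post_test_ms
        Recorded context before the control pulse and after the test pulse.
    """

    interpulse_intervals_ms: tuple[float, ...] = DEFAULT_INTERVALS_MS
    pulse_width_ms: float = 0.2
    trials_per_interval: int = 3
    sweeps_per_trial: int = 10
    inter_sweep_period_s: float = 3.0
    sampling_rate_hz: float = 20_000.0
    pre_stimulus_ms: float = 5.0
    post_test_ms: float = 15.0

    def __post_init__(self) -> None:
        iv = tuple(float(v) for v in self.interpulse_intervals_ms)
        if len(iv) == 0:
            raise ConfigurationError("protocol needs at least one interpulse interval")
        if any(v <= 0 for v in iv):
            raise ConfigurationError("interpulse intervals must be positive")
        if any(b <= a for a, b in zip(iv, iv[1:])):
            raise ConfigurationError("interpulse intervals must be strictly increasing")
        if self.sweeps_per_trial < 1 or self.trials_per_interval < 1:
            raise ConfigurationError("trials_per_interval and sweeps_per_trial must be >= 1")
        if self.sampling_rate_hz <= 0 or self.pulse_width_ms <= 0:
            raise ConfigurationError("sampling rate and pulse width must be positive")
        if self.post_test_ms < 15.0:
            raise ConfigurationError("sweeps must cover at least 15 ms after the test pulse")
        object.__setattr__(self, "interpulse_intervals_ms", iv)

    @property
    def sweeps_per_interval(self) -> int:
        return self.trials_per_interval * self.sweeps_per_trial

    def with_intervals(self, intervals_ms) -> "StimulusProtocol":
        return replace(self, interpulse_intervals_ms=tuple(float(v) for v in intervals_ms))


@dataclass
class EMGSweep:
    """One sampled paired-pulse EMG sweep.

    ``samples`` are signed voltages in mV; ``control_onset_idx`` and
    ``test_onset_idx`` mark the two stimulus onsets.  ``intensity_T`` is the
    stimulus intensity in threshold units (T).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    control_onset_idx: int
    test_onset_idx: int
    intensity_T: float = 1.5

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n = self.samples.shape[0]
        if not (0 <= self.control_onset_idx < self.test_onset_idx < n):
            raise ConfigurationError(
                "require 0 <= control_onset_idx < test_onset_idx < len(samples)"
            )

    @property
    def interval_ms(self) -> float:
        return (self.test_onset_idx - self.control_onset_idx) / self.sampling_rate_hz * 1e3

    def copy_with(self, samples: np.ndarray) -> "EMGSweep":
        return EMGSweep(
            samples=samples,
            sampling_rate_hz=self.sampling_rate_hz,
            control_onset_idx=self.control_onset_idx,
            test_onset_idx=self.test_onset_idx,
            intensity_T=self.intensity_T,
        )


@dataclass(frozen=True)
class WaveWindows:
    """Measurement windows (ms) relative to a stimulus onset.

    The M-wave and H-reflex are measured baseline-to-peak inside half-open
    windows placed after the onset; the baseline window precedes the onset.
    Defaults suit a mouse plantar-muscle recording (M onset ~1 ms, H onset
    ~5 ms after the stimulus).
    """

    m_window_ms: tuple[float, float] = (0.5, 3.5)
    h_window_ms: tuple[float, float] = (3.5, 12.0)
    baseline_window_ms: tuple[float, float] = (-5.0, 0.0)
    #: Below this interpulse interval the test epoch is cleaned by
    #: subtracting the control-complex template before rectification.
    overlap_threshold_ms: float = 8.0

    def __post_init__(self) -> None:
        m0, m1 = self.m_window_ms
        h0, h1 = self.h_window_ms
        b0, b1 = self.baseline_window_ms
        if not (m0 < m1 and h0 < h1 and b0 < b1):
            raise ConfigurationError("windows must be non-empty (start < end)")
        if not m1 <= h0:
            raise ConfigurationError("M window must precede (not overlap) the H window")
        if b1 > 0:
            raise ConfigurationError("baseline window must end at or before the stimulus onset")
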