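"""Synthetic cohort generation for pipeline validation by parameter recovery.

No raw data from the animal study is available, so every analysis stage is
validated against cohorts generated here, whose ground truth (the
:class:`~reflexmorph.presets.GroupPreset` / ``SpinePreset`` parameters)
encodes the published group means.

EMG model
---------
Each sweep is a sampled voltage trace holding a control-pulse and a
test-pulse M+H complex.  M and H waves are biphasic Gaussian-windowed sine
templates (one positive and one negative lobe, 1.5 ms wide, unit peak)
placed at fixed latencies after each stimulus onset.  The test-pulse H
amplitude is ``control_H x (%H/100) x animal_factor``, where the animal
factor is a mean-one lognormal draw per animal (and analogously for M with
its own factor).  White Gaussian noise of SD ``noise_sd_mv`` is added to
every sample.  Identical (preset, protocol, seed) inputs give bit-identical
outputs; child random streams are spawned per animal (and per neuron /
field) from the root seed via ``numpy.random.SeedSequence.spawn``.

Morphometry model
-----------------
Neurons get a soma drawn around the group's mean geometry and straight
radial dendritic branches.  Spines are placed along each branch by a
Poisson process whose per-class intensity is piecewise constant over the
proximal/medial/distal Sholl regions (uniform weights give a homogeneous
process).  Spine geometry is drawn so that the head-vs-neck classification
rule reproduces the intended class by construction: thin spines get a neck
at least as long as the head diameter, mushroom spines a neck strictly
shorter.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.draw import disk as _disk

from .errors import ConfigurationError
from .histology import CellRecord, HistologyField
from .presets import GroupPreset, SpinePreset
from .protocol import EMGSweep, StimulusProtocol
from .spines import SHOLL_BINS, Branch, NeuronReconstruction, SpineAnnotation

__all__ = [
    "make_emg_cohort",
    "make_recruitment_series",
    "make_neuron_cohort",
    "make_histology_field",
    "wave_template",
]


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _lognormal_mean_one(rng: np.random.Generator, rel_sd: float, size=None):
    """Multiplicative factor(s) with mean exactly 1 and relative SD rel_sd."""
    if rel_sd == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log1p(rel_sd**2)
    return np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size))


def _lognormal_mean_sd(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draw(s) with the given arithmetic mean and SD."""
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    sigma2 = math.log1p((sd / mean) ** 2)
    return np.exp(rng.normal(math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2), size))


def wave_template(sampling_rate_hz: float, width_ms: float = 1.5) -> np.ndarray:
    """Unit-peak biphasic waveform: Gaussian-windowed single-cycle sine.

    One positive then one negative lobe over ``width_ms``; the maximum
    absolute value is exactly 1, so a scaled template has a well-defined
    baseline-to-peak amplitude equal to its scale factor.
    """
    n = max(3, int(round(width_ms * 1e-3 * sampling_rate_hz)))
    t = np.arange(n) / sampling_rate_hz * 1e3  # ms
    centre = width_ms / 2.0
    sigma = width_ms / 6.0
    s = np.sin(2.0 * np.pi * t / width_ms) * np.exp(-((t - centre) ** 2) / (2 * sigma**2))
    return s / np.max(np.abs(s))


def _add_complex(
    samples: np.ndarray,
    onset_idx: int,
    m_amp: float,
    h_amp: float,
    preset: GroupPreset,
    fs: float,
    template: np.ndarray,
) -> None:
    """Add an M+H response complex in place at a stimulus onset."""
    for amp, latency in ((m_amp, preset.m_latency_ms), (h_amp, preset.h_latency_ms)):
        start = onset_idx + int(round(latency * 1e-3 * fs))
        stop = min(start + template.size, samples.size)
        if stop > start:
            samples[start:stop] += amp * template[: stop - start]


# --------------------------------------------------------------------------
# EMG cohorts
# --------------------------------------------------------------------------

def make_emg_cohort(
    preset: GroupPreset,
    protocol: StimulusProtocol,
    n_animals: int,
    seed: int,
) -> dict[str, dict[float, list[EMGSweep]]]:
    """Generate a paired-pulse EMG cohort: animal -> interval -> sweeps.

    Every protocol interval must be present in the preset's depression
    maps; otherwise a :class:`ConfigurationError` is raised.
    """
    if n_animals < 1:
        raise ConfigurationError("n_animals must be >= 1")
    for iv in protocol.interpulse_intervals_ms:
        preset.expected("percent_h", iv)  # raises if unconfigured
        preset.expected("percent_m", iv)

    fs = protocol.sampling_rate_hz
    template = wave_template(fs, preset.wave_width_ms)
    control_onset = int(round(protocol.pre_stimulus_ms * 1e-3 * fs))
    cohort: dict[str, dict[float, list[EMGSweep]]] = {}
    for a, rng in enumerate(_child_rngs(seed, n_animals)):
        animal_id = f"a{a:03d}"
        f_h = float(_lognormal_mean_one(rng, preset.animal_sd_frac))
        f_m = float(_lognormal_mean_one(rng, preset.m_animal_sd_frac))
        recordings: dict[float, list[EMGSweep]] = {}
        for iv in protocol.interpulse_intervals_ms:
            test_onset = control_onset + int(round(iv * 1e-3 * fs))
            n_samples = test_onset + int(round(protocol.post_test_ms * 1e-3 * fs))
            m_test = preset.m_amp_mv * preset.expected("percent_m", iv) / 100.0 * f_m
            h_test = preset.h_amp_mv * preset.expected("percent_h", iv) / 100.0 * f_h
            sweeps = []
            for _ in range(protocol.sweeps_per_interval):
                samples = (
                    rng.normal(0.0, preset.noise_sd_mv, n_samples)
                    if preset.noise_sd_mv > 0
                    else np.zeros(n_samples)
                )
                _add_complex(samples, control_onset, preset.m_amp_mv, preset.h_amp_mv,
                             preset, fs, template)
                _add_complex(samples, test_onset, m_test, h_test, preset, fs, template)
                sweeps.append(
                    EMGSweep(samples, fs, control_onset, test_onset, intensity_T=1.5)
                )
            recordings[float(iv)] = sweeps
        cohort[animal_id] = recordings
    return cohort


#: Logistic steepness of the M-wave recruitment curve (in T units); gives
#: response probability 0.5 at exactly 1.0 T and ~1 beyond ~1.4 T.
RECRUITMENT_SLOPE_T = 0.08


def recruitment_probability(intensity_T: float) -> float:
    """P(M-wave response) as a nondecreasing sigmoid of intensity."""
    return 1.0 / (1.0 + math.exp(-(intensity_T - 1.0) / RECRUITMENT_SLOPE_T))


def make_recruitment_series(
    preset: GroupPreset,
    intensities_T: list[float],
    sweeps_per_intensity: int,
    seed: int,
) -> dict[float, list[EMGSweep]]:
    """Single-pulse sweeps over an ascending intensity series.

    On responding sweeps the M-wave amplitude grows linearly up to the
    preset control amplitude at ~1.4 T; non-responding sweeps contain noise
    only.  Sweeps carry the stimulus at ``control_onset_idx`` (the test
    onset index is a sentinel at the last sample).
    """
    if not intensities_T:
        raise ConfigurationError("empty intensity list")
    if any(b <= a for a, b in zip(intensities_T, intensities_T[1:])):
        raise ConfigurationError("intensities must be sorted ascending")
    fs = 20_000.0
    template = wave_template(fs, preset.wave_width_ms)
    onset = int(round(5.0e-3 * fs))
    n_samples = onset + int(round(20.0e-3 * fs))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    series: dict[float, list[EMGSweep]] = {}
    for intensity in intensities_T:
        p = recruitment_probability(intensity)
        amp = preset.m_amp_mv * min(1.0, max(0.0, intensity) / 1.4)
        sweeps = []
        for _ in range(sweeps_per_intensity):
            samples = (
                rng.normal(0.0, preset.noise_sd_mv, n_samples)
                if preset.noise_sd_mv > 0
                else np.zeros(n_samples)
            )
            if rng.random() < p:
                start = onset + int(round(preset.m_latency_ms * 1e-3 * fs))
                samples[start : start + template.size] += amp * template
            sweeps.append(
                EMGSweep(samples, fs, onset, n_samples - 1, intensity_T=intensity)
            )
        series[float(intensity)] = sweeps
    return series


# --------------------------------------------------------------------------
# Neuron / spine cohorts
# --------------------------------------------------------------------------

_FAILURE_MODES = ("small_diameter", "small_area", "one_branch", "not_lamina_ix", "not_visible")


def _draw_soma(rng: np.random.Generator, preset: SpinePreset) -> tuple[float, float, float]:
    sd = preset.soma_sd_frac
    max_d = max(26.0, rng.normal(preset.soma_diameter_um_mean, sd * preset.soma_diameter_um_mean))
    area = max(460.0, rng.normal(preset.soma_area_um2_mean, sd * preset.soma_area_um2_mean))
    ratio = preset.soma_min_diameter_um_mean / preset.soma_diameter_um_mean
    min_d = max_d * min(1.0, max(0.2, rng.normal(ratio, 0.05)))
    return area, max_d, min_d


def _spine_positions(
    rng: np.random.Generator, branch_len: float, density: float, weights
) -> np.ndarray:
    """Poisson placement along one branch, piecewise-constant over regions."""
    if density == 0 or branch_len == 0:
        return np.empty(0)
    segments = []
    for (lo, hi), w in zip(SHOLL_BINS, weights):
        hi_eff = min(hi, branch_len)
        if hi_eff > lo:
            segments.append((lo, hi_eff, 3.0 * w * density))
    if branch_len > SHOLL_BINS[-1][1]:
        segments.append((SHOLL_BINS[-1][1], branch_len, density))
    positions = []
    for lo, hi, lam in segments:
        k = rng.poisson(lam * (hi - lo))
        if k:
            positions.append(rng.uniform(lo, hi, k))
    if not positions:
        return np.empty(0)
    return np.sort(np.concatenate(positions))


def _make_spines(
    rng: np.random.Generator,
    neuron_id: str,
    branch: Branch,
    preset: SpinePreset,
) -> list[SpineAnnotation]:
    spines: list[SpineAnnotation] = []
    for cls, density, weights, mean_len, mean_head in (
        ("thin", preset.thin_density_per_um, preset.thin_regional_weights,
         preset.thin_length_um, preset.thin_head_um),
        ("mushroom", preset.mushroom_density_per_um, preset.mushroom_regional_weights,
         preset.mushroom_length_um, preset.mushroom_head_um),
    ):
        for d in _spine_positions(rng, branch.length_um, density, weights):
            head = float(_lognormal_mean_sd(rng, mean_head, preset.size_sd_um))
            length = float(_lognormal_mean_sd(rng, mean_len, preset.size_sd_um))
            if cls == "thin":
                # neck at least as long as the head (tie classifies thin)
                neck = head * max(1.0, 1.3 + 0.2 * rng.standard_normal())
            else:
                # neck strictly shorter than the head
                neck = head * float(np.clip(0.5 + 0.15 * rng.standard_normal(), 0.05, 0.99))
            spines.append(
                SpineAnnotation(
                    neuron_id=neuron_id,
                    branch_id=branch.branch_id,
                    distance_um=float(d),
                    spine_length_um=length,
                    neck_length_um=neck,
                    head_diameter_um=head,
                )
            )
    return spines


def make_neuron_cohort(
    preset: SpinePreset,
    n_neurons: int,
    seed: int,
    fail_fraction: float = 0.0,
) -> list[tuple[NeuronReconstruction, list[SpineAnnotation]]]:
    """Generate reconstructed neurons with annotated spines.

    ``fail_fraction`` makes exactly ``round(fail_fraction * n_neurons)``
    neurons deliberately violate one inclusion criterion each (cycling
    through the criteria), for testing the screening stage; all other
    neurons pass inclusion by construction.
    """
    if n_neurons < 1:
        raise ConfigurationError("n_neurons must be >= 1")
    if preset.total_density_per_um < 0:
        raise ConfigurationError("spine density must be >= 0")
    if not 0.0 <= fail_fraction <= 1.0:
        raise ConfigurationError("fail_fraction must lie in [0, 1]")

    root = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n_fail = int(round(fail_fraction * n_neurons))
    fail_idx = set(root.choice(n_neurons, size=n_fail, replace=False).tolist()) if n_fail else set()

    cohort = []
    for i, rng in enumerate(_child_rngs(seed, n_neurons)):
        neuron_id = f"n{i:03d}"
        area, max_d, min_d = _draw_soma(rng, preset)
        lamina, visible = True, True
        n_branches = preset.n_branches
        if i in fail_idx:
            mode = _FAILURE_MODES[len([j for j in sorted(fail_idx) if j <= i]) % len(_FAILURE_MODES)]
            if mode == "small_diameter":
                max_d = 22.0
                min_d = min(min_d, max_d)
            elif mode == "small_area":
                area = 400.0
            elif mode == "one_branch":
                n_branches = 1
            elif mode == "not_lamina_ix":
                lamina = False
            else:
                visible = False
        mean_len = preset.total_dendrite_um_mean / preset.n_branches
        branches = []
        for b in range(n_branches):
            length = float(_lognormal_mean_sd(rng, mean_len, preset.branch_sd_frac * mean_len))
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            n_nodes = max(2, int(math.ceil(length / 5.0)) + 1)
            pts = np.linspace(0.0, length, n_nodes)[:, None] * direction[None, :]
            branches.append(Branch(branch_id=f"b{b:02d}", points=pts))
        neuron = NeuronReconstruction(
            neuron_id=neuron_id,
            soma_area_um2=area,
            soma_max_diameter_um=max_d,
            soma_min_diameter_um=min_d,
            lamina_IX=lamina,
            soma_visible=visible,
            branches=branches,
        )
        spines: list[SpineAnnotation] = []
        for br in branches:
            spines.extend(_make_spines(rng, neuron_id, br, preset))
        cohort.append((neuron, spines))
    return cohort


# --------------------------------------------------------------------------
# Histology fields
# --------------------------------------------------------------------------

def make_histology_field(
    n_chat_cells: int,
    transduction_prob: float,
    positive_area_frac: float,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    marker_channel: str = "IBA1",
) -> HistologyField:
    """Two-channel field: a marker channel with a set positive-area
    fraction inside the ROI, and ChAT cells independently co-labelled with
    tdTomato at ``transduction_prob``.

    Exactly ``round(positive_area_frac * n_roi_pixels)`` ROI pixels are set
    above threshold; the rest stay at sub-threshold background.
    """
    if not 0.0 <= transduction_prob <= 1.0:
        raise ConfigurationError("transduction_prob must lie in [0, 1]")
    if not 0.0 <= positive_area_frac <= 1.0:
        raise ConfigurationError("positive_area_frac must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    h, w = image_shape
    margin_r, margin_c = max(2, h // 10), max(2, w // 10)
    roi = np.array(
        [
            [margin_r, margin_c],
            [margin_r, w - margin_c],
            [h - margin_r, w - margin_c],
            [h - margin_r, margin_c],
        ],
        dtype=float,
    )
    from .histology import roi_mask  # local import avoids cycle at module load

    mask = roi_mask((h, w), roi)
    roi_rows, roi_cols = np.nonzero(mask)
    n_roi = roi_rows.size
    if n_chat_cells > 0 and n_roi < 16 * n_chat_cells:
        raise ConfigurationError("image too small to place the requested cells")

    background_level = 20.0
    marker = rng.normal(background_level, 4.0, (h, w)).clip(min=0.0)
    n_pos = int(round(positive_area_frac * n_roi))
    if n_pos:
        pick = rng.choice(n_roi, size=n_pos, replace=False)
        marker[roi_rows[pick], roi_cols[pick]] = 240.0 + rng.normal(0.0, 5.0, n_pos)

    chat = np.zeros((h, w))
    tdt = np.zeros((h, w))
    cells: list[CellRecord] = []
    if n_chat_cells:
        pick = rng.choice(n_roi, size=n_chat_cells, replace=False)
        tdt_flags = rng.random(n_chat_cells) < transduction_prob
        for (r, c), flag in zip(zip(roi_rows[pick], roi_cols[pick]), tdt_flags):
            rr, cc = _disk((int(r), int(c)), 3, shape=(h, w))
            chat[rr, cc] = 220.0
            if flag:
                tdt[rr, cc] = 200.0
            cells.append(
                CellRecord(
                    centroid=(float(r), float(c)),
                    chat_positive=True,
                    tdtomato_positive=bool(flag),
                )
            )
    return HistologyField(
        channels={marker_channel: marker, "ChAT": chat, "tdTomato": tdt},
        roi=roi,
        cell_records=cells,
        pixel_size_um=0.5,
        background=background_level,
        suggested_threshold=100.0,
    )
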