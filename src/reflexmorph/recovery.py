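"""End-to-end parameter recovery: generate a synthetic cohort from a preset
and push it through the full analysis pipeline, returning the recovered
cohort-level estimate of a ground-truth quantity.

These runs are the package's primary validation: the recovered estimate
must agree with the preset's true value within sampling error (2 generator
standard errors at the stated cohort size).  The ``expected_se_*`` helpers
give those standard errors analytically from the generator's noise model.
"""

from __future__ import annotations

import math

import numpy as np

from .emg import analyze_cohort
from .histology import transduction_yield
from .presets import GroupPreset, SpinePreset, get_preset, get_spine_preset
from .protocol import StimulusProtocol, WaveWindows
from .spines import SHOLL_BIN_NAMES, cohort_spine_table, sholl_profile
from .synthdata import make_emg_cohort, make_histology_field, make_neuron_cohort

__all__ = [
    "recover_emg_metric",
    "recover_spine_density",
    "recover_regional_density",
    "recover_transduction_yield",
    "expected_se_emg",
    "expected_se_density",
    "expected_se_regional_density",
    "expected_se_yield",
]


def recover_emg_metric(
    preset: GroupPreset | str,
    metric: str,
    interval_ms: float,
    n_animals: int,
    seed: int,
    sampling_rate_hz: float = 20_000.0,
    windows: WaveWindows = WaveWindows(),
) -> float:
    """Cohort-mean %H, %M or H/M at one interval, via the full EMG pipeline
    (generate sweeps, rectify, average, baseline-to-peak, normalise)."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    protocol = StimulusProtocol(
        interpulse_intervals_ms=(float(interval_ms),), sampling_rate_hz=sampling_rate_hz
    )
    cohort = make_emg_cohort(preset, protocol, n_animals, seed)
    metrics = analyze_cohort(cohort, windows)
    return float(metrics[metric].mean())


def expected_se_emg(
    preset: GroupPreset | str, metric: str, interval_ms: float, n_animals: int
) -> float:
    """Generator SE of the cohort mean, from the between-animal noise model.

    The per-animal %H (or %M) is the true value times a mean-one lognormal
    factor with relative SD ``animal_sd_frac`` (``m_animal_sd_frac``); the
    H/M ratio carries both factors, so its relative SD adds in quadrature.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    true = preset.expected(metric, interval_ms)
    if metric == "percent_h":
        rel = preset.animal_sd_frac
    elif metric == "percent_m":
        rel = preset.m_animal_sd_frac
    else:
        rel = math.sqrt(preset.animal_sd_frac**2 + preset.m_animal_sd_frac**2)
    return true * rel / math.sqrt(n_animals)


def recover_spine_density(
    preset: SpinePreset | str, spine_class: str, n_neurons: int, seed: int
) -> float:
    """Cohort-mean per-neuron spine density (spines/µm) for a class
    (``total``, ``thin`` or ``mushroom``), with spines classified from
    their head/neck geometry by the analysis pipeline."""
    if isinstance(preset, str):
        preset = get_spine_preset(preset)
    cohort = make_neuron_cohort(preset, n_neurons, seed)
    table = cohort_spine_table(cohort)
    return float(table[f"density_{spine_class}"].mean())


def expected_se_density(
    preset: SpinePreset | str, spine_class: str, n_neurons: int
) -> float:
    """SE of the cohort-mean density under Poisson placement: a neuron with
    dendrite length L contributes count ~ Poisson(d·L), so Var(count/L) ≈
    d / E[L]."""
    if isinstance(preset, str):
        preset = get_spine_preset(preset)
    d = {
        "total": preset.total_density_per_um,
        "thin": preset.thin_density_per_um,
        "mushroom": preset.mushroom_density_per_um,
    }[spine_class]
    return math.sqrt(d / preset.total_dendrite_um_mean) / math.sqrt(n_neurons)


def recover_regional_density(
    preset: SpinePreset | str, spine_class: str, region: str, n_neurons: int, seed: int
) -> float:
    """Cohort-mean regional (Sholl-bin) density for one class; neurons with
    no dendrite in the bin are excluded for that bin."""
    if isinstance(preset, str):
        preset = get_spine_preset(preset)
    idx = SHOLL_BIN_NAMES.index(region)
    cohort = make_neuron_cohort(preset, n_neurons, seed)
    vals = [sholl_profile(n, s).density(spine_class)[idx] for n, s in cohort]
    return float(np.nanmean(vals))


def expected_se_regional_density(
    preset: SpinePreset | str, spine_class: str, region: str, n_neurons: int
) -> float:
    if isinstance(preset, str):
        preset = get_spine_preset(preset)
    idx = SHOLL_BIN_NAMES.index(region)
    weights = (
        preset.mushroom_regional_weights
        if spine_class == "mushroom"
        else preset.thin_regional_weights
    )
    base = {
        "thin": preset.thin_density_per_um,
        "mushroom": preset.mushroom_density_per_um,
        "total": preset.total_density_per_um,
    }[spine_class]
    regional = 3.0 * weights[idx] * base
    # expected dendrite length inside the bin, over the neuron's branches
    lo, hi = 40.0 * idx, 40.0 * (idx + 1)
    mean_branch = preset.total_dendrite_um_mean / preset.n_branches
    bin_len = preset.n_branches * max(0.0, min(mean_branch, hi) - lo)
    if bin_len <= 0 or regional <= 0:
        return float("nan")
    return math.sqrt(regional / bin_len) / math.sqrt(n_neurons)


def recover_transduction_yield(
    n_chat_cells: int, transduction_prob: float, seed: int
) -> float:
    """Transduction yield (%) recovered from a generated histology field."""
    fld = make_histology_field(
        n_chat_cells=n_chat_cells,
        transduction_prob=transduction_prob,
        positive_area_frac=0.09,
        seed=seed,
    )
    return transduction_yield(fld.cell_records)


def expected_se_yield(n_chat_cells: int, transduction_prob: float) -> float:
    p = transduction_prob
    return 100.0 * math.sqrt(p * (1.0 - p) / n_chat_cells)
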