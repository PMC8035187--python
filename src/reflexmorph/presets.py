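"""Group presets: the generative ground truth for synthetic cohorts.

A :class:`GroupPreset` stores, per experimental group, the *true* expected
paired-pulse outcomes (%H-reflex, %M-wave and test-pulse H/M ratio as
functions of the interpulse interval), the waveform amplitudes/latencies,
noise levels, and the spine-morphometry parameters of that group.  The
analysis pipeline is validated by recovering these values from generated
cohorts.

Shipped presets encode the group means of a mouse contusion-SCI spasticity
study at two timepoints: ``sham_wk1``/``sci_wk1`` (one week after surgery)
and ``sham_wk4``/``sci_wk4``/``sci_rac1ko_wk4`` (four weeks after surgery,
three weeks after intramuscular AAV9-Cre delivery knocking out Rac1 in
ipsilateral motor neurons).  Values not reported at some interval are filled
by interpolation, linear in log10(interval).

The three published per-interval quantities are mutually constrained:
``H/M(test) = (h_amp/m_amp) * (%H / %M)`` for a single control-amplitude
pair.  The printed triples are rounded and therefore not exactly consistent
under one amplitude ratio.  Presets keep the printed %H and H/M maps as
ground truth and derive the %M map from them with a least-squares amplitude
ratio fitted to the printed %M values, so every stored map is exactly
realisable by one generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .protocol import DEFAULT_INTERVALS_MS

# --------------------------------------------------------------------------
# Spine-morphometry presets
# --------------------------------------------------------------------------

_UNIFORM = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


@dataclass(frozen=True)
class SpinePreset:
    """True spine-population parameters of one group.

    Densities are spines per µm of dendrite; the thin/mushroom split is
    given by ``mushroom_fraction`` (thin fraction is its complement).
    ``regional_weights`` redistribute each class's placement intensity over
    the proximal [0,40), medial [40,80) and distal [80,120) µm regions; the
    triple sums to 1 and the uniform triple gives a homogeneous Poisson
    process.  Sizes are per-class means (µm) with a shared spread.
    """

    name: str
    total_density_per_um: float
    mushroom_fraction: float
    thin_regional_weights: tuple[float, float, float] = _UNIFORM
    mushroom_regional_weights: tuple[float, float, float] = _UNIFORM
    thin_length_um: float = 1.0
    mushroom_length_um: float = 1.4
    thin_head_um: float = 0.6
    mushroom_head_um: float = 1.2
    size_sd_um: float = 0.25
    soma_area_um2_mean: float = 600.0
    soma_diameter_um_mean: float = 39.0
    soma_min_diameter_um_mean: float = 22.0
    total_dendrite_um_mean: float = 300.0
    n_branches: int = 3
    branch_sd_frac: float = 0.15
    soma_sd_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.total_density_per_um < 0:
            raise ConfigurationError("total spine density must be >= 0")
        if not 0.0 <= self.mushroom_fraction <= 1.0:
            raise ConfigurationError("mushroom_fraction must lie in [0, 1]")
        for w in (self.thin_regional_weights, self.mushroom_regional_weights):
            if len(w) != 3 or any(v < 0 for v in w):
                raise ConfigurationError("regional weights are three nonnegative reals")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ConfigurationError("regional weights must sum to 1")
        if self.size_sd_um < 0:
            raise ConfigurationError("size_sd_um must be >= 0")
        for v in (
            self.thin_length_um,
            self.mushroom_length_um,
            self.thin_head_um,
            self.mushroom_head_um,
            self.soma_area_um2_mean,
            self.soma_diameter_um_mean,
            self.soma_min_diameter_um_mean,
            self.total_dendrite_um_mean,
        ):
            if v <= 0:
                raise ConfigurationError("size and soma parameters must be positive")
        if self.n_branches < 2:
            raise ConfigurationError("neurons need more than one dendritic branch")

    @property
    def thin_fraction(self) -> float:
        return 1.0 - self.mushroom_fraction

    @property
    def mushroom_density_per_um(self) -> float:
        return self.total_density_per_um * self.mushroom_fraction

    @property
    def thin_density_per_um(self) -> float:
        return self.total_density_per_um * self.thin_fraction


# --------------------------------------------------------------------------
# EMG group presets
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupPreset:
    """True paired-pulse EMG outcomes and noise model of one group.

    ``h_depression_by_interval`` etc. map interpulse interval (ms) to the
    expected %H-reflex, %M-wave, and test-pulse H/M ratio.  ``h_amp_mv`` and
    ``m_amp_mv`` are the control-pulse baseline-to-peak amplitudes.  The
    between-animal variability model is a mean-one multiplicative lognormal
    factor per animal applied to each wave's depression (relative SD
    ``animal_sd_frac`` for H, ``m_animal_sd_frac`` for M); within-sweep noise
    is additive white Gaussian with SD ``noise_sd_mv``.
    """

    name: str
    h_depression_by_interval: dict[float, float]
    m_depression_by_interval: dict[float, float]
    hm_ratio_by_interval: dict[float, float]
    m_latency_ms: float = 1.0
    h_latency_ms: float = 5.0
    m_amp_mv: float = 2.0
    h_amp_mv: float = 2.0
    wave_width_ms: float = 1.5
    noise_sd_mv: float = 0.02
    animal_sd_frac: float = 0.25
    m_animal_sd_frac: float = 0.10
    spine_params: SpinePreset | None = None
    transduction_prob: float = 0.512

    def __post_init__(self) -> None:
        for m in (
            self.h_depression_by_interval,
            self.m_depression_by_interval,
            self.hm_ratio_by_interval,
        ):
            if any(v < 0 for v in m.values()):
                raise ConfigurationError("expected percentages and ratios must be >= 0")
        if not self.h_latency_ms > self.m_latency_ms:
            raise ConfigurationError("H latency must exceed M latency")
        if self.m_amp_mv <= 0 or self.h_amp_mv <= 0:
            raise ConfigurationError("control amplitudes must be positive")
        if self.noise_sd_mv < 0 or self.animal_sd_frac < 0 or self.m_animal_sd_frac < 0:
            raise ConfigurationError("noise parameters must be nonnegative")
        if not 0.0 <= self.transduction_prob <= 1.0:
            raise ConfigurationError("transduction_prob must lie in [0, 1]")

    def expected(self, kind: str, interval_ms: float) -> float:
        """Look up a true expected value; raises if the interval is absent."""
        table = {
            "percent_h": self.h_depression_by_interval,
            "percent_m": self.m_depression_by_interval,
            "hm_ratio": self.hm_ratio_by_interval,
        }[kind]
        key = float(interval_ms)
        if key not in table:
            raise ConfigurationError(
                f"interval {interval_ms} ms not configured in preset {self.name!r}"
            )
        return table[key]


def interpolate_by_interval(
    printed: dict[float, float], grid=DEFAULT_INTERVALS_MS
) -> dict[float, float]:
    """Fill an interval->value map on ``grid``, linear in log10(interval).

    Values outside the printed range are held flat at the nearest endpoint.
    """
    if not printed:
        raise ConfigurationError("need at least one printed value to interpolate")
    xs = np.log10(np.array(sorted(printed), dtype=float))
    ys = np.array([printed[k] for k in sorted(printed)], dtype=float)
    out = {}
    for iv in grid:
        out[float(iv)] = float(np.interp(math.log10(iv), xs, ys))
    return out


def _fit_amplitude_ratio(
    h_map: dict[float, float], hm_map: dict[float, float], m_printed: dict[float, float]
) -> float:
    """Least-squares h_amp/m_amp making rho * %H / (H/M) match printed %M."""
    a = np.array([h_map[i] / hm_map[i] for i in m_printed], dtype=float)
    m = np.array(list(m_printed.values()), dtype=float)
    return float(a @ m / (a @ a))


def _build_emg_preset(
    name: str,
    h_printed: dict[float, float],
    hm_printed: dict[float, float],
    m_printed: dict[float, float],
    spine_params: SpinePreset | None,
    grid=DEFAULT_INTERVALS_MS,
) -> GroupPreset:
    h_map = interpolate_by_interval(h_printed, grid)
    hm_map = interpolate_by_interval(hm_printed, grid)
    rho = _fit_amplitude_ratio(h_map, hm_map, m_printed)
    m_map = {iv: rho * h_map[iv] / hm_map[iv] for iv in h_map}
    return GroupPreset(
        name=name,
        h_depression_by_interval=h_map,
        m_depression_by_interval=m_map,
        hm_ratio_by_interval=hm_map,
        m_amp_mv=2.0,
        h_amp_mv=2.0 * rho,
        spine_params=spine_params,
    )


# --------------------------------------------------------------------------
# Published group means (generator ground truth)
# --------------------------------------------------------------------------

# %H-reflex (test/control x 100), week 1 post-surgery
_H_WK1 = {
    "sham": {10.0: 53.1, 50.0: 38.1, 100.0: 38.2, 2000.0: 52.6},
    "sci": {10.0: 79.8, 50.0: 60.8, 100.0: 60.8, 2000.0: 76.8},
}
# test-pulse H/M ratio, week 1
_HM_WK1 = {
    "sham": {10.0: 0.79, 100.0: 0.80, 1000.0: 1.03},
    "sci": {10.0: 1.32, 100.0: 1.30, 1000.0: 1.12},
}
# %M-wave, week 1 (used only to fit the control-amplitude ratio)
_M_WK1 = {
    "sham": {5.0: 32.8, 10.0: 73.4, 50.0: 56.8, 100.0: 53.7, 150.0: 52.0,
             300.0: 56.0, 500.0: 57.8, 1000.0: 57.0, 2000.0: 62.6},
    "sci": {5.0: 86.7, 10.0: 62.8, 50.0: 73.2, 100.0: 50.9, 150.0: 56.0,
            300.0: 53.7, 500.0: 52.5, 1000.0: 53.7, 2000.0: 68.4},
}

# week 4 post-surgery (three weeks after AAV9-Cre injection)
_H_WK4 = {
    "sham": {5.0: 3.4, 10.0: 44.5, 50.0: 36.4, 100.0: 42.1, 150.0: 53.2, 1000.0: 52.2},
    "sci": {5.0: 83.9, 10.0: 71.0, 50.0: 54.6, 100.0: 59.2, 150.0: 57.9, 1000.0: 63.5},
    "sci_rac1ko": {5.0: 24.7, 10.0: 53.7, 50.0: 38.3, 100.0: 41.5, 150.0: 42.3, 1000.0: 48.5},
}
_HM_WK4 = {
    "sham": {10.0: 0.70, 100.0: 0.70, 1000.0: 0.90},
    "sci": {10.0: 1.10, 100.0: 1.10, 1000.0: 1.10},
    "sci_rac1ko": {10.0: 0.90, 100.0: 0.90, 1000.0: 1.00},
}
_M_WK4 = {
    "sham": {300.0: 62.8, 500.0: 55.5},
    "sci": {300.0: 51.0, 500.0: 52.4},
    "sci_rac1ko": {300.0: 50.5, 500.0: 48.4},
}

# Spine morphometry: whole-neuron total density and mushroom density
# (spines/µm), per-class size means (µm), soma geometry and total dendritic
# length per group.  Thin density is carried implicitly as total - mushroom.
_SPINES = {
    "sham": dict(total=0.10, mushroom=0.01, thin_len=1.04, mush_len=1.4,
                 thin_head=0.58, mush_head=1.2,
                 soma_area=580.0, soma_max=39.1, soma_min=21.4, dendrite=230.3),
    "sci": dict(total=0.20, mushroom=0.02, thin_len=1.6, mush_len=1.9,
                thin_head=1.1, mush_head=1.7,
                soma_area=684.8, soma_max=40.5, soma_min=25.8, dendrite=374.2),
    "sci_rac1ko": dict(total=0.10, mushroom=0.004, thin_len=1.2, mush_len=1.0,
                       thin_head=0.64, mush_head=0.7,
                       soma_area=544.4, soma_max=35.8, soma_min=22.1, dendrite=216.9),
}

# Medial-bin (40-80 µm) mushroom density reported for the SCI group; the
# Sholl variant preset concentrates mushroom placement medially to realise
# it: medial density = 3 * w_medial * whole-neuron mushroom density.
_SCI_MEDIAL_MUSHROOM = 0.08
_SHOLL_MUSH_WEIGHTS = (1.0 / 6.0, 2.0 / 3.0, 1.0 / 6.0)


def _build_spine_preset(name: str, key: str, **overrides) -> SpinePreset:
    p = _SPINES[key]
    kwargs = dict(
        name=name,
        total_density_per_um=p["total"],
        mushroom_fraction=p["mushroom"] / p["total"],
        thin_length_um=p["thin_len"],
        mushroom_length_um=p["mush_len"],
        thin_head_um=p["thin_head"],
        mushroom_head_um=p["mush_head"],
        soma_area_um2_mean=p["soma_area"],
        soma_diameter_um_mean=p["soma_max"],
        soma_min_diameter_um_mean=p["soma_min"],
        total_dendrite_um_mean=p["dendrite"],
    )
    kwargs.update(overrides)
    return SpinePreset(**kwargs)


def _build_registry() -> dict[str, GroupPreset]:
    spine_presets = {
        "sham_spines": _build_spine_preset("sham_spines", "sham"),
        "sci_spines": _build_spine_preset("sci_spines", "sci"),
        "sci_rac1ko_spines": _build_spine_preset("sci_rac1ko_spines", "sci_rac1ko"),
    }
    # Region-weighted SCI variant: mushroom intensity concentrated in the
    # medial bin so the medial mushroom density equals the reported value.
    mush_density = _SCI_MEDIAL_MUSHROOM / (3.0 * _SHOLL_MUSH_WEIGHTS[1])
    sci = _SPINES["sci"]
    total = sci["total"] - sci["mushroom"] + mush_density
    spine_presets["sci_spines_sholl"] = _build_spine_preset(
        "sci_spines_sholl",
        "sci",
        total_density_per_um=total,
        mushroom_fraction=mush_density / total,
        mushroom_regional_weights=_SHOLL_MUSH_WEIGHTS,
    )

    emg = {}
    for grp in ("sham", "sci"):
        emg[f"{grp}_wk1"] = _build_emg_preset(
            f"{grp}_wk1", _H_WK1[grp], _HM_WK1[grp], _M_WK1[grp],
            spine_params=spine_presets[f"{grp}_spines"],
        )
    for grp in ("sham", "sci", "sci_rac1ko"):
        emg[f"{grp}_wk4"] = _build_emg_preset(
            f"{grp}_wk4", _H_WK4[grp], _HM_WK4[grp], _M_WK4[grp],
            spine_params=spine_presets[f"{grp}_spines"],
        )
    registry: dict[str, GroupPreset] = dict(emg)
    registry.update({name: sp for name, sp in spine_presets.items()})
    return registry


_REGISTRY = _build_registry()


def preset_names() -> list[str]:
    return sorted(_REGISTRY)


def get_preset(name: str) -> GroupPreset:
    """Fetch a shipped EMG group preset by name (e.g. ``sci_wk1``)."""
    try:
        p = _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    if not isinstance(p, GroupPreset):
        raise ConfigurationError(f"{name!r} is a spine preset; use get_spine_preset")
    return p


def get_spine_preset(name: str) -> SpinePreset:
    """Fetch a shipped spine preset by name (e.g. ``sci_spines``)."""
    try:
        p = _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    if isinstance(p, GroupPreset):
        if p.spine_params is None:
            raise ConfigurationError(f"preset {name!r} carries no spine parameters")
        return p.spine_params
    return p
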