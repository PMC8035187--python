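import numpy as np
import pytest

from reflexmorph.presets import GroupPreset, SpinePreset
from reflexmorph.protocol import StimulusProtocol

#: reduced sampling rate for tests: stimulus onsets in the shipped interval
#: grids land on exact sample indices at 5 kHz, so control and test waves are
#: sampled at identical phases and amplitude ratios remain exact.
TEST_FS = 5_000.0


def make_group_preset(
    percent_h: float = 80.0,
    percent_m: float = 60.0,
    intervals=(10.0,),
    noise_sd_mv: float = 0.0,
    animal_sd_frac: float = 0.0,
    m_animal_sd_frac: float = 0.0,
    m_amp_mv: float = 2.0,
    h_amp_mv: float = 1.6,
    **kw,
) -> GroupPreset:
    """Self-consistent preset: the H/M map is implied by the %H/%M maps."""
    h_map = {float(iv): percent_h for iv in intervals}
    m_map = {float(iv): percent_m for iv in intervals}
    rho = h_amp_mv / m_amp_mv
    hm_map = {
        iv: (rho * h_map[iv] / m_map[iv] if m_map[iv] > 0 else 0.0) for iv in h_map
    }
    return GroupPreset(
        name="test",
        h_depression_by_interval=h_map,
        m_depression_by_interval=m_map,
        hm_ratio_by_interval=hm_map,
        m_amp_mv=m_amp_mv,
        h_amp_mv=h_amp_mv,
        noise_sd_mv=noise_sd_mv,
        animal_sd_frac=animal_sd_frac,
        m_animal_sd_frac=m_animal_sd_frac,
        **kw,
    )


def make_spine_preset(
    total_density: float = 0.2,
    mushroom_fraction: float = 0.1,
    size_sd_um: float = 0.25,
    **kw,
) -> SpinePreset:
    return SpinePreset(
        name="test",
        total_density_per_um=total_density,
        mushroom_fraction=mushroom_fraction,
        size_sd_um=size_sd_um,
        **kw,
    )


@pytest.fixture
def quiet_preset():
    return make_group_preset()


@pytest.fixture
def protocol_10ms():
    return StimulusProtocol(interpulse_intervals_ms=(10.0,), sampling_rate_hz=TEST_FS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
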