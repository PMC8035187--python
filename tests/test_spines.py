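"""Spine morphometry: inclusion screening, thin/mushroom classification,
densities, Sholl profiles, and size summaries."""

import numpy as np
import pytest

from reflexmorph.errors import ConfigurationError, ReflexMorphError
from reflexmorph.presets import get_spine_preset
from reflexmorph.spines import (
    Branch,
    NeuronReconstruction,
    SpineAnnotation,
    apply_inclusion,
    classify_spine,
    cohort_spine_table,
    neuron_summary,
    sholl_profile,
    size_summary,
    spine_density,
    summarize_neuron,
)
from reflexmorph.synthdata import make_neuron_cohort

from conftest import make_spine_preset


def _branch(bid="b00", length=100.0):
    return Branch(bid, np.array([[0.0, 0.0, 0.0], [length, 0.0, 0.0]]))


def _neuron(
    nid="n0", area=500.0, dmax=30.0, dmin=20.0, lamina=True, visible=True, n_branches=2,
    branch_length=100.0,
):
    return NeuronReconstruction(
        neuron_id=nid, soma_area_um2=area, soma_max_diameter_um=dmax,
        soma_min_diameter_um=dmin, lamina_IX=lamina, soma_visible=visible,
        branches=[_branch(f"b{i:02d}", branch_length) for i in range(n_branches)],
    )


def _spine(dist, head=0.8, neck=0.4, length=1.2, nid="n0", bid="b00"):
    return SpineAnnotation(
        neuron_id=nid, branch_id=bid, distance_um=dist, spine_length_um=length,
        neck_length_um=neck, head_diameter_um=head,
    )


class TestInclusion:
    def test_all_criteria_pass(self):
        included, reasons = apply_inclusion(_neuron(area=451.0, dmax=26.0))
        assert included and reasons == []

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(dmax=25.0, dmin=20.0), "diameter not > 25 µm"),
            (dict(area=450.0), "cross-sectional area not > 450 µm²"),
            (dict(n_branches=1), "not more than one dendritic branch"),
            (dict(lamina=False), "not located in lamina IX"),
            (dict(visible=False), "cell body not visible"),
        ],
    )
    def test_each_failure_enumerated(self, kwargs, reason):
        params = dict(area=500.0, dmax=30.0)
        params.update(kwargs)
        included, reasons = apply_inclusion(_neuron(**params))
        assert not included
        assert reason in reasons

    def test_missing_field_is_error_not_exclusion(self):
        neuron = _neuron()
        neuron.soma_area_um2 = None
        with pytest.raises(ConfigurationError):
            apply_inclusion(neuron)

    def test_generator_failure_fraction_roundtrip(self):
        """30% deliberate failures: inclusion fraction matches the
        generator's intent exactly."""
        n = 20
        cohort = make_neuron_cohort(make_spine_preset(), n, seed=9, fail_fraction=0.3)
        included = sum(apply_inclusion(neuron)[0] for neuron, _ in cohort)
        assert included == n - round(0.3 * n)


class TestClassification:
    @pytest.mark.parametrize(
        "head,neck,expect",
        [(0.5, 0.5, "thin"), (0.8, 0.4, "mushroom"), (0.3, 0.9, "thin"), (1.0, 0.0, "mushroom")],
    )
    def test_rule(self, head, neck, expect):
        assert classify_spine(head, neck) == expect

    def test_nonpositive_head_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_spine(0.0, 0.5)

    def test_exhaustive_grid_matches_bruteforce_rule(self):
        """Labels equal a direct evaluation of 'thin iff head <= neck' on
        the full 20x20 grid (0.1..2.0, step 0.1)."""
        grid = np.round(np.arange(0.1, 2.01, 0.1), 10)
        for head in grid:
            for neck in grid:
                expect = "thin" if head <= neck else "mushroom"
                assert classify_spine(head, neck) == expect


class TestDensity:
    def test_basic(self):
        assert spine_density(10, 100.0) == pytest.approx(0.1)
        assert spine_density(0, 50.0) == 0.0

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ConfigurationError):
            spine_density(5, 0.0)

    def test_partition_total_equals_thin_plus_mushroom(self):
        cohort = make_neuron_cohort(get_spine_preset("sci_spines"), 10, seed=2)
        for neuron, spines in cohort:
            s = summarize_neuron(neuron, spines)
            assert s["n_thin"] + s["n_mushroom"] == s["n_spines"]
            assert s["density_total"] == pytest.approx(
                s["density_thin"] + s["density_mushroom"]
            )

    def test_poisson_recovery_500_neurons(self):
        preset = make_spine_preset(total_density=0.15, mushroom_fraction=0.2)
        table = cohort_spine_table(make_neuron_cohort(preset, 500, seed=4))
        se = np.sqrt(0.15 / preset.total_dendrite_um_mean) / np.sqrt(500)
        assert abs(table.density_total.mean() - 0.15) < 2 * se


class TestSholl:
    def test_boundary_bins(self):
        neuron = _neuron(branch_length=130.0)
        spines = [_spine(40.0), _spine(39.999), _spine(80.0), _spine(120.0), _spine(125.0)]
        prof = sholl_profile(neuron, spines)
        assert prof.counts["total"].tolist() == [1, 1, 1]  # 120+ excluded

    def test_all_proximal_leaves_other_bins_zero(self):
        neuron = _neuron(branch_length=130.0)
        prof = sholl_profile(neuron, [_spine(5.0), _spine(20.0)])
        assert prof.counts["total"].tolist() == [2, 0, 0]
        assert prof.density("total")[1] == 0.0 and prof.density("total")[2] == 0.0

    def test_density_nan_when_no_dendrite_in_bin(self):
        neuron = _neuron(branch_length=50.0)
        prof = sholl_profile(neuron, [_spine(5.0)])
        assert np.isnan(prof.density("total")[2])

    def test_count_conservation_on_generated_cohort(self):
        cohort = make_neuron_cohort(get_spine_preset("sci_spines"), 20, seed=5)
        for neuron, spines in cohort:
            prof = sholl_profile(neuron, spines)
            within = sum(1 for s in spines if s.distance_um < 120.0)
            assert int(prof.counts["total"].sum()) == within
            assert np.array_equal(
                prof.counts["total"], prof.counts["thin"] + prof.counts["mushroom"]
            )

    def test_homogeneous_placement_uniform_density(self):
        """Uniform Poisson placement: pooled bin densities agree pairwise
        within 3 SEs over 500 neurons."""
        preset = make_spine_preset(total_density=0.2, total_dendrite_um_mean=360.0)
        cohort = make_neuron_cohort(preset, 500, seed=13)
        counts = np.zeros(3)
        lengths = np.zeros(3)
        for neuron, spines in cohort:
            prof = sholl_profile(neuron, spines)
            counts += prof.counts["total"]
            lengths += prof.bin_lengths_um
        dens = counts / lengths
        for i in range(3):
            for j in range(i + 1, 3):
                se = np.sqrt(dens[i] / lengths[i] + dens[j] / lengths[j])
                assert abs(dens[i] - dens[j]) < 3 * se

    def test_negative_distance_rejected(self):
        with pytest.raises(ConfigurationError):
            _spine(-1.0)


class TestSizeSummary:
    def test_single_spine(self):
        t = size_summary([_spine(10.0, head=0.6, neck=0.9, length=1.2)])
        assert t.loc["total", "mean_length_um"] == pytest.approx(1.2)
        assert t.loc["thin", "mean_head_um"] == pytest.approx(0.6)
        assert np.isnan(t.loc["total", "sem_length_um"])

    def test_mean_and_sem(self):
        spines = [_spine(1.0, length=v, head=0.5, neck=1.0) for v in (1.0, 2.0, 3.0)]
        t = size_summary(spines)
        assert t.loc["total", "mean_length_um"] == pytest.approx(2.0)
        assert t.loc["total", "sem_length_um"] == pytest.approx(1.0 / np.sqrt(3))

    def test_empty_class_is_missing_not_zero(self):
        t = size_summary([_spine(1.0, head=0.9, neck=0.2)])  # mushroom only
        assert np.isnan(t.loc["thin", "mean_length_um"])
        assert t.loc["thin", "n"] == 0

    def test_per_neuron_pooling_weights_neurons_equally(self):
        spines = [
            _spine(1.0, length=1.0, nid="a"),
            _spine(2.0, length=1.0, nid="a"),
            _spine(3.0, length=4.0, nid="b"),
        ]
        per_spine = size_summary(spines, "per_spine")
        per_neuron = size_summary(spines, "per_neuron")
        assert per_spine.loc["total", "mean_length_um"] == pytest.approx(2.0)
        assert per_neuron.loc["total", "mean_length_um"] == pytest.approx(2.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            size_summary([])

    def test_size_recovery_1000_spines(self):
        """Per-class size means recovered at ~1000 spines.

        Four means are checked jointly, so each gets a 3-SE bound to hold
        the family-wise false-alarm rate near 1%."""
        preset = make_spine_preset(
            total_density=0.5, mushroom_fraction=0.5, size_sd_um=0.25,
            total_dendrite_um_mean=400.0,
        )
        cohort = make_neuron_cohort(preset, 5, seed=2)
        spines = [s for _, sp in cohort for s in sp]
        assert len(spines) > 800
        t = size_summary(spines)
        for cls, mean_len, mean_head in (
            ("thin", preset.thin_length_um, preset.thin_head_um),
            ("mushroom", preset.mushroom_length_um, preset.mushroom_head_um),
        ):
            n = t.loc[cls, "n"]
            se = 0.25 / np.sqrt(n)
            assert abs(t.loc[cls, "mean_length_um"] - mean_len) < 3 * se
            assert abs(t.loc[cls, "mean_head_um"] - mean_head) < 3 * se


class TestNeuronSummary:
    def test_single_neuron_reports_own_values(self):
        s = neuron_summary([_neuron(area=500.0, dmax=30.0, dmin=20.0)])
        assert s["soma_area_um2_mean"] == 500.0
        assert s["total_dendrite_length_um_mean"] == pytest.approx(200.0)
        assert np.isnan(s["soma_area_um2_sem"])

    def test_two_identical_neurons_sem_zero(self):
        ns = [_neuron(nid="a"), _neuron(nid="b")]
        s = neuron_summary(ns)
        assert s["soma_area_um2_sem"] == 0.0

    def test_excluded_neurons_do_not_contribute(self):
        ns = [_neuron(nid="a"), _neuron(nid="b", area=100.0)]
        s = neuron_summary(ns)
        assert s["n_neurons"] == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ReflexMorphError):
            neuron_summary([_neuron(area=100.0)])

    def test_generator_recovery_soma_geometry(self):
        """Cohort morphology (soma area/diameters, dendrite length) within
        2 analytic SEs of the preset means at n=12."""
        preset = get_spine_preset("sham_spines")
        cohort = make_neuron_cohort(preset, 12, seed=7)
        s = neuron_summary(cohort)
        se_area = preset.soma_sd_frac * preset.soma_area_um2_mean / np.sqrt(12)
        se_len = (
            preset.branch_sd_frac * preset.total_dendrite_um_mean
            / np.sqrt(preset.n_branches) / np.sqrt(12)
        )
        assert abs(s["soma_area_um2_mean"] - preset.soma_area_um2_mean) < 2 * se_area
        assert abs(
            s["total_dendrite_length_um_mean"] - preset.total_dendrite_um_mean
        ) < 2 * se_len
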