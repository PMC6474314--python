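"""Synthetic scenario generators: determinism, noise-free limits, structure."""

import dataclasses

import numpy as np
import pytest

from sedmix.calibration import AbundanceProfile, extraction_efficiency
from sedmix.mixing import steady_state_pb210, transient_cs137
from sedmix.srr import srr_profile
from sedmix.synthetic import (ScenarioConfig, TaxonArchetype,
                              expected_relative_abundance, gen_community,
                              gen_qpcr_tcc, gen_radionuclide_data,
                              gen_srr_and_sulfate, true_srr, true_sulfate)


class TestRadionuclideGenerator:
    def test_noise_off_equals_forward_model(self, scenario):
        cfg = dataclasses.replace(scenario, counting_time=None)
        radio = gen_radionuclide_data(cfg)
        pb = steady_state_pb210(cfg.true_mixing, cfg.grid)
        cs = transient_cs137(cfg.true_mixing, cfg.grid, t_run=cfg.t_run_cs,
                             inventory=cfg.cs_inventory)
        np.testing.assert_allclose(radio.pb210_total - cfg.supported_activity,
                                   pb.value, rtol=1e-12)
        np.testing.assert_allclose(radio.cs137, cs.value, rtol=1e-12)
        assert radio.sigma_pb210 is None

    def test_fixed_seed_bit_identical(self, scenario):
        a = gen_radionuclide_data(scenario)
        b = gen_radionuclide_data(scenario)
        np.testing.assert_array_equal(a.pb210_total, b.pb210_total)
        np.testing.assert_array_equal(a.cs137, b.cs137)

    def test_truth_in_metadata(self, scenario):
        radio = gen_radionuclide_data(scenario)
        assert radio.metadata["seed"] == scenario.seed
        assert radio.metadata["truth"]["true_mixing"]["z_mix"] == 6.0

    def test_empirical_sd_matches_declared_sigma(self):
        """Monte-Carlo: per-bin sd over replicates ~ declared Poisson sigma."""
        base = ScenarioConfig(seed=0, grid=dataclasses.replace(
            ScenarioConfig().grid, dz=0.2, dt=0.5))
        reps = 200
        vals = []
        for seed in range(reps):
            radio = gen_radionuclide_data(dataclasses.replace(base, seed=seed))
            vals.append(radio.pb210_total)
        vals = np.array(vals)
        declared = gen_radionuclide_data(base).sigma_pb210
        empirical = vals.std(axis=0)
        # compare on well-counted bins (surface, high activity)
        sel = slice(0, 10)
        ratio = empirical[sel] / declared[sel]
        assert np.all((ratio > 0.85) & (ratio < 1.15))

    def test_nonpositive_counting_time_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(counting_time=0.0)


class TestQpcrTccGenerator:
    def test_noise_off_all_bacterial_identity(self, sample_depths):
        cfg = ScenarioConfig(qpcr_cv=0.0, tcc_cv=0.0, tcc_surface=None,
                             arch_cells_surface=1e-30, extraction_efficiency=1.0)
        qpcr, tcc = gen_qpcr_tcc(cfg, sample_depths)
        np.testing.assert_allclose(qpcr["bac"].value, tcc.value * 4.1, rtol=1e-9)

    def test_copy_drop_exceeds_tcc_drop(self, sample_depths):
        """Over the mixed zone, gene copies fall faster than microscopy counts."""
        cfg = ScenarioConfig(qpcr_cv=0.0, tcc_cv=0.0)
        qpcr, tcc = gen_qpcr_tcc(cfg, [0.0, 6.0])
        bac_drop = 1 - qpcr["bac"].value[1] / qpcr["bac"].value[0]
        arch_drop = 1 - qpcr["arch"].value[1] / qpcr["arch"].value[0]
        tcc_drop = 1 - tcc.value[1] / tcc.value[0]
        assert bac_drop == pytest.approx(0.86, abs=0.01)
        assert arch_drop == pytest.approx(0.70, abs=0.01)
        assert tcc_drop == pytest.approx(0.65, abs=0.01)
        assert bac_drop > tcc_drop

    def test_efficiency_closed_loop(self, sample_depths):
        """Noise-free consistent mode: configured efficiency recovered exactly."""
        cfg = ScenarioConfig(qpcr_cv=0.0, tcc_cv=0.0, tcc_surface=None)
        qpcr, tcc = gen_qpcr_tcc(cfg, sample_depths)
        res = extraction_efficiency(AbundanceProfile(profile=tcc),
                                    qpcr["bac"], qpcr["arch"])
        np.testing.assert_allclose(res.per_depth.value,
                                   cfg.extraction_efficiency, rtol=1e-12)
        assert res.mean == pytest.approx(cfg.extraction_efficiency, rel=1e-12)

    def test_seeded_determinism(self, scenario, sample_depths):
        a, _ = gen_qpcr_tcc(scenario, sample_depths)
        b, _ = gen_qpcr_tcc(scenario, sample_depths)
        np.testing.assert_array_equal(a["dsrb"].value, b["dsrb"].value)


class TestSrrGenerator:
    def test_closed_loop_inversion(self, scenario, sample_depths):
        srr_true_prof, _, tracer = gen_srr_and_sulfate(scenario, sample_depths)
        recomputed = srr_profile(tracer, bins=srr_true_prof)
        np.testing.assert_allclose(recomputed.value, srr_true_prof.value,
                                   rtol=1e-7)  # 6+ significant digits

    def test_sulfate_anchor_values(self, scenario):
        _, sulfate, _ = gen_srr_and_sulfate(scenario, [3.0, 50.0])
        assert sulfate.value[0] == pytest.approx(27.0, abs=0.1)
        assert sulfate.value[1] == pytest.approx(2.0, abs=0.1)

    def test_sulfate_monotone_decline(self, scenario, sample_depths):
        _, sulfate, _ = gen_srr_and_sulfate(scenario, sample_depths)
        assert np.all(np.diff(sulfate.value) <= 1e-12)

    def test_srr_shape(self, scenario):
        vals = true_srr(scenario, np.array([0.5, 2.0, 50.0]))
        assert vals[0] < vals[1]                       # suppressed top cm
        assert vals[1] == pytest.approx(200.0)         # plateau max
        assert vals[2] == pytest.approx(0.4, rel=1e-6)

    def test_zero_deep_rate_means_zero_tris(self):
        cfg = ScenarioConfig(srr_deep=0.0)
        _, _, tracer = gen_srr_and_sulfate(cfg, [50.0])
        assert tracer[0].a_tris == 0.0


class TestCommunityGenerator:
    def test_flat_single_structure_differs_only_by_noise(self):
        arche = (TaxonArchetype("flat_a", "flat", 5, 1.0, floor=1.0),
                 TaxonArchetype("flat_b", "flat", 5, 1.0, floor=1.0))
        cfg = ScenarioConfig(archetypes=arche, seed=0)
        rel, _, _, _ = expected_relative_abundance(cfg, [1.0, 30.0])
        np.testing.assert_allclose(rel[0], rel[1])

    def test_riser_share_grows_below_mixing_zone(self, scenario):
        """Deep-biosphere archetypes: negligible in the mixed zone, dominant share at depth."""
        rel, _, _, arch = expected_relative_abundance(scenario, [3.0, 50.0])
        riser = np.array([a == "subsurface_riser" for a in arch])
        share_3 = rel[0, riser].sum()
        share_50 = rel[1, riser].sum()
        assert share_50 > share_3
        assert share_3 < 1e-4          # well under 0.01 %
        assert share_50 > 0.10

    def test_multinomial_mean_matches_expectation(self, scenario):
        depth = [10.0]
        rel, _, _, _ = expected_relative_abundance(scenario, depth)
        reps = 1000
        acc = np.zeros(rel.shape[1])
        for seed in range(reps):
            cfg = dataclasses.replace(scenario, seed=seed)
            acc += gen_community(cfg, depth).counts[0]
        mean = acc / reps
        expected = scenario.sequencing_depth * rel[0]
        se = np.sqrt(scenario.sequencing_depth * rel[0] * (1 - rel[0]) / reps)
        sel = expected > 1.0
        z = np.abs(mean[sel] - expected[sel]) / np.maximum(se[sel], 1e-9)
        # ~100 OTUs compared at once: 4 se family-wise, and no systematic bias
        assert np.all(z <= 4.0)
        assert z.mean() < 1.5

    def test_persister_floor_gives_nonzero_expectation_everywhere(self, scenario,
                                                                  sample_depths):
        rel, ids, _, arch = expected_relative_abundance(scenario, sample_depths)
        floored = np.array([a in ("subsurface_riser", "persister_flat") for a in arch])
        assert np.all(rel[:, floored] > 0)

    def test_determinism_and_guards(self, scenario, sample_depths):
        a = gen_community(scenario, sample_depths)
        b = gen_community(scenario, sample_depths)
        np.testing.assert_array_equal(a.counts, b.counts)
        with pytest.raises(ValueError):
            gen_community(dataclasses.replace(scenario, sequencing_depth=10),
                          sample_depths)
        with pytest.raises(ValueError):
            gen_community(dataclasses.replace(
                scenario, archetypes=(scenario.archetypes[0],)), sample_depths)


def test_sulfate_seawater_cap(scenario):
    vals = true_sulfate(scenario, np.array([0.0]))
    assert 27.0 < vals[0] <= 29.0
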