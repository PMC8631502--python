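"""Synthetic-spectra generator: presets, determinism, faithfulness, series."""

import numpy as np
import pytest

from fishglycomics.digestion import ALPHA_GALACTOSIDASE, BETA_GALACTOSIDASE
from fishglycomics.glycan_model import MonosaccharideComposition as C, parse_topology
from fishglycomics.msn import detect_disa, predicted_mz_set
from fishglycomics.synthetic import (
    DP4_MZ_THEORETICAL,
    NoiseModel,
    SpeciesPreset,
    build_presets,
    generate_digest_series,
    generate_ms1,
    generate_msn,
)


class TestPresets:
    def test_five_species(self, presets):
        assert set(presets) == {"atlantic-salmon", "arctic-char",
                                "shortnose-sturgeon", "atlantic-sturgeon",
                                "channel-catfish"}

    def test_abundances_sum_to_100(self, presets):
        for p in presets.values():
            assert sum(g.abundance for g in p.glycans) == pytest.approx(100.0)

    def test_all_glycans_satisfy_core_constraint(self, presets):
        for p in presets.values():
            for g in p.glycans:
                assert parse_topology(g.topology).composition() \
                    .is_nglycan_plausible()

    @pytest.mark.parametrize("species,expected_disa", [
        ("arctic-char", 5.0), ("atlantic-salmon", 2.0)])
    def test_disa_prevalence(self, presets, species, expected_disa):
        total = sum(
            g.abundance for g in presets[species].glycans
            if (detect_disa(parse_topology(g.topology).composition()) or 0) >= 1)
        assert total == pytest.approx(expected_disa)

    def test_tetrasialylated_trace_abundances(self, presets):
        tetra = C(neuac=4, hex=6, hexnac=5)
        sal = {parse_topology(g.topology).composition(): g.abundance
               for g in presets["atlantic-salmon"].glycans}
        char = {parse_topology(g.topology).composition(): g.abundance
                for g in presets["arctic-char"].glycans}
        assert sal[tetra] == pytest.approx(0.38)
        assert char[tetra] == pytest.approx(0.12)

    def test_catfish_top_glycan(self, presets):
        top = max(presets["channel-catfish"].glycans, key=lambda g: g.abundance)
        assert parse_topology(top.topology).composition() == \
            C(neuac=2, hex=7, hexnac=4)
        # the salmonid trisialylated biantennary is absent from catfish
        comps = {parse_topology(g.topology).composition()
                 for g in presets["channel-catfish"].glycans}
        assert C(neuac=3, hex=5, hexnac=4) not in comps

    def test_core_fucose_split_between_sturgeons(self, presets):
        def fuc_total(name):
            return sum(g.abundance for g in presets[name].glycans
                       if parse_topology(g.topology).composition().dhex >= 1)
        assert fuc_total("shortnose-sturgeon") > 40.0
        assert fuc_total("atlantic-sturgeon") == pytest.approx(2.0)

    def test_json_round_trip(self, presets):
        p = presets["arctic-char"]
        assert SpeciesPreset.from_json(p.to_json()) == p


class TestGenerateMs1:
    def test_deterministic(self, presets):
        a, _ = generate_ms1(presets["atlantic-salmon"], seed=7)
        b, _ = generate_ms1(presets["atlantic-salmon"], seed=7)
        assert [(p.mz, p.intensity) for p in a.peaks] == \
            [(p.mz, p.intensity) for p in b.peaks]

    def test_different_seeds_differ(self, presets):
        a, _ = generate_ms1(presets["atlantic-salmon"], seed=7)
        b, _ = generate_ms1(presets["atlantic-salmon"], seed=8)
        assert [p.mz for p in a.peaks] != [p.mz for p in b.peaks]

    def test_zero_noise_mz_exact(self, salmon_clean):
        peaklist, _ = salmon_clean
        target = 1408.18812  # biantennary disialylated, 2+, A+1
        assert any(abs(p.mz - target) < 1e-5 for p in peaklist.peaks)

    def test_dp4_standard_spiked(self, salmon_clean):
        peaklist, truth = salmon_clean
        assert any(abs(p.mz - DP4_MZ_THEORETICAL) < 1e-6 for p in peaklist)
        assert truth.dp4_spike_fraction == 0.05

    def test_ground_truth_records_all_glycans(self, salmon_clean, presets):
        _, truth = salmon_clean
        assert len(truth.glycans) == len(presets["atlantic-salmon"].glycans)
        assert any(g["abundance_from_study"] for g in truth.glycans)

    def test_native_ladder_spacing(self, presets):
        peaklist, _ = generate_ms1(presets["arctic-char"], mode="native-",
                                   seed=3, noise=NoiseModel.silent())
        mzs = np.array(sorted(p.mz for p in peaklist.peaks))
        # the A2S2 base and +1 OAc rungs at 2-: spacing 42.01057/2
        m = (C(neuac=2, hex=5, hexnac=4),)
        from fishglycomics.mass_engine import neutral_mass
        base = (neutral_mass(m[0], "native") - 2 * 1.00728) / 2
        for n in range(4):
            rung = base + n * 42.01057 / 2
            assert np.min(np.abs(mzs - rung)) < 1e-6

    def test_faithful_recovery_with_noise_off(self, salmon_clean, config):
        from fishglycomics.pipeline import run_pipeline
        peaklist, truth = salmon_clean
        result = run_pipeline(config, peaklist)
        rec = {str(e.composition): e.abundance for e in result.profile.entries}
        for g in truth.glycans:
            assert rec[g["composition"]] == pytest.approx(g["abundance"],
                                                          abs=1e-6)

    def test_bad_mode_rejected(self, presets):
        with pytest.raises(ValueError):
            generate_ms1(presets["arctic-char"], mode="magic", seed=0)


class TestGenerateMsn:
    def test_catfish_epitope_noise_free(self, topologies):
        obs = generate_msn(topologies["catfish_epitope"], (2, 3), seed=0)
        assert any(abs(f - 1051.5) < 0.05 for f in obs.fragments)
        assert any(abs(f - 676.32) < 0.05 for f in obs.fragments)

    def test_full_dropout_empties_list(self, topologies):
        obs = generate_msn(topologies["catfish_epitope"], (2, 3), seed=0,
                           dropout=1.0)
        assert obs.fragments == []

    def test_seed_reproducibility(self, topologies):
        a = generate_msn(topologies["branched_hex3"], (2, 3), seed=5,
                         dropout=0.3, spurious_rate=0.2)
        b = generate_msn(topologies["branched_hex3"], (2, 3), seed=5,
                         dropout=0.3, spurious_rate=0.2)
        assert a.fragments == b.fragments


class TestDigestSeries:
    def test_empty_enzyme_list(self, presets):
        pls, truths = generate_digest_series(presets["shortnose-sturgeon"],
                                             [], seed=2,
                                             noise=NoiseModel.silent())
        assert len(pls) == 1 and len(truths) == 1

    def test_shortnose_alpha_shift(self, presets):
        _, truths = generate_digest_series(
            presets["shortnose-sturgeon"], [ALPHA_GALACTOSIDASE], seed=2,
            noise=NoiseModel.silent())
        after = {g["composition"] for g in truths[1].glycans}
        # the large tetra-antennary glycan loses its two alpha-Gal
        assert "NeuAc1dHex1Hex8HexNAc6" in after

    def test_catfish_beta_resistance(self, presets):
        _, truths = generate_digest_series(
            presets["channel-catfish"], [BETA_GALACTOSIDASE], seed=2,
            noise=NoiseModel.silent())
        before = {g["topology"]: g["composition"] for g in truths[0].glycans}
        after = {g["topology"]: g["composition"] for g in truths[1].glycans}
        # the fully sialylated (branch-blocked) glycan is unshifted
        cat_top = max(presets["channel-catfish"].glycans,
                      key=lambda g: g.abundance).topology
        assert "NeuAc2Hex7HexNAc4" in before.values()
        assert any(c == "NeuAc2Hex7HexNAc4" for c in after.values())
        # the nonsialylated GalGal glycan loses 4 Hex
        assert "Hex3HexNAc4" in after.values()

    def test_partial_digestion_probability(self, presets):
        _, full = generate_digest_series(
            presets["shortnose-sturgeon"], [ALPHA_GALACTOSIDASE], seed=2,
            noise=NoiseModel.silent(), partial_probability=1.0)
        _, none = generate_digest_series(
            presets["shortnose-sturgeon"], [ALPHA_GALACTOSIDASE], seed=2,
            noise=NoiseModel.silent(), partial_probability=0.0)
        assert {g["composition"] for g in none[1].glycans} == \
            {g["composition"] for g in none[0].glycans}
        assert {g["composition"] for g in full[1].glycans} != \
            {g["composition"] for g in full[0].glycans}
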