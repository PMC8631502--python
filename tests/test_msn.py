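"""MSn fragment prediction, topology scoring, di-SA detection, MGF I/O."""

import pytest
from hypothesis import given, settings, strategies as st

from fishglycomics.glycan_model import GlycanNode, GlycanTopology, \
    MonosaccharideComposition as C, parse_topology
from fishglycomics.mass_engine import b_fragment_mz, round_mz
from fishglycomics.msn import (
    FragmentObservation,
    detect_disa,
    discriminating_fragments,
    predict_fragments,
    predicted_mz_set,
    read_mgf,
    score_topologies,
    write_mgf,
)


class TestPredictFragments:
    def test_catfish_epitope_signature_ions(self, topologies):
        mzs = predicted_mz_set(topologies["catfish_epitope"], 3,
                               precursor_is_b=True)
        # intact sialylated B-ion and its NeuAc-loss product
        assert 1051.5 in mzs and 676.3 in mzs

    def test_single_residue_has_no_fragments(self):
        assert predict_fragments(parse_topology("GlcNAc")) == []

    def test_branched_vs_linear_sets_differ(self, topologies):
        only_br, only_ln = discriminating_fragments(
            topologies["branched_hex3"], topologies["linear_hex3"],
            precursor_is_b=True)
        assert only_br and only_ln
        # a Hex2 chain B-ion exists only in the linear form
        assert round_mz(2 * 204.09977 + 14.01565 + 22.98977, 1) in only_ln

    def test_disa_b_ion_predicted_for_disa_antenna(self, topologies):
        assert 759.4 in predicted_mz_set(topologies["disa_antenna"], 3,
                                         precursor_is_b=True)

    def test_fragment_mz_consistent_with_composition_arithmetic(self,
                                                                topologies):
        # tree-walk prediction must agree with the composition-level
        # B-fragment formula for every emitted ion (dual-route check)
        for frag in predict_fragments(topologies["catfish_mixed"], 3,
                                      precursor_is_b=True):
            assert frag.mz == pytest.approx(
                b_fragment_mz(frag.composition, frag.n_scars), abs=1e-9)

    def test_size_limit(self):
        big = parse_topology("Gal(b1-4)" * 31 + "GlcNAc")
        with pytest.raises(ValueError):
            predict_fragments(big)


class TestScoring:
    def test_generating_topology_ranks_first(self, topologies):
        obs = FragmentObservation(
            stage=3, precursor_mz=894.43, precursor_charge=1,
            fragments=sorted(predicted_mz_set(topologies["branched_hex3"], 2,
                                              precursor_is_b=True)))
        ranked, warn = score_topologies(
            [topologies["linear_hex3"], topologies["branched_hex3"]], obs,
            precursor_is_b=True)
        assert not warn
        assert ranked[0].topology == topologies["branched_hex3"]

    def test_exact_observation_scores_maximal(self, topologies):
        cand = topologies["catfish_epitope"]
        obs = FragmentObservation(
            stage=3, precursor_mz=1051.5, precursor_charge=1,
            fragments=[f.mz for f in predict_fragments(cand, 3,
                                                       precursor_is_b=True)])
        ranked, _ = score_topologies(
            [cand, topologies["sturgeon_epitope"]], obs,
            max_cleavages=3, precursor_is_b=True)
        assert ranked[0].topology == cand
        assert ranked[0].unexplained_observed == 0

    def test_disa_discriminated_from_two_singly_sialylated(self):
        disa = parse_topology(
            "NeuAc(a2-8)NeuAc(a2-3)Gal(b1-4)GlcNAc(b1-2)Man(a1-3)"
            "[NeuAc(a2-3)Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]"
            "Man(b1-4)GlcNAc(b1-4)GlcNAc")
        # same composition, all three NeuAc on separate antennae
        spread = parse_topology(
            "NeuAc(a2-3)Gal(b1-4)GlcNAc(b1-2)[NeuAc(a2-6)GlcNAc(b1-4)]Man(a1-3)"
            "[NeuAc(a2-3)Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]"
            "Man(b1-4)GlcNAc(b1-4)GlcNAc")
        obs = FragmentObservation(
            stage=2, precursor_mz=1066.85, precursor_charge=3,
            fragments=[759.35])       # the NeuAc-NeuAc B-ion
        ranked, _ = score_topologies([spread, disa], obs)
        assert ranked[0].topology == disa

    def test_all_zero_scores_warn(self, topologies):
        obs = FragmentObservation(stage=2, precursor_mz=2000.0,
                                  precursor_charge=1, fragments=[123.4])
        ranked, warn = score_topologies([topologies["linear_hex3"]], obs)
        assert warn

    def test_needs_candidates(self):
        obs = FragmentObservation(stage=2, precursor_mz=1.0,
                                  precursor_charge=1, fragments=[])
        with pytest.raises(ValueError):
            score_topologies([], obs)


# scoring sanity over random topologies: the generating topology never loses
_residues = st.sampled_from(["Gal", "Man", "GlcNAc", "Fuc", "NeuAc"])


def _rand_tree(depth):
    node = st.builds(GlycanNode, residue=_residues,
                     anomer=st.sampled_from(["a", "b"]))
    if depth == 0:
        return node
    return st.builds(
        lambda n, ch: GlycanNode(n.residue, n.anomer, children=ch),
        node, st.lists(_rand_tree(depth - 1), max_size=2))


@settings(max_examples=40, derandomize=True, deadline=None)
@given(_rand_tree(3), _rand_tree(3))
def test_generating_topology_never_outranked(a, b):
    ta, tb = GlycanTopology(a), GlycanTopology(b)
    if ta.n_residues < 2 or ta == tb:
        return
    obs = FragmentObservation(
        stage=2, precursor_mz=5000.0, precursor_charge=1,
        fragments=sorted(predicted_mz_set(ta, 2)))
    if not obs.fragments:
        return
    ranked, warn = score_topologies([tb, ta], obs, max_cleavages=2)
    if warn:
        return
    best = max(s.score for s in ranked)
    mine = next(s.score for s in ranked if s.topology == ta)
    assert mine == best


class TestDetectDisa:
    @pytest.mark.parametrize("comp,expected", [
        (C(neuac=3, hex=5, hexnac=4), 1),   # trisialylated biantennary
        (C(neuac=2, hex=5, hexnac=4), 0),
        (C(neuac=4, hex=6, hexnac=5), 1),   # tetrasialylated triantennary
    ])
    def test_complex_type(self, comp, expected):
        assert detect_disa(comp) == expected

    def test_high_mannose_not_applicable(self):
        assert detect_disa(C(hex=9, hexnac=2)) is None

    def test_explicit_antenna_count_overrides(self):
        assert detect_disa(C(neuac=3, hex=5, hexnac=4), antennae=3) == 0


class TestMgf:
    def test_round_trip(self, tmp_path):
        obs = [FragmentObservation(stage=3, precursor_mz=1051.5,
                                   precursor_charge=1,
                                   fragments=[676.32, 398.18],
                                   title="catfish epitope MS3")]
        path = tmp_path / "frags.mgf"
        write_mgf(obs, path)
        back = read_mgf(path)
        assert len(back) == 1
        assert back[0].stage == 3
        assert back[0].precursor_mz == pytest.approx(1051.5)
        assert back[0].fragments == pytest.approx([398.18, 676.32]) or \
            back[0].fragments == pytest.approx([676.32, 398.18])
        assert back[0].title == "catfish epitope MS3"

    def test_malformed_reports_line(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text("BEGIN IONS\nTITLE=x\n12.3 bad extra\nEND IONS\n")
        back = read_mgf(path)  # "12.3 bad" parses m/z then ignores rest
        assert back[0].fragments == [12.3]
        path.write_text("BEGIN IONS\n1x2.3 1.0\nEND IONS\n")
        with pytest.raises(ValueError, match="line 2"):
            read_mgf(path)
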