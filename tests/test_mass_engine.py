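"""Mass, isotope, ion and fragment arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fishglycomics.glycan_model import MonosaccharideComposition as C
from fishglycomics.mass_engine import (
    ISOTOPE_ABUNDANCE,
    ElementalFormula,
    IonSpecies,
    b_fragment_mz,
    elemental_formula,
    ion_mz,
    isotope_distribution,
    most_abundant_ion_mz,
    most_abundant_k,
    neutral_loss,
    neutral_mass,
    round_mz,
)


class TestNeutralMass:
    def test_biantennary_disialylated_permethylated(self):
        assert neutral_mass(C(neuac=2, hex=5, hexnac=4)) == pytest.approx(
            2769.3934, abs=1e-3)

    def test_empty_composition_is_end_group(self):
        assert neutral_mass(C()) == pytest.approx(46.0419, abs=1e-3)

    def test_native_with_oacetyl(self):
        m = neutral_mass(C(neuac=2, hex=5, hexnac=4, oacetyl=1), "native")
        assert m == pytest.approx(2264.7936, abs=1e-3)

    def test_oacetyl_incompatible_with_permethylation(self):
        with pytest.raises(ValueError, match="[Oo]-acetyl"):
            neutral_mass(C(neuac=1, oacetyl=1), "permethylated")


class TestElementalFormula:
    def test_hex_permethylated(self):
        assert elemental_formula(C(hex=1)) == ElementalFormula(C=11, H=22, O=6)

    def test_empty_native_is_water(self):
        assert elemental_formula(C(), "native") == ElementalFormula(H=2, O=1)

    def test_shortnose_glycan_carbon_count(self):
        f = elemental_formula(C(neuac=1, dhex=1, hex=10, hexnac=6))
        assert f.C == 182

    @pytest.mark.parametrize("comp,derivatization", [
        (C(neuac=2, hex=5, hexnac=4), "permethylated"),
        (C(neuac=3, hex=6, hexnac=5, dhex=1), "permethylated"),
        (C(neuac=2, hex=5, hexnac=4, oacetyl=3), "native"),
    ])
    def test_formula_mass_matches_neutral_mass(self, comp, derivatization):
        f = elemental_formula(comp, derivatization)
        assert f.mass == pytest.approx(neutral_mass(comp, derivatization),
                                       abs=1e-3)


# ----------------------------------------------------------------------
# Isotopes: independent brute-force oracle
# ----------------------------------------------------------------------

def brute_force_isotopes(formula: ElementalFormula, depth: int) -> np.ndarray:
    """Multiply the isotope polynomial one atom at a time (pure Python)."""
    poly = [1.0]
    for el in ("C", "H", "N", "O", "Na"):
        for _ in range(getattr(formula, el)):
            p = ISOTOPE_ABUNDANCE[el]
            new = [0.0] * min(depth + 1, len(poly) + len(p) - 1)
            for i, a in enumerate(poly):
                for j, b in enumerate(p):
                    if i + j <= depth:
                        new[i + j] += a * b
            poly = new
    out = np.zeros(depth + 1)
    out[: len(poly)] = poly
    return out / out[0]


class TestIsotopeDistribution:
    def test_zero_atoms(self):
        dist = isotope_distribution(ElementalFormula(), 3)
        assert dist[0] == 1.0 and np.all(dist[1:] == 0)

    def test_small_molecule_first_isotopologue(self):
        # permethylation end group C2H6O: A+1 from 2x13C + 6x2H + 17O
        dist = isotope_distribution(ElementalFormula(C=2, H=6, O=1), 2)
        oracle = brute_force_isotopes(ElementalFormula(C=2, H=6, O=1), 2)
        assert dist[1] == pytest.approx(oracle[1], rel=1e-9)
        assert dist[1] == pytest.approx(0.0226, abs=5e-4)

    def test_biantennary_top_is_a_plus_one(self):
        assert most_abundant_k(C(neuac=2, hex=5, hexnac=4)) == 1

    @settings(max_examples=120, derandomize=True)
    @given(st.builds(ElementalFormula, C=st.integers(0, 12),
                     H=st.integers(0, 12), N=st.integers(0, 3),
                     O=st.integers(0, 6), Na=st.integers(0, 1)))
    def test_matches_brute_force_oracle(self, formula):
        depth = 4
        dist = isotope_distribution(formula, depth)
        oracle = brute_force_isotopes(formula, depth)
        assert np.allclose(dist, oracle, rtol=1e-9, atol=1e-12)


# ----------------------------------------------------------------------
# Ion m/z
# ----------------------------------------------------------------------

class TestIonMz:
    @pytest.mark.parametrize("comp,z,k,expected", [
        (C(neuac=2, hex=5, hexnac=4), 2, 1, 1408.19),
        (C(neuac=2, hex=5, hexnac=4), 3, 1, 946.46),
        (C(neuac=2, hex=7, hexnac=4), 3, 1, 1082.52),
        (C(neuac=3, hex=5, hexnac=4), 3, 1, 1066.85),
        (C(neuac=3, hex=6, hexnac=5), 3, 1, 1216.59),
        (C(neuac=4, hex=6, hexnac=5), 3, 1, 1336.98),
        (C(), 1, 0, 69.03),
    ])
    def test_sodiated_positive_mode(self, comp, z, k, expected):
        mz = ion_mz(comp, IonSpecies(charge=z, k=k))
        assert round_mz(mz) == expected

    def test_polarity_derivatization_mismatch(self):
        with pytest.raises(ValueError):
            IonSpecies(derivatization="native", polarity="+")
        with pytest.raises(ValueError):
            IonSpecies(derivatization="permethylated", polarity="-")

    def test_charge_consistency(self):
        # neutral+k mass recovered from any charge state agrees to 1e-6
        comp = C(neuac=3, hex=6, hexnac=5)
        recovered = {
            round(ion_mz(comp, IonSpecies(charge=z, k=2)) * z - z * 22.98977, 6)
            for z in (1, 2, 3, 4)}
        assert len(recovered) == 1

    @pytest.mark.parametrize("comp,z,expected,k_expected", [
        (C(neuac=3, hex=10, hexnac=6), 4, 1183.82, 2),
        (C(neuac=1, hex=7, hexnac=4), 3, 962.13, 1),
        (C(neuac=1, hex=7, hexnac=4), 2, 1431.70, 1),
    ])
    def test_most_abundant_ion(self, comp, z, expected, k_expected):
        assert most_abundant_k(comp) == k_expected
        assert round_mz(most_abundant_ion_mz(comp, charge=z)) == expected

    def test_small_glycan_top_is_monoisotopic(self):
        assert most_abundant_k(C(hex=1)) == 0


# ----------------------------------------------------------------------
# Fragments
# ----------------------------------------------------------------------

class TestFragments:
    @pytest.mark.parametrize("comp,scars,expected", [
        (C(hex=3, hexnac=1), 0, 894.43),
        (C(hex=2, hexnac=1), 0, 690.33),
        (C(hex=2, hexnac=1), 1, 676.32),
        (C(neuac=1, hex=2, hexnac=1), 0, 1051.50),
        (C(neuac=2), 0, 759.35),           # di-SA B-ion
    ])
    def test_b_fragment(self, comp, scars, expected):
        assert round_mz(b_fragment_mz(comp, scars)) == expected

    def test_excess_scars_rejected(self):
        with pytest.raises(ValueError):
            b_fragment_mz(C(), 10)

    @pytest.mark.parametrize("kind,expected", [
        ("NeuAc", 375.19), ("Hex", 218.12)])
    def test_neutral_loss(self, kind, expected):
        assert round_mz(neutral_loss(kind)) == expected

    def test_neutral_loss_per_charge(self):
        # NeuAc loss at 3+ shifts m/z by ~125.06 (e.g. 1388.02 -> 1263.00)
        assert round_mz(neutral_loss("NeuAc") / 3) == 125.06

    def test_unknown_residue(self):
        with pytest.raises(ValueError, match="Pent"):
            neutral_loss("Pent")


# ----------------------------------------------------------------------
# Structural mass properties
# ----------------------------------------------------------------------

_comps = st.builds(C, neuac=st.integers(0, 4), hex=st.integers(1, 10),
                   hexnac=st.integers(0, 6), dhex=st.integers(0, 3))


@settings(max_examples=60, derandomize=True)
@given(_comps)
def test_hex_removal_shifts_permethylated_mass_exactly(comp):
    less = C(comp.neuac, comp.neugc, comp.kdn, comp.hex - 1, comp.hexnac,
             comp.dhex)
    assert neutral_mass(comp) - neutral_mass(less) == pytest.approx(
        204.09977, abs=1e-9)


@settings(max_examples=60, derandomize=True)
@given(_comps, st.sampled_from(["neuac", "hex", "hexnac", "dhex"]))
def test_neutral_mass_strictly_increasing(comp, slot):
    import dataclasses
    more = dataclasses.replace(comp, **{slot: getattr(comp, slot) + 1})
    assert neutral_mass(more) > neutral_mass(comp)


def test_round_half_up():
    assert round_mz(1066.845) == 1066.85
    assert round_mz(946.4551) == 946.46
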