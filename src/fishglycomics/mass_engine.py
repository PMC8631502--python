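"""Exact-mass, isotopic, adduct and fragment arithmetic for glycan ions.

Conventions modelled after direct-infusion NSI-MS practice for serum
N-glycans:

* permethylated glycans fly in positive mode as sodiated ions
  ``[M + zNa]z+`` with z = 1..4;
* native (underivatized) glycans fly in negative mode as deprotonated ions
  ``[M - zH]z-`` and retain base-labile O-acetyl groups;
* observed profile peaks usually correspond to the *most abundant*
  isotopologue (A+1 around 2.7-3.6 kDa, A+2 at >= 4 kDa), not the
  monoisotopic one, so every m/z routine takes an explicit isotopologue
  index ``k`` (extra neutrons over monoisotopic) and a most-abundant-k
  convenience is provided;
* MSn fragments of permethylated glycans are B-type sodiated oxocarbenium
  ions; a glycosidic cleavage leaves the leaving (non-reducing) group fully
  methylated while the retained side keeps an unmethylated hydroxyl "scar"
  worth -CH2 relative to full methylation.

m/z values are displayed to two decimals with half-up rounding, matching
instrument-software output.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache

import numpy as np

from .glycan_model import (
    CH2,
    END_GROUP_NATIVE,
    END_GROUP_PERME,
    NA,
    NEUTRON_SHIFT,
    OACETYL,
    PROTON,
    RESIDUE_TABLE,
    MonosaccharideComposition,
    residue_class,
)

__all__ = [
    "IonSpecies",
    "ElementalFormula",
    "neutral_mass",
    "elemental_formula",
    "isotope_distribution",
    "ion_mz",
    "most_abundant_k",
    "most_abundant_ion_mz",
    "b_fragment_mz",
    "neutral_loss",
    "round_mz",
    "constants_table",
]

# monoisotopic atomic masses (Da)
ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "Na": 22.98976928,
}

# isotopic abundance vectors indexed by extra neutrons, light isotope first
ISOTOPE_ABUNDANCE = {
    "C": (0.9893, 0.0107),            # 12C, 13C
    "H": (0.999885, 0.000115),        # 1H, 2H
    "N": (0.99636, 0.00364),          # 14N, 15N
    "O": (0.99757, 0.00038, 0.00205),  # 16O, 17O, 18O
    "Na": (1.0,),
}

MAX_CHARGE = 4
MAX_ISOTOPOLOGUE = 6


def round_mz(mz: float, ndigits: int = 2) -> float:
    """Round half-up to *ndigits* decimals (instrument display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(mz)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IonSpecies:
    """Ion descriptor: derivatization, polarity, charge and isotopologue.

    Positive mode pairs with permethylation and per-charge sodiation;
    negative mode pairs with native glycans and per-charge proton loss.
    """

    derivatization: str = "permethylated"   # "permethylated" | "native"
    polarity: str = "+"                     # "+" | "-"
    charge: int = 1
    k: int = 0                              # extra neutrons over monoisotopic

    def __post_init__(self) -> None:
        if self.derivatization not in ("permethylated", "native"):
            raise ValueError(f"unknown derivatization {self.derivatization!r}")
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        if not 1 <= self.charge <= MAX_CHARGE:
            raise ValueError(f"charge must be in 1..{MAX_CHARGE}, got {self.charge}")
        if not 0 <= self.k <= MAX_ISOTOPOLOGUE:
            raise ValueError(f"isotopologue index must be in 0..{MAX_ISOTOPOLOGUE}")
        if self.polarity == "+" and self.derivatization != "permethylated":
            raise ValueError("positive-mode sodiated ions require permethylation")
        if self.polarity == "-" and self.derivatization != "native":
            raise ValueError("negative-mode deprotonated ions require native glycans")


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition over C/H/N/O/Na; addition is componentwise."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    Na: int = 0

    def __post_init__(self) -> None:
        for el in ("C", "H", "N", "O", "Na"):
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count")

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(*(getattr(self, e) + getattr(other, e)
                                  for e in ("C", "H", "N", "O", "Na")))

    @property
    def mass(self) -> float:
        return sum(ATOMIC_MASS[e] * getattr(self, e) for e in ("C", "H", "N", "O", "Na"))

    @property
    def n_atoms(self) -> int:
        return self.C + self.H + self.N + self.O + self.Na

    def as_dict(self) -> dict[str, int]:
        return {e: getattr(self, e) for e in ("C", "H", "N", "O", "Na") if getattr(self, e)}

    def __str__(self) -> str:
        return "".join(f"{e}{n}" for e, n in self.as_dict().items())


_END_FORMULA = {
    "native": ElementalFormula(H=2, O=1),
    "permethylated": ElementalFormula(C=2, H=6, O=1),
}
_OAC_FORMULA = ElementalFormula(C=2, H=2, O=1)


def _check_derivatization(comp: MonosaccharideComposition, derivatization: str) -> None:
    if derivatization not in ("permethylated", "native"):
        raise ValueError(f"unknown derivatization {derivatization!r}")
    if derivatization == "permethylated" and comp.oacetyl:
        raise ValueError(
            "O-acetyl groups are incompatible with permethylation: the reaction "
            "removes base-labile modifications; analyze native glycans instead")


def residue_mass(kind: str, derivatization: str = "permethylated") -> float:
    """Residue (dehydro-monosaccharide) mass for a residue kind or class."""
    entry = RESIDUE_TABLE[residue_class(kind) if kind not in RESIDUE_TABLE else kind]
    if derivatization == "permethylated":
        return entry.mass + entry.perme_sites * CH2
    return entry.mass


def neutral_mass(comp: MonosaccharideComposition, derivatization: str = "permethylated") -> float:
    """Monoisotopic neutral mass of a free-reducing glycan.

    Sum of residue masses plus the reducing/non-reducing end-group constant
    (+H2O native, +C2H6O permethylated), plus 42.01057 Da per O-acetyl group
    (native only).
    """
    _check_derivatization(comp, derivatization)
    total = 0.0
    for slot in ("neuac", "neugc", "kdn", "hex", "hexnac", "dhex"):
        n = getattr(comp, slot)
        if n:
            total += n * residue_mass(slot, derivatization)
    total += END_GROUP_PERME if derivatization == "permethylated" else END_GROUP_NATIVE
    total += comp.oacetyl * OACETYL
    return total


def elemental_formula(comp: MonosaccharideComposition,
                      derivatization: str = "permethylated") -> ElementalFormula:
    """Elemental formula of the neutral glycan; mass-consistent with
    :func:`neutral_mass` to better than 1e-3 Da."""
    _check_derivatization(comp, derivatization)
    out = _END_FORMULA[derivatization]
    for slot in ("neuac", "neugc", "kdn", "hex", "hexnac", "dhex"):
        n = getattr(comp, slot)
        if not n:
            continue
        entry = RESIDUE_TABLE[slot]
        f = ElementalFormula(**entry.formula)
        if derivatization == "permethylated":
            f = f + ElementalFormula(C=entry.perme_sites, H=2 * entry.perme_sites)
        for _ in range(n):
            out = out + f
    for _ in range(comp.oacetyl):
        out = out + _OAC_FORMULA
    return out


# ----------------------------------------------------------------------
# Isotopes
# ----------------------------------------------------------------------

def _poly_power(p: np.ndarray, n: int, depth: int) -> np.ndarray:
    """p(x)^n truncated to degree *depth*, by squaring."""
    result = np.zeros(depth + 1)
    result[0] = 1.0
    base = np.zeros(depth + 1)
    base[: len(p)] = p[: depth + 1]
    while n:
        if n & 1:
            result = np.convolve(result, base)[: depth + 1]
        n >>= 1
        base = np.convolve(base, base)[: depth + 1]
    return result


def isotope_distribution(formula: ElementalFormula, depth: int = 4) -> np.ndarray:
    """Relative isotopologue abundances for k = 0..depth.

    Computed by per-element convolution of the isotope polynomials using
    standard terrestrial abundances, then normalized so the monoisotopic
    peak (k = 0) is 1.  A formula with zero atoms returns ``[1, 0, ...]``.
    """
    if depth > MAX_ISOTOPOLOGUE:
        raise ValueError(f"depth must be <= {MAX_ISOTOPOLOGUE}")
    dist = np.zeros(depth + 1)
    dist[0] = 1.0
    for el in ("C", "H", "N", "O", "Na"):
        n = getattr(formula, el)
        if n:
            dist = np.convolve(dist, _poly_power(
                np.asarray(ISOTOPE_ABUNDANCE[el]), n, depth))[: depth + 1]
    if dist[0] <= 0:
        return dist
    return dist / dist[0]


@lru_cache(maxsize=4096)
def mono_visibility(comp: MonosaccharideComposition,
                    derivatization: str = "permethylated") -> float:
    """Predicted intensity of the monoisotopic peak relative to A+1.

    Large glycans bury their monoisotopic peak (the ratio falls with size);
    assignment uses this to judge whether a "monoisotopic member missing"
    hypothesis is credible for a candidate composition.
    """
    dist = isotope_distribution(elemental_formula(comp, derivatization), 1)
    return float(dist[0] / dist[1]) if dist[1] > 0 else float("inf")


@lru_cache(maxsize=4096)
def most_abundant_k(comp: MonosaccharideComposition,
                    derivatization: str = "permethylated",
                    depth: int = 4) -> int:
    """Isotopologue index of the most intense peak; ties go to smaller k."""
    dist = isotope_distribution(elemental_formula(comp, derivatization), depth)
    return int(np.argmax(dist))  # argmax returns the first (smallest) maximizer


# ----------------------------------------------------------------------
# Ion m/z
# ----------------------------------------------------------------------

def ion_mz(comp: MonosaccharideComposition, ion: IonSpecies) -> float:
    """m/z of the given ion species (unrounded).

    Positive: ``(M + k*1.00336 + z*22.98977) / z``;
    negative: ``(M + k*1.00336 - z*1.00728) / z``.
    """
    m = neutral_mass(comp, ion.derivatization) + ion.k * NEUTRON_SHIFT
    if ion.polarity == "+":
        return (m + ion.charge * NA) / ion.charge
    return (m - ion.charge * PROTON) / ion.charge


def most_abundant_ion_mz(comp: MonosaccharideComposition,
                         derivatization: str = "permethylated",
                         charge: int = 1, depth: int = 4) -> float:
    """m/z at the most abundant isotopologue — the peak-picking convention
    used when reading profile spectra of large glycans."""
    k = most_abundant_k(comp, derivatization, depth)
    polarity = "+" if derivatization == "permethylated" else "-"
    return ion_mz(comp, IonSpecies(derivatization, polarity, charge, k))


# ----------------------------------------------------------------------
# Fragments (permethylated chemistry, singly charged sodiated B-type ions)
# ----------------------------------------------------------------------

def b_fragment_mz(comp: MonosaccharideComposition, n_scars: int = 0) -> float:
    """Sodiated B-type fragment of a terminal subtree.

    ``n_scars`` counts glycosidic cleavages that left an unmethylated
    hydroxyl on *this* fragment: 0 for an epitope released before
    permethylation or by a single B-cleavage; +1 per subsequent loss of a
    terminal residue from the fragment.
    """
    if comp.oacetyl:
        raise ValueError("B-fragment arithmetic is defined for permethylated glycans")
    total = sum(getattr(comp, slot) * residue_mass(slot, "permethylated")
                for slot in ("neuac", "neugc", "kdn", "hex", "hexnac", "dhex"))
    mz = total + CH2 + NA - n_scars * CH2
    if mz <= 0:
        raise ValueError(f"B-fragment mass is non-positive ({mz:.2f}); "
                         "too many scars for this composition")
    return mz


def neutral_loss(kind: str, derivatization: str = "permethylated") -> float:
    """Mass lost when a terminal residue departs in MSn.

    For permethylated glycans the leaving group retains the glycosidic
    oxygen's methyl, so the loss is residue mass + CH2 and the retained
    fragment gains one scar.
    """
    if derivatization != "permethylated":
        raise ValueError("neutral-loss arithmetic is defined for permethylated glycans")
    return residue_mass(kind, derivatization) + CH2


# ----------------------------------------------------------------------
# Constants export
# ----------------------------------------------------------------------

def constants_table():
    """The full constants/residue table as a DataFrame (for versioned export)."""
    import pandas as pd

    rows = [
        {"name": "CH2", "value": CH2, "kind": "constant"},
        {"name": "Na", "value": NA, "kind": "constant"},
        {"name": "proton", "value": PROTON, "kind": "constant"},
        {"name": "neutron_shift_13C", "value": NEUTRON_SHIFT, "kind": "constant"},
        {"name": "O-acetyl", "value": OACETYL, "kind": "constant"},
        {"name": "end_group_native", "value": END_GROUP_NATIVE, "kind": "constant"},
        {"name": "end_group_permethylated", "value": END_GROUP_PERME, "kind": "constant"},
    ]
    for name, entry in RESIDUE_TABLE.items():
        rows.append({
            "name": name, "value": entry.mass, "kind": "residue",
            "formula": str(ElementalFormula(**entry.formula)),
            "perme_sites": entry.perme_sites,
            "permethylated_mass": entry.mass + entry.perme_sites * CH2,
        })
    return pd.DataFrame(rows)
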