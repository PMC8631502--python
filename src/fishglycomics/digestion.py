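"""In-silico exoglycosidase digestion.

Two views of a digestion experiment:

* topology level — :func:`apply_enzyme` / :func:`sequential_digest` trim
  eligible terminal residues from a glycan tree under enzyme specificity and
  branch-blocking rules;
* composition level — :func:`interpret_shift` reads an observed before/after
  composition pair and reports whether the mass shift is consistent with the
  enzyme used.

Blocking semantics: a terminal residue is removable only if it is a leaf and
its parent carries no other substituent from the rule's blocker set.  This
encodes the two cases demonstrated experimentally: a branching sialic acid
protects the GalβGalβ cap from β-galactosidase, and a branching α-Gal blocks
the inner β-Gals of the Galα(Galβ)Galβ cap until α-galactosidase has acted —
which is why α is applied before β.
"""

from __future__ import annotations

from dataclasses import dataclass

from .glycan_model import (
    GlycanNode,
    GlycanTopology,
    MonosaccharideComposition,
    residue_class,
)

__all__ = [
    "DigestRule",
    "ALPHA_GALACTOSIDASE",
    "BETA_GALACTOSIDASE",
    "ENZYMES",
    "apply_enzyme",
    "sequential_digest",
    "DigestStep",
    "interpret_shift",
    "ShiftReport",
]


@dataclass(frozen=True)
class DigestRule:
    """Specificity of one exoglycosidase.

    *removable* names the residue kinds cleaved; *anomer* the required
    anomeric configuration of the bond to the parent; *blockers* the
    (residue kind, anomer) substituents on the parent that protect the
    target.  Anomer ``"?"`` in a blocker matches any configuration.
    """

    enzyme: str
    removable: frozenset[str] = frozenset({"Gal"})
    anomer: str = "b"
    blockers: frozenset[tuple[str, str]] = frozenset()

    def blocks(self, sibling: GlycanNode) -> bool:
        return any(
            sibling.residue == kind and (anomer == "?" or sibling.anomer == anomer)
            for kind, anomer in self.blockers)


ALPHA_GALACTOSIDASE = DigestRule(
    enzyme="alpha-galactosidase", removable=frozenset({"Gal"}), anomer="a")
BETA_GALACTOSIDASE = DigestRule(
    enzyme="beta-galactosidase", removable=frozenset({"Gal"}), anomer="b",
    blockers=frozenset({("NeuAc", "?"), ("NeuGc", "?"), ("KDN", "?"), ("Gal", "a")}))

ENZYMES = {r.enzyme: r for r in (ALPHA_GALACTOSIDASE, BETA_GALACTOSIDASE)}
# common short aliases
ENZYMES["alpha-gal"] = ALPHA_GALACTOSIDASE
ENZYMES["beta-gal"] = BETA_GALACTOSIDASE


def _removable_leaves(topology: GlycanTopology, rule: DigestRule) -> list[tuple[GlycanNode, GlycanNode]]:
    """(parent, leaf) pairs eligible for cleavage in the current state."""
    out = []
    for node, parent in topology.nodes_with_parents():
        if parent is None or node.children:
            continue
        if node.residue not in rule.removable or node.anomer != rule.anomer:
            continue
        siblings = [c for c in parent.children if c is not node]
        if any(rule.blocks(s) for s in siblings):
            continue
        out.append((parent, node))
    return out


def apply_enzyme(topology: GlycanTopology, rule: DigestRule,
                 exhaustive: bool = True) -> tuple[GlycanTopology, int]:
    """Digest a topology; returns (product topology, residues removed).

    One pass removes every currently eligible terminal residue; exhaustive
    digestion repeats passes until no residue is eligible (newly exposed
    termini become substrates, so GalβGalβ-HexNAc loses both galactoses).
    The input topology is not modified.
    """
    work = topology.copy()
    removed = 0
    while True:
        eligible = _removable_leaves(work, rule)
        if not eligible:
            break
        for parent, leaf in eligible:
            parent.children.remove(leaf)
            removed += 1
        if not exhaustive:
            break
    return work, removed


@dataclass
class DigestStep:
    enzyme: str
    removed: int
    product: GlycanTopology


def sequential_digest(topology: GlycanTopology,
                      rules: list[DigestRule]) -> list[DigestStep]:
    """Apply each enzyme exhaustively in order, desalting between steps.

    Returns the per-step trace (enzyme, residues removed, intermediate
    product); an empty rule list returns an empty trace and leaves the
    substrate untouched.
    """
    steps: list[DigestStep] = []
    current = topology
    for rule in rules:
        current, n = apply_enzyme(current, rule, exhaustive=True)
        steps.append(DigestStep(rule.enzyme, n, current))
    return steps


# ----------------------------------------------------------------------
# Composition-level shift interpretation
# ----------------------------------------------------------------------

@dataclass
class ShiftReport:
    """Interpretation of an observed before/after composition pair."""

    enzyme: str
    removed: dict[str, int]          # residue class -> count removed
    consistent: bool                 # only enzyme-removable classes lost
    resistant: bool                  # nothing removed
    partial: bool                    # less removed than expected (if known)
    note: str = ""


def interpret_shift(before: MonosaccharideComposition,
                    after: MonosaccharideComposition,
                    rule: DigestRule,
                    expected_removed: int | None = None) -> ShiftReport:
    """Report the residue-count difference and its consistency with *rule*.

    Galactosidases remove hexoses only, so any loss in another residue class
    — or any gain — is flagged inconsistent rather than silently accepted.
    *expected_removed* (e.g. a count of template terminal sites) enables the
    partial-digestion flag used for sterically hindered structures.
    """
    classes = ("neuac", "neugc", "kdn", "hex", "hexnac", "dhex", "oacetyl")
    diff = {c: getattr(before, c) - getattr(after, c) for c in classes}
    removable_classes = {residue_class(k) for k in rule.removable}
    gained = any(v < 0 for v in diff.values())
    wrong_class = any(v > 0 for c, v in diff.items() if c not in removable_classes)
    removed = {c: v for c, v in diff.items() if v > 0}
    total_removed = sum(removed.values())
    consistent = not gained and not wrong_class
    partial = (expected_removed is not None and consistent
               and 0 < total_removed < expected_removed)
    if gained:
        note = "composition gained residues; not a digestion product"
    elif wrong_class:
        note = (f"loss outside {sorted(removable_classes)} is inconsistent "
                f"with {rule.enzyme}")
    elif total_removed == 0:
        note = "resistant (no shift)"
    elif partial:
        note = (f"only {total_removed}/{expected_removed} expected residues "
                "removed; partial digestion (possible steric interference)")
    else:
        note = f"{total_removed} {'/'.join(sorted(removable_classes))} removed, consistent"
    return ShiftReport(
        enzyme=rule.enzyme, removed=removed, consistent=consistent,
        resistant=(total_removed == 0 and consistent), partial=partial, note=note)
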