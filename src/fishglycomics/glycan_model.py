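"""Domain types for serum N-glycan analysis.

The unit of MS1 assignment is a :class:`MonosaccharideComposition` — counts
of the residue *classes* distinguishable by mass alone (Hex, HexNAc, dHex and
the sialic-acid family).  The unit of MSn interpretation and exoglycosidase
digestion is a :class:`GlycanTopology` — a rooted tree of named residues
(Gal/Man/Glc identity is carried on topology nodes but deliberately erased
when reducing to a composition, because MS1 cannot distinguish hexoses;
identity is only ever inferred through enzyme specificity or fragmentation).

Topology strings use an IUPAC-condensed linear code: linkages in parentheses,
branches in square brackets, reducing end (the tree root) rightmost::

    NeuAc(a2-3)Gal(b1-4)GlcNAc
    Gal(a1-?)[Gal(b1-?)]Gal(b1-?)GlcNAc

Anomeric configuration is ``a``, ``b`` or ``?`` (unknown); linkage positions
may be ``?`` and are never required for matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

__all__ = [
    "MonosaccharideComposition",
    "RESIDUE_TABLE",
    "ResidueEntry",
    "GlycanNode",
    "GlycanTopology",
    "EpitopeMotif",
    "MOTIF_LIBRARY",
    "parse_topology",
    "composition_of",
    "match_motif",
]

# residue-class mapping: specific node names -> composition slots
_HEXOSES = {"Hex", "Gal", "Man", "Glc"}
_HEXNACS = {"HexNAc", "GlcNAc", "GalNAc"}
_DEOXYHEXOSES = {"dHex", "Fuc"}
_SIALIC = {"NeuAc", "NeuGc", "KDN"}
KNOWN_RESIDUES = _HEXOSES | _HEXNACS | _DEOXYHEXOSES | _SIALIC


def residue_class(name: str) -> str:
    """Map a residue token (e.g. ``Gal``) to its composition slot (``hex``)."""
    if name in _HEXOSES:
        return "hex"
    if name in _HEXNACS:
        return "hexnac"
    if name in _DEOXYHEXOSES:
        return "dhex"
    if name in _SIALIC:
        return name.lower()
    raise ValueError(f"unknown residue kind: {name!r}")


@dataclass(frozen=True, order=True)
class MonosaccharideComposition:
    """Counts of mass-distinguishable residue classes plus O-acetyl groups.

    O-acetyl groups are ester modifications of sialic-acid hydroxyls
    (+42.01057 Da each); they survive only in native (underivatized) glycans
    because permethylation removes base-labile modifications.
    """

    neuac: int = 0
    neugc: int = 0
    kdn: int = 0
    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    oacetyl: int = 0

    def __post_init__(self) -> None:
        for f in ("neuac", "neugc", "kdn", "hex", "hexnac", "dhex", "oacetyl"):
            v = getattr(self, f)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{f} must be a nonnegative integer, got {v!r}")

    # ------------------------------------------------------------------
    @property
    def sialic(self) -> int:
        """Total sialic-acid residues (NeuAc + NeuGc + KDN)."""
        return self.neuac + self.neugc + self.kdn

    @property
    def n_residues(self) -> int:
        return self.sialic + self.hex + self.hexnac + self.dhex

    def oacetyl_valid(self, cap_per_sialic: int = 3) -> bool:
        """O-acetyl count within the per-sialic-acid cap (default 3/residue)."""
        return self.oacetyl <= cap_per_sialic * self.sialic

    def is_nglycan_plausible(self) -> bool:
        """Chitobiose-trimannosyl core requirement: HexNAc >= 2 and Hex >= 3."""
        return self.hexnac >= 2 and self.hex >= 3

    def without_oacetyl(self) -> "MonosaccharideComposition":
        return replace(self, oacetyl=0)

    def __add__(self, other: "MonosaccharideComposition") -> "MonosaccharideComposition":
        return MonosaccharideComposition(
            *(getattr(self, f) + getattr(other, f) for f in _FIELDS)
        )

    def __str__(self) -> str:
        parts = []
        for label, f in (
            ("NeuAc", "neuac"), ("NeuGc", "neugc"), ("KDN", "kdn"),
            ("dHex", "dhex"), ("Hex", "hex"), ("HexNAc", "hexnac"),
        ):
            n = getattr(self, f)
            if n:
                parts.append(f"{label}{n}")
        if self.oacetyl:
            parts.append(f"OAc{self.oacetyl}")
        return "".join(parts) if parts else "empty"


_FIELDS = ("neuac", "neugc", "kdn", "hex", "hexnac", "dhex", "oacetyl")


# ----------------------------------------------------------------------
# Residue mass / element table
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueEntry:
    """Per-class monoisotopic residue mass, elemental formula, methylation sites."""

    mass: float            # underivatized residue (monosaccharide - H2O), Da
    formula: dict          # element -> count
    perme_sites: int       # free OH/NH positions methylated by permethylation


RESIDUE_TABLE: dict[str, ResidueEntry] = {
    "hex": ResidueEntry(162.05282, {"C": 6, "H": 10, "O": 5}, 3),
    "hexnac": ResidueEntry(203.07937, {"C": 8, "H": 13, "N": 1, "O": 5}, 3),
    "dhex": ResidueEntry(146.05791, {"C": 6, "H": 10, "O": 4}, 2),
    "neuac": ResidueEntry(291.09542, {"C": 11, "H": 17, "N": 1, "O": 8}, 5),
    "neugc": ResidueEntry(307.09033, {"C": 11, "H": 17, "N": 1, "O": 9}, 6),
    "kdn": ResidueEntry(250.06887, {"C": 9, "H": 14, "O": 8}, 6),
}

# mass constants (Da)
CH2 = 14.01565          # methyl increment per permethylation site
NA = 22.98977           # sodium cation
PROTON = 1.00728
NEUTRON_SHIFT = 1.00336  # 13C - 12C; the per-isotopologue m/z step
OACETYL = 42.01057
END_GROUP_NATIVE = 18.01056     # +H2O on the free reducing glycan
END_GROUP_PERME = 46.04186      # +C2H6O after permethylation


# ----------------------------------------------------------------------
# Topology
# ----------------------------------------------------------------------

@dataclass
class GlycanNode:
    """One residue in a rooted glycan tree.

    ``anomer`` and ``linkage`` describe the bond to the *parent* (toward the
    reducing end); both may be ``"?"``.  The root's bond fields are ignored.
    """

    residue: str
    anomer: str = "?"
    linkage: str = "?"
    oacetyl: int = 0
    children: list["GlycanNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.residue not in KNOWN_RESIDUES:
            raise ValueError(f"unknown residue kind: {self.residue!r}")
        if self.anomer not in ("a", "b", "?"):
            raise ValueError(f"anomer must be 'a', 'b' or '?', got {self.anomer!r}")


@dataclass
class GlycanTopology:
    """Rooted tree of residues; the root is the reducing-end residue."""

    root: GlycanNode

    # -- traversal ------------------------------------------------------
    def walk(self) -> Iterator[GlycanNode]:
        """Depth-first pre-order traversal."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def nodes_with_parents(self) -> Iterator[tuple[GlycanNode, Optional[GlycanNode]]]:
        stack: list[tuple[GlycanNode, Optional[GlycanNode]]] = [(self.root, None)]
        while stack:
            node, parent = stack.pop()
            yield node, parent
            stack.extend((c, node) for c in reversed(node.children))

    @property
    def n_residues(self) -> int:
        return sum(1 for _ in self.walk())

    def composition(self) -> MonosaccharideComposition:
        return composition_of(self)

    # -- serialization --------------------------------------------------
    def serialize(self) -> str:
        return _serialize_node(self.root, is_root=True)

    def copy(self) -> "GlycanTopology":
        return parse_topology(self.serialize())

    def __str__(self) -> str:
        return self.serialize()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanTopology):
            return NotImplemented
        return _canonical(self.root, True) == _canonical(other.root, True)


def _serialize_node(node: GlycanNode, is_root: bool = False) -> str:
    token = node.residue
    if node.oacetyl:
        token += "{%dAc}" % node.oacetyl
    suffix = "" if is_root else f"({node.anomer}{'1' if node.residue not in _SIALIC else '2'}-{node.linkage})"
    if not node.children:
        return token + suffix
    # first child continues the main chain (written leftmost, unbracketed);
    # remaining children are bracketed branches
    main, *branches = node.children
    parts = [_serialize_node(main)]
    parts.extend("[" + _serialize_node(b) + "]" for b in branches)
    return "".join(parts) + token + suffix


def _canonical(node: GlycanNode, is_root: bool = False):
    # the root is the reducing end: it has no bond toward a parent, so its
    # anomer/linkage fields are not part of the glycan's identity
    return (
        node.residue,
        "?" if is_root else node.anomer,
        "?" if is_root else node.linkage,
        node.oacetyl,
        tuple(sorted(_canonical(c) for c in node.children)),
    )


_TOKEN_RE = re.compile(
    r"(?P<residue>[A-Za-z]+)"
    r"(?:\{(?P<oac>\d+)Ac\})?"
    r"(?:\((?P<anomer>[ab?])(?P<pos1>[\d?]*)-(?P<pos2>[\d?]*)\))?"
)


def parse_topology(text: str) -> GlycanTopology:
    """Parse the IUPAC-condensed linear code into a rooted tree.

    The rightmost residue is the reducing end (root).  Square brackets open
    branches; the linkage in parentheses belongs to the residue it follows
    and describes its bond toward the root.
    """
    items = _parse_items(text.strip())
    if not items:
        raise ValueError("empty topology string")
    root = _build_chain(items)
    return GlycanTopology(root)


def _parse_items(text: str) -> list:
    """Split into a flat list of GlycanNode prototypes and bracketed sublists."""
    items: list = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            depth = 1
            j = i + 1
            while j < len(text) and depth:
                if text[j] == "[":
                    depth += 1
                elif text[j] == "]":
                    depth -= 1
                j += 1
            if depth:
                raise ValueError(f"unbalanced '[' in topology string: {text!r}")
            items.append(_parse_items(text[i + 1:j - 1]))
            i = j
        else:
            m = _TOKEN_RE.match(text, i)
            if not m or not m.group("residue"):
                raise ValueError(f"cannot parse topology at {text[i:]!r}")
            node = GlycanNode(
                residue=m.group("residue"),
                anomer=m.group("anomer") or "?",
                linkage=(m.group("pos2") or "?") or "?",
                oacetyl=int(m.group("oac") or 0),
            )
            items.append(node)
            i = m.end()
    return items


def _build_chain(items: list) -> GlycanNode:
    """Right-to-left: last node is root; preceding items attach to it."""
    node = items[-1]
    if isinstance(node, list):
        raise ValueError("topology cannot end with a branch group")
    rest = items[:-1]
    # scan leftward; each bracketed group and the main-chain prefix are children
    while rest:
        last = rest[-1]
        if isinstance(last, list):
            node.children.append(_build_chain(last))
            rest = rest[:-1]
        else:
            node.children.insert(0, _build_chain(rest))
            rest = []
    return node


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def composition_of(topology: GlycanTopology) -> MonosaccharideComposition:
    """Reduce a topology to its monosaccharide composition.

    Hexose identity (Gal/Man/Glc) and HexNAc identity (GlcNAc/GalNAc) are
    erased; node-level O-acetyl groups are summed into the composition.
    """
    counts = {f: 0 for f in _FIELDS}
    for node in topology.walk():
        counts[residue_class(node.residue)] += 1
        counts["oacetyl"] += node.oacetyl
    return MonosaccharideComposition(**counts)


# ----------------------------------------------------------------------
# Epitope motifs
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class EpitopeMotif:
    """A named terminal subtree pattern.

    The pattern is itself a topology whose root is the innermost residue of
    the motif.  A match site is a node ``t`` of the target such that:

    * residue kinds are compatible (generic Hex/HexNAc/dHex match specific
      names; otherwise names must agree) and anomers agree unless either is
      ``?``;
    * each pattern child maps bijectively onto the children of ``t`` — the
      target node carries *no* unexplained substituents (this is what
      discriminates the plain GalβGalβ-HexNAc cap from its NeuAc- or
      Galα-branched forms, and the terminal NeuAc-Gal cap from a NeuAc
      branched on an internal Gal);
    * pattern leaves map onto target leaves (the occurrence is terminal).

    ``allow_extra_at_site=True`` relaxes the no-extras rule at the match-site
    node itself; ``anchor_root=True`` restricts match sites to the tree root.
    Both are needed for core fucosylation, where the Fuc shares the
    reducing-end HexNAc with the rest of the glycan.
    """

    name: str
    pattern: str
    anchor_root: bool = False
    allow_extra_at_site: bool = False

    def topology(self) -> GlycanTopology:
        return parse_topology(self.pattern)


MOTIF_LIBRARY: dict[str, EpitopeMotif] = {
    m.name: m
    for m in (
        EpitopeMotif("diSA", "NeuAc(a2-8)NeuAc"),
        EpitopeMotif("salmonid-cap", "NeuAc(a2-?)Gal"),
        EpitopeMotif("sturgeon-cap", "Gal(a1-?)[Gal(b1-?)]Gal(b1-?)HexNAc"),
        EpitopeMotif("catfish-cap", "NeuAc(a2-?)[Gal(b1-?)]Gal(b1-?)HexNAc"),
        EpitopeMotif("nonsialylated-GalGal", "Gal(b1-?)Gal(b1-?)HexNAc"),
        EpitopeMotif("core-fucose", "Fuc(a1-6)HexNAc", anchor_root=True,
                     allow_extra_at_site=True),
    )
}


def _kinds_compatible(pattern_name: str, target_name: str) -> bool:
    if pattern_name == target_name:
        return True
    for family in (_HEXOSES, _HEXNACS, _DEOXYHEXOSES):
        if pattern_name in family and target_name in family:
            # generic names (Hex / HexNAc / dHex) act as wildcards within
            # their class; two distinct specific names do not match
            return pattern_name in ("Hex", "HexNAc", "dHex") or target_name in (
                "Hex", "HexNAc", "dHex")
    return False


def _anomers_compatible(pattern: str, target: str) -> bool:
    return pattern == "?" or target == "?" or pattern == target


def _match_at(pnode: GlycanNode, tnode: GlycanNode, is_pattern_root: bool,
              allow_extra: bool = False) -> bool:
    if not _kinds_compatible(pnode.residue, tnode.residue):
        return False
    if not is_pattern_root and not _anomers_compatible(pnode.anomer, tnode.anomer):
        return False
    if not pnode.children:
        # pattern leaf must sit on a target leaf (terminal occurrence),
        # except at the match-site node itself which may continue toward
        # the core
        return is_pattern_root or not tnode.children
    if not (is_pattern_root and allow_extra) and \
            len(tnode.children) != len(pnode.children):
        return False  # no unexplained substituents
    if len(tnode.children) < len(pnode.children):
        return False
    # injective assignment of pattern children onto target children
    return _assign(pnode.children, tnode.children)


def _assign(pchildren: list[GlycanNode], tchildren: list[GlycanNode]) -> bool:
    if not pchildren:
        return True
    p, rest = pchildren[0], pchildren[1:]
    for i, t in enumerate(tchildren):
        if _match_at(p, t, is_pattern_root=False):
            if _assign(rest, tchildren[:i] + tchildren[i + 1:]):
                return True
    return False


def match_motif(topology: GlycanTopology, motif: EpitopeMotif) -> list[GlycanNode]:
    """Return every non-overlapping terminal occurrence of *motif*.

    Sites are the target nodes at which the motif's innermost residue sits.
    Occurrences are collected leaf-ward first so that non-overlap never
    discards a deeper match in favour of a shallower one.
    """
    proot = motif.topology().root
    used: set[int] = set()
    sites: list[GlycanNode] = []

    def subtree_ids(node: GlycanNode) -> set[int]:
        out = {id(node)}
        for c in node.children:
            out |= subtree_ids(c)
        return out

    def visit(node: GlycanNode) -> None:
        for c in node.children:
            visit(c)
        if motif.anchor_root and node is not topology.root:
            return
        if id(node) in used:
            return
        if _match_at(proot, node, is_pattern_root=True,
                     allow_extra=motif.allow_extra_at_site):
            ids = subtree_ids(node)
            if motif.anchor_root:
                # only the motif's own substituent overlaps, not the whole tree
                ids = {id(node)}
            if ids & used:
                return
            used.update(ids)
            sites.append(node)

    visit(topology.root)
    return sites
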