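"""MSn fragment prediction and topology scoring.

Fragmentation model for permethylated, sodiated glycans under CID:

* every glycosidic cleavage splits the tree at one edge; the non-reducing
  (distal) piece leaves fully methylated, the retained piece keeps an
  unmethylated hydroxyl scar (-CH2 relative to full methylation);
* B-type ions are the sodiated distal pieces; Y-type retention products are
  the precursor (or intermediate fragment) minus the distal neutral;
* sequential MSn stages apply further cleavages to fragments, with scars
  travelling with the nodes they sit on.

Only singly charged sodiated fragments are predicted; these cover the
low-m/z epitope diagnostics (branched vs linear trihexose caps, the di-SA
NeuAc-NeuAc B-ion) that drive topology discrimination in serum N-glycomics.

Fragment lists travel as MGF (Mascot generic format); the reader/writer here
handles the plain BEGIN IONS/END IONS dialect with PEPMASS/CHARGE/TITLE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .glycan_model import (
    CH2,
    NA,
    GlycanNode,
    GlycanTopology,
    MonosaccharideComposition,
)
from .mass_engine import residue_mass

__all__ = [
    "FragmentIon",
    "FragmentObservation",
    "predict_fragments",
    "score_topologies",
    "TopologyScore",
    "detect_disa",
    "read_mgf",
    "write_mgf",
]


@dataclass(frozen=True)
class FragmentIon:
    mz: float
    label: str          # e.g. "B:Hex3HexNAc1" or "B:Hex2HexNAc1-1scar"
    n_scars: int
    composition: MonosaccharideComposition


@dataclass
class FragmentObservation:
    """An observed MSn fragment list with its provenance."""

    stage: int                       # 2 for MS2, 3 for MS3, ...
    precursor_mz: float
    precursor_charge: int
    fragments: list[float]
    title: str = ""

    def __post_init__(self) -> None:
        if self.stage < 2:
            raise ValueError("MSn stage must be >= 2")


# ----------------------------------------------------------------------
# Prediction
# ----------------------------------------------------------------------

def _subtree_nodes(node: GlycanNode) -> list[GlycanNode]:
    out = [node]
    for c in node.children:
        out.extend(_subtree_nodes(c))
    return out


def _fragment_mz(nodes: Sequence[GlycanNode], n_scars: int) -> float:
    total = sum(residue_mass(n.residue, "permethylated") for n in nodes)
    return total + CH2 + NA - n_scars * CH2


def _comp_of_nodes(nodes: Sequence[GlycanNode]) -> MonosaccharideComposition:
    from .glycan_model import residue_class
    counts: dict[str, int] = {}
    for n in nodes:
        c = residue_class(n.residue)
        counts[c] = counts.get(c, 0) + 1
    return MonosaccharideComposition(**counts)


def predict_fragments(topology: GlycanTopology,
                      max_cleavages: int = 3,
                      precursor_is_b: bool = False) -> list[FragmentIon]:
    """Predicted sodiated 1+ fragment m/z set for a candidate topology.

    Enumerates every state reachable by up to *max_cleavages* glycosidic
    cleavages starting from the intact precursor.  Each cut splits a piece
    at one edge: the distal (non-reducing) part becomes a fully methylated
    B-type piece; the retained part gains one scar (an unmethylated hydroxyl
    at the cut site).  Scars travel with the node they sit on when a piece
    is cut again, so sequential-loss products are bookkept exactly.

    Only B-type pieces are reported (Y-type molecular losses fly at the
    precursor's charge and are excluded from the 1+ prediction), so the
    intact precursor is reported only when it is itself a B ion being
    refragmented at a later MSn stage (*precursor_is_b*, e.g. the m/z 894
    or 1051 epitope ions).  A single-residue topology yields no fragments.
    """
    if topology.n_residues > 30:
        raise ValueError("fragment prediction is limited to <= 30 residues")

    id2node = {id(n): n for n in topology.walk()}
    all_ids = frozenset(id2node)
    if len(all_ids) < 2:
        return []

    ions: dict[tuple[float, str], FragmentIon] = {}
    seen: set[tuple[frozenset[int], tuple[int, ...], bool, int]] = set()

    def emit(present: frozenset[int], scars: tuple[int, ...]) -> None:
        nodes = [id2node[i] for i in present]
        n_scars = len(scars)
        comp = _comp_of_nodes(nodes)
        mz = _fragment_mz(nodes, n_scars)
        label = f"B:{comp}" + (f"-{n_scars}scar" if n_scars else "")
        ions.setdefault((round(mz, 4), label),
                        FragmentIon(mz, label, n_scars, comp))

    def expand(present: frozenset[int], scars: tuple[int, ...],
               is_b: bool, cleavages_left: int) -> None:
        # scars is a sorted multiset of node ids: a node loses one methyl
        # per subtree cleaved off it, so the same parent can scar twice
        state = (present, scars, is_b, cleavages_left)
        if state in seen:
            return
        seen.add(state)
        if is_b and not (present == all_ids and not precursor_is_b):
            emit(present, scars)
        if cleavages_left == 0 or len(present) < 2:
            return
        for nid in present:
            node = id2node[nid]
            for child in node.children:
                if id(child) not in present:
                    continue
                distal = frozenset(i for i in (id(n) for n in _subtree_nodes(child))
                                   if i in present)
                retained = present - distal
                # distal piece: fully methylated B ion (keeps scars already
                # sitting on its own nodes)
                expand(distal, tuple(s for s in scars if s in distal),
                       True, cleavages_left - 1)
                # retained piece: same type as its parent piece, +1 scar at
                # the cut parent node
                expand(retained,
                       tuple(sorted([s for s in scars if s in retained] + [nid])),
                       is_b, cleavages_left - 1)

    expand(all_ids, (), precursor_is_b, max_cleavages)
    return sorted(ions.values(), key=lambda f: f.mz)


def predicted_mz_set(topology: GlycanTopology, max_cleavages: int = 3,
                     ndigits: int = 1,
                     precursor_is_b: bool = False) -> set[float]:
    return {round(f.mz, ndigits)
            for f in predict_fragments(topology, max_cleavages, precursor_is_b)}


# ----------------------------------------------------------------------
# Scoring
# ----------------------------------------------------------------------

@dataclass
class TopologyScore:
    topology: GlycanTopology
    score: float
    matched: int
    unmatched_predicted: int
    unexplained_observed: int
    matched_mz: list[float] = field(default_factory=list)


def score_topologies(candidates: Sequence[GlycanTopology],
                     observation: FragmentObservation,
                     tolerance: float = 0.5,
                     max_cleavages: int = 3,
                     unexplained_penalty: float = 0.5,
                     precursor_is_b: bool = False,
                     ) -> tuple[list[TopologyScore], bool]:
    """Rank candidate topologies against an observed fragment list.

    score = matched predicted fragments - penalty x unexplained observed
    peaks.  With ``precursor_is_b`` the candidates are treated as isolated
    B-type epitope ions being refragmented (MS3/MS4 of an antenna cap)
    rather than intact molecular ions.  Returns (ranked scores, all_zero_warning); with every score at
    zero the candidates come back in input order with the warning flag set
    rather than pretending to discriminate.  Ties break deterministically on
    the serialized topology string.
    """
    if not candidates:
        raise ValueError("need at least one candidate topology")
    scores = []
    for idx, cand in enumerate(candidates):
        predicted = predict_fragments(cand, max_cleavages, precursor_is_b)
        pred_mzs = sorted({round(f.mz, 4) for f in predicted})
        matched_obs = set()
        matched_pred = set()
        for omz in observation.fragments:
            for pmz in pred_mzs:
                if abs(omz - pmz) <= tolerance:
                    matched_obs.add(omz)
                    matched_pred.add(pmz)
        unexplained = len(set(observation.fragments) - matched_obs)
        score = len(matched_pred) - unexplained_penalty * unexplained
        scores.append(TopologyScore(
            topology=cand, score=score, matched=len(matched_pred),
            unmatched_predicted=len(pred_mzs) - len(matched_pred),
            unexplained_observed=unexplained,
            matched_mz=sorted(matched_obs)))
    all_zero = all(s.matched == 0 for s in scores)
    if all_zero:
        return scores, True
    scores.sort(key=lambda s: (-s.score, s.topology.serialize()))
    return scores, False


def discriminating_fragments(a: GlycanTopology, b: GlycanTopology,
                             max_cleavages: int = 3, ndigits: int = 1,
                             precursor_is_b: bool = False,
                             ) -> tuple[set[float], set[float]]:
    """Predicted m/z unique to each of two candidate topologies."""
    sa = predicted_mz_set(a, max_cleavages, ndigits, precursor_is_b)
    sb = predicted_mz_set(b, max_cleavages, ndigits, precursor_is_b)
    return sa - sb, sb - sa


# ----------------------------------------------------------------------
# di-SA detection from composition
# ----------------------------------------------------------------------

def detect_disa(comp: MonosaccharideComposition,
                antennae: Optional[int] = None) -> Optional[int]:
    """Number of NeuAc-NeuAc (di-SA) units implied by a composition.

    For complex-type glycans (HexNAc >= 4) the antenna count defaults to
    HexNAc - 2; any NeuAc beyond one per antenna must stack as di-SA.
    Returns None for hybrid/high-mannose compositions (HexNAc < 4 with no
    explicit antenna count), where the heuristic does not apply.
    """
    if antennae is None:
        if comp.hexnac < 4:
            return None
        antennae = comp.hexnac - 2
    return max(0, comp.neuac - antennae)


# ----------------------------------------------------------------------
# MGF I/O
# ----------------------------------------------------------------------

def write_mgf(observations: Sequence[FragmentObservation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for obs in observations:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={obs.title or f'MS{obs.stage}'}\n")
            fh.write(f"PEPMASS={obs.precursor_mz:.5f}\n")
            fh.write(f"CHARGE={obs.precursor_charge}+\n")
            fh.write(f"SCANS={obs.stage}\n")
            for mz in obs.fragments:
                fh.write(f"{mz:.4f} 1.0\n")
            fh.write("END IONS\n")


def read_mgf(path: str | Path) -> list[FragmentObservation]:
    observations = []
    current: Optional[dict] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                current = {"fragments": [], "title": "", "stage": 2,
                           "pepmass": 0.0, "charge": 1}
            elif line == "END IONS":
                if current is None:
                    raise ValueError(f"{path}: line {lineno}: END IONS without BEGIN")
                observations.append(FragmentObservation(
                    stage=current["stage"], precursor_mz=current["pepmass"],
                    precursor_charge=current["charge"],
                    fragments=current["fragments"], title=current["title"]))
                current = None
            elif current is None:
                continue  # header lines outside blocks
            elif "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                if key == "TITLE":
                    current["title"] = value
                elif key == "PEPMASS":
                    current["pepmass"] = float(value.split()[0])
                elif key == "CHARGE":
                    current["charge"] = int(value.rstrip("+-"))
                elif key == "SCANS":
                    current["stage"] = max(2, int(value))
            else:
                try:
                    current["fragments"].append(float(line.split()[0]))
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return observations
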