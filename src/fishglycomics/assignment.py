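"""Composition search: map observed (m/z, z) peaks to monosaccharide
compositions.

Matching is isotopologue-aware: observed profile peaks of large glycans sit
at the most abundant isotopologue (A+1 or A+2), so candidates are scored over
k = 0..k_max rather than against the monoisotopic m/z only.  Mass collisions
within tolerance are always reported; the ranking that resolves them (envelope
plausibility, rare-residue penalty, binned mass error, parsimony) is
documented on :func:`assign_peak`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .glycan_model import NA, NEUTRON_SHIFT, PROTON, MonosaccharideComposition
from . import mass_engine
from .peak_processing import PeakList, collapse_isotope_clusters, \
    sum_charge_states

__all__ = [
    "CompositionBounds",
    "DEFAULT_BOUNDS",
    "AssignedPeak",
    "enumerate_compositions",
    "assign_peak",
    "assign_spectrum",
    "SpectrumAssignment",
]

_MAX_CANDIDATES = 10_000_000


@dataclass(frozen=True)
class CompositionBounds:
    """Inclusive per-residue search ranges.

    Defaults cover complex/hybrid/high-mannose serum N-glycans; NeuGc and
    KDN are searched even though they are not expected in these sera, so
    their absence is a result rather than an assumption.  O-acetyl is only
    searched in native mode (permethylation erases it).
    """

    neuac: tuple[int, int] = (0, 6)
    neugc: tuple[int, int] = (0, 2)
    kdn: tuple[int, int] = (0, 2)
    hex: tuple[int, int] = (3, 14)
    hexnac: tuple[int, int] = (2, 8)
    dhex: tuple[int, int] = (0, 3)
    oacetyl: tuple[int, int] = (0, 6)

    def n_candidates(self, native: bool = False) -> int:
        n = 1
        for f in ("neuac", "neugc", "kdn", "hex", "hexnac", "dhex"):
            lo, hi = getattr(self, f)
            n *= hi - lo + 1
        if native:
            lo, hi = self.oacetyl
            n *= hi - lo + 1
        return n


DEFAULT_BOUNDS = CompositionBounds()


def enumerate_compositions(bounds: CompositionBounds = DEFAULT_BOUNDS,
                           native: bool = False,
                           oacetyl_cap_per_sialic: int = 3,
                           ) -> Iterator[MonosaccharideComposition]:
    """Exhaustively enumerate compositions within *bounds*.

    In native mode the O-acetyl dimension is included, capped at
    *oacetyl_cap_per_sialic* per sialic-acid residue.
    """
    if bounds.n_candidates(native) > _MAX_CANDIDATES:
        raise ValueError(
            f"bounds produce more than {_MAX_CANDIDATES:,} candidate "
            "compositions; tighten the per-residue ranges")
    ranges = [range(lo, hi + 1) for lo, hi in (
        bounds.neuac, bounds.neugc, bounds.kdn,
        bounds.hex, bounds.hexnac, bounds.dhex)]
    for neuac, neugc, kdn, hex_, hexnac, dhex in itertools.product(*ranges):
        base = MonosaccharideComposition(neuac, neugc, kdn, hex_, hexnac, dhex)
        if not native:
            yield base
            continue
        oac_hi = min(bounds.oacetyl[1], oacetyl_cap_per_sialic * base.sialic)
        for oac in range(bounds.oacetyl[0], oac_hi + 1):
            yield MonosaccharideComposition(neuac, neugc, kdn, hex_, hexnac, dhex, oac)


@dataclass(frozen=True)
class AssignedPeak:
    """One candidate explanation of an observed (m/z, z) peak."""

    observed_mz: float
    charge: int
    composition: MonosaccharideComposition
    k: int                       # matched isotopologue index
    theoretical_mz: float
    error_ppm: float
    nglycan_plausible: bool
    disa_capable: bool           # complex-type with NeuAc in excess of antennae

    @property
    def error_mz(self) -> float:
        return self.observed_mz - self.theoretical_mz


# ----------------------------------------------------------------------
# Cached vectorized candidate table
# ----------------------------------------------------------------------

class _CandidateTable:
    def __init__(self, bounds: CompositionBounds, derivatization: str,
                 oacetyl_cap: int):
        native = derivatization == "native"
        self.comps = list(enumerate_compositions(bounds, native, oacetyl_cap))
        self.masses = np.array([mass_engine.neutral_mass(c, derivatization)
                                for c in self.comps])
        self.n_residues = np.array([c.n_residues for c in self.comps])


_table_cache: dict = {}


def _candidates(bounds: CompositionBounds, derivatization: str,
                oacetyl_cap: int) -> _CandidateTable:
    key = (bounds, derivatization, oacetyl_cap)
    if key not in _table_cache:
        _table_cache[key] = _CandidateTable(bounds, derivatization, oacetyl_cap)
    return _table_cache[key]


def _disa_capable(comp: MonosaccharideComposition) -> bool:
    return comp.hexnac >= 4 and comp.neuac > comp.hexnac - 2


def assign_peak(mz: float, charge: int,
                tolerance_mz: float = 0.05,
                bounds: CompositionBounds = DEFAULT_BOUNDS,
                k_max: int = 3,
                derivatization: str = "permethylated",
                oacetyl_cap_per_sialic: int = 3,
                margin_ppm: float = 1.0,
                observed_is_top: bool = True,
                ) -> list[AssignedPeak]:
    """All candidate compositions matching an observed peak, best first.

    A candidate matches when ``|observed - ion_mz(comp, z, k)| <= tolerance``
    for some k <= k_max.  Ranking:

    1. isotopologue plausibility (only with ``observed_is_top``, the default)
       — observed profile peaks sit at (or next to) the top of the isotope
       envelope, so candidates matched at a k within 1 of their own
       most-abundant isotopologue outrank those whose envelope maximum is
       elsewhere; pass ``observed_is_top=False`` when matching an estimated
       *monoisotopic* m/z, where k means the envelope's starting index;
    2. fewer rare sialic acids (NeuGc + KDN): NeuGc1dHex1 is elementally
       identical to NeuAc1Hex1 and KDN1HexNAc1 to NeuAc1Hex1, so rare-sialic
       candidates collide with common ones at exactly or nearly equal mass;
       the common-residue explanation is preferred outright, and rare
       assignments surface only through the collision audit;
    3. mass error in bins of ``margin_ppm`` (default 1 ppm) above the best
       |ppm error| — fine enough that genuinely distinct masses rank by
       nearness, while exactly degenerate candidates share a bin and fall
       to parsimony (fewer residues), then smaller k, then |ppm|.

    All collisions remain visible in the returned list.
    """
    table = _candidates(bounds, derivatization, oacetyl_cap_per_sialic)
    if derivatization == "permethylated":
        neutral_target = lambda k: mz * charge - charge * NA - k * NEUTRON_SHIFT
    else:
        neutral_target = lambda k: mz * charge + charge * PROTON - k * NEUTRON_SHIFT
    hits: list[AssignedPeak] = []
    for k in range(k_max + 1):
        target = neutral_target(k)
        sel = np.where(np.abs(table.masses - target) <= tolerance_mz * charge)[0]
        for i in sel:
            comp = table.comps[i]
            theo = (table.masses[i] + k * NEUTRON_SHIFT
                    + (charge * NA if derivatization == "permethylated"
                       else -charge * PROTON)) / charge
            if abs(mz - theo) > tolerance_mz:
                continue
            hits.append(AssignedPeak(
                observed_mz=mz, charge=charge, composition=comp, k=k,
                theoretical_mz=theo,
                error_ppm=(mz - theo) / theo * 1e6,
                nglycan_plausible=comp.is_nglycan_plausible(),
                disa_capable=_disa_capable(comp)))
    if not hits:
        return hits

    def k_implausible(h: AssignedPeak) -> int:
        # graded distance between the matched isotopologue and the
        # candidate's own envelope maximum: an observed profile peak is the
        # envelope top, so a candidate that explains it as top+-1 is a
        # neutron-shifted near-twin and ranks below an exact-top match
        if not observed_is_top:
            return 0
        top = mass_engine.most_abundant_k(h.composition.without_oacetyl()
                                          if derivatization == "permethylated"
                                          else h.composition, derivatization)
        return min(abs(h.k - top), 2)

    def k_start_implausible(h: AssignedPeak) -> int:
        # in monoisotopic matching, a k>=1 start claims the monoisotopic
        # member fell below detection — credible only if the candidate's
        # own envelope predicts a weak monoisotopic peak; otherwise the
        # hypothesis would systematically admit -1-neutron twins
        if observed_is_top or h.k == 0:
            return 0
        ratio = mass_engine.mono_visibility(
            h.composition.without_oacetyl()
            if derivatization == "permethylated" else h.composition,
            derivatization)
        return 0 if ratio <= 0.3 else 1

    best_ppm = min(abs(h.error_ppm) for h in hits)
    hits.sort(key=lambda h: (
        k_implausible(h),
        h.composition.neugc + h.composition.kdn,
        k_start_implausible(h),
        int((abs(h.error_ppm) - best_ppm) / margin_ppm),
        h.composition.n_residues, h.k,
        round(abs(h.error_ppm), 2)))
    return hits


# ----------------------------------------------------------------------
# Whole-spectrum assignment
# ----------------------------------------------------------------------

@dataclass
class SpectrumAssignment:
    """Result of assigning a full MS1 peak list.

    ``abundances`` maps composition -> relative abundance (%) over the
    retained (thresholded) glycans, normalized to 100.  ``collisions``
    records peaks with more than one candidate within tolerance — these are
    reported, never silently resolved.
    """

    abundances: dict[MonosaccharideComposition, float] = field(default_factory=dict)
    intensities: dict[MonosaccharideComposition, float] = field(default_factory=dict)
    assigned: list[AssignedPeak] = field(default_factory=list)
    collisions: list[list[AssignedPeak]] = field(default_factory=list)
    unassigned_fraction: float = 0.0
    mode: str = "permethylated+"


def assign_spectrum(peaklist: PeakList,
                    tolerance_mz: float = 0.05,
                    bounds: CompositionBounds = DEFAULT_BOUNDS,
                    k_max: int = 3,
                    threshold: float = 0.03,
                    z_hypotheses: Sequence[int] = (1, 2, 3, 4),
                    nglycan_only: bool = True,
                    exclude_mz: Sequence[float] = (),
                    ) -> SpectrumAssignment:
    """Cluster -> assign -> charge-sum -> threshold -> normalize to 100%.

    *exclude_mz* suppresses known non-glycan responses (e.g. the Dp4
    standard) from assignment; their intensity is not counted as unassigned.
    """
    derivatization = "native" if peaklist.mode.startswith("native") else "permethylated"
    adduct = NA if derivatization == "permethylated" else -PROTON
    clusters = collapse_isotope_clusters(peaklist.peaks, z_hypotheses, tolerance_mz)
    detections: list[tuple[MonosaccharideComposition, float]] = []
    assigned: list[AssignedPeak] = []
    collisions: list[list[AssignedPeak]] = []
    assigned_intensity = 0.0
    excluded_intensity = 0.0
    total = sum(c.intensity for c in clusters)

    multis, singles = [], []
    for cluster in clusters:
        if any(abs(cluster.mz - x) <= max(tolerance_mz, 0.5) for x in exclude_mz):
            excluded_intensity += cluster.intensity
            continue
        if len(cluster.members) >= 2 and cluster.charge is not None:
            multis.append(cluster)
        else:
            singles.append(cluster)

    # -- multi-member clusters: pool charge states of the same neutral mass
    # ("peaks for all charge states summed") and assign each pool once from
    # its combined monoisotopic-mass estimate; pooling shrinks the m/z
    # jitter that would otherwise make near-isobaric candidates a lottery
    pools: list[list] = []
    for cluster in sorted(multis,
                          key=lambda c: c.charge * c.monoisotopic_mz
                          - c.charge * adduct):
        m_est = cluster.charge * cluster.monoisotopic_mz - cluster.charge * adduct
        if pools and abs(m_est - pools[-1][-1][0]) <= max(2 * tolerance_mz, 0.05):
            pools[-1].append((m_est, cluster))
        else:
            pools.append([(m_est, cluster)])

    for pool in pools:
        # weight each charge state's estimate by its precision: the mono
        # m/z error scales back to neutral mass as ~z/sqrt(n_members)
        weights = [len(c.members) / c.charge ** 2 for _, c in pool]
        m_comb = float(np.average([m for m, _ in pool], weights=weights))
        ref = max((c for _, c in pool), key=lambda c: c.intensity)
        z = ref.charge
        # a collapsed cluster normally starts at its monoisotopic member,
        # but jitter can detach it, so the lowest member is searched as
        # k = 0 or 1; the margin ranking plus the envelope filter below
        # disambiguate the -1 Da near-twins this admits
        hits = assign_peak((m_comb + z * adduct) / z, z, tolerance_mz,
                           bounds, 1, derivatization, observed_is_top=False)
        # the candidate's envelope maximum must sit about k + k_top above
        # its monoisotopic peak (+-1: near-tied A+1/A+2 envelopes flicker
        # under intensity noise)
        strict = [
            h for h in hits
            if abs(mass_engine.most_abundant_k(
                h.composition.without_oacetyl()
                if derivatization == "permethylated" else h.composition,
                derivatization) - (h.k + ref.k_top)) <= 1]
        hits = strict or hits
        if nglycan_only:
            hits = [h for h in hits if h.nglycan_plausible]
        if not hits:
            # a jitter-split cluster remainder does not start at k=0; fall
            # back to a free isotopologue search on its strongest member
            hits = assign_peak(ref.mz, z, tolerance_mz, bounds, k_max,
                               derivatization)
            if nglycan_only:
                hits = [h for h in hits if h.nglycan_plausible]
        if not hits:
            continue
        if len(hits) > 1:
            collisions.append(hits)
        pool_intensity = sum(c.intensity for _, c in pool)
        detections.append((hits[0].composition, pool_intensity))
        assigned.append(hits[0])
        assigned_intensity += pool_intensity

    # -- singletons: isotopologue-aware search over k and (if unknown) z
    for cluster in singles:
        zs = [cluster.charge] if cluster.charge else list(z_hypotheses)
        best: Optional[AssignedPeak] = None
        for z in zs:
            hits = assign_peak(cluster.mz, z, tolerance_mz, bounds, k_max,
                               derivatization)
            if nglycan_only:
                hits = [h for h in hits if h.nglycan_plausible]
            if hits:
                if len(hits) > 1:
                    collisions.append(hits)
                if best is None or abs(hits[0].error_ppm) < abs(best.error_ppm):
                    best = hits[0]
        if best is not None:
            detections.append((best.composition, cluster.intensity))
            assigned.append(best)
            assigned_intensity += cluster.intensity

    totals = sum_charge_states(detections)
    # the detection threshold references the most intense single MS1 peak
    # (the base peak), not the largest per-composition total: a summed
    # response is several-fold its base peak, and referencing totals would
    # silently drop the sub-percent glycans the threshold is meant to keep
    base_peak = max((p.intensity for c in multis + singles for p in c.members),
                    default=0.0)
    retained = {c: v for c, v in totals.items() if v >= threshold * base_peak}
    grand = sum(retained.values())
    abundances = {c: 100.0 * v / grand for c, v in retained.items()} if grand else {}
    denom = total - excluded_intensity
    return SpectrumAssignment(
        abundances=abundances,
        intensities=retained,
        assigned=assigned,
        collisions=collisions,
        unassigned_fraction=(1.0 - assigned_intensity / denom) if denom > 0 else 0.0,
        mode=peaklist.mode,
    )
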