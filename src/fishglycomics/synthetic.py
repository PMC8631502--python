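"""Ground-truthed synthetic spectra emulating five fish serum N-glycomes.

Every pipeline stage is testable without instrument data: the generator
emits centroided MS1 peak lists (sodiated multiply charged permethylated
isotope clusters in positive mode, or deprotonated native glycans with
O-acetyl ladders in negative mode), MSn fragment lists, and exoglycosidase
digestion series, always alongside a serialized ground truth.

The five built-in presets encode the species-specific profiles established
for these sera:

* Atlantic salmon / Arctic char — dominated by the biantennary disialylated
  glycan NeuAc2Hex5HexNAc4; di-SA variants carry 2% (salmon) and 5% (char)
  of the pool; the triantennary trisialylated glycan is abundant in salmon
  and absent from char; the tetrasialylated di-SA glycan sits at 0.38% and
  0.12%; native-mode O-acetyl ladders reach 3 (salmon) and 6 (char) groups.
* shortnose / Atlantic sturgeon — Galα(Galβ)Galβ antenna caps; core fucose
  on 45% vs 2% of the pool.
* channel catfish — centred on NeuAc2Hex7HexNAc4 bearing the NeuAc-branched
  GalβGalβ epitope; no NeuAc3Hex5HexNAc4; O-acetyl ladder to 2.

Abundances not established by the study are filled with plausible values
and flagged ``abundance_from_study = False`` in the ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .glycan_model import (
    NA,
    NEUTRON_SHIFT,
    PROTON,
    GlycanTopology,
    MonosaccharideComposition,
    parse_topology,
)
from .digestion import DigestRule, apply_enzyme
from .mass_engine import b_fragment_mz, elemental_formula, isotope_distribution, \
    neutral_mass
from .msn import FragmentObservation, predict_fragments
from .peak_processing import Peak, PeakList

__all__ = [
    "NoiseModel",
    "SpeciesPreset",
    "GroundTruth",
    "build_presets",
    "generate_ms1",
    "generate_msn",
    "generate_digest_series",
    "DP4_MZ_THEORETICAL",
    "DP4_MZ_OBSERVED",
]

# Permethylated maltotetraose [M+Na]+ (the Dp4 quantification standard).
# Theory puts it at 885.43; the instrument convention in the source study
# logged it at 899.48 (one CH2 higher, unexplained) — the expected position
# is therefore configurable, defaulting to theory.
DP4_MZ_THEORETICAL = neutral_mass(MonosaccharideComposition(hex=4)) + NA  # 885.43
DP4_MZ_OBSERVED = 899.48


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise: m/z jitter (Da), multiplicative intensity CV,
    and spurious peaks per true peak."""

    mz_jitter_sd: float = 0.01
    intensity_cv: float = 0.10
    spurious_rate: float = 0.05

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PresetGlycan:
    topology: str                    # serialized
    abundance: float                 # % of pool
    abundance_from_study: bool = False


@dataclass(frozen=True)
class SpeciesPreset:
    species: str
    glycans: tuple[PresetGlycan, ...]
    oacetyl_weights: tuple[tuple[int, float], ...]   # ladder rung -> weight
    charge_weights: tuple[tuple[int, float], ...] = ((1, 0.05), (2, 0.5), (3, 0.35), (4, 0.1))
    noise: NoiseModel = NoiseModel()
    dp4_spike_fraction: float = 0.05
    dp4_amount: float = 1.0
    dp4_mz: float = DP4_MZ_THEORETICAL
    oacetyl_cap_per_sialic: int = 3

    def __post_init__(self) -> None:
        total = sum(g.abundance for g in self.glycans)
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"{self.species}: abundances sum to {total}, not 100")
        for g in self.glycans:
            comp = parse_topology(g.topology).composition()
            if not comp.is_nglycan_plausible():
                raise ValueError(f"{self.species}: {g.topology} is not a valid N-glycan")

    def topologies(self) -> list[GlycanTopology]:
        return [parse_topology(g.topology) for g in self.glycans]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SpeciesPreset":
        d = json.loads(text)
        d["glycans"] = tuple(PresetGlycan(**g) for g in d["glycans"])
        d["oacetyl_weights"] = tuple((int(k), float(v)) for k, v in d["oacetyl_weights"])
        d["charge_weights"] = tuple((int(k), float(v)) for k, v in d["charge_weights"])
        d["noise"] = NoiseModel(**d["noise"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Serialized alongside every generated dataset."""

    preset: str
    mode: str
    seed: int
    glycans: list[dict]              # topology, composition, abundance, from_study
    total_intensity_scale: float = 1000.0
    dp4_mz: Optional[float] = None
    dp4_amount: Optional[float] = None
    dp4_spike_fraction: Optional[float] = None
    # total glycan amount implied by the standard spike: the measured aliquot
    # is spike_fraction of the pool, so pool = dp4_amount / spike_fraction^2
    # when the standard and aliquot responses are equal per amount
    pool_amount: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ----------------------------------------------------------------------
# Topology template builders
# ----------------------------------------------------------------------

_SIAL = "NeuAc(a2-3)Gal(b1-4)"            # salmonid antenna cap
_DISA = "NeuAc(a2-8)NeuAc(a2-3)Gal(b1-4)"  # di-SA antenna cap
_GAL = "Gal(b1-4)"
_STURGEON = "Gal(a1-?)[Gal(b1-?)]Gal(b1-?)"
_CATFISH = "NeuAc(a2-?)[Gal(b1-?)]Gal(b1-?)"
_GALGAL = "Gal(b1-?)Gal(b1-?)"


def _core(fucose: bool = False) -> str:
    root = "GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc" if fucose else "GlcNAc(b1-4)GlcNAc"
    return root


def nglycan(antennae: Sequence[str], fucose: bool = False) -> str:
    """Assemble a complex N-glycan topology string from antenna cap strings.

    Supports 2-4 antennae: the first two go on the α3/α6 mannoses, the
    third branches the α3 arm (β1-4), the fourth the α6 arm (β1-6).
    """
    if not 2 <= len(antennae) <= 4:
        raise ValueError("2-4 antennae supported")
    a = [f"{cap}GlcNAc" for cap in antennae]
    arm3 = f"{a[0]}(b1-2)"
    if len(antennae) >= 3:
        arm3 += f"[{a[2]}(b1-4)]"
    arm6 = f"{a[1]}(b1-2)"
    if len(antennae) == 4:
        arm6 += f"[{a[3]}(b1-6)]"
    return (f"{arm3}Man(a1-3)[{arm6}Man(a1-6)]Man(b1-4)" + _core(fucose))


def high_mannose(n_mannose: int = 5) -> str:
    """Man5-Man9 high-mannose topologies."""
    if not 5 <= n_mannose <= 9:
        raise ValueError("5-9 mannoses supported")
    extra = n_mannose - 5
    arm3 = "Man(a1-2)" * min(extra, 2) + "Man(a1-3)"
    arm6a = ("Man(a1-2)" if extra >= 3 else "") + "Man(a1-3)"
    arm6b = ("Man(a1-2)" if extra >= 4 else "") + "Man(a1-6)"
    return (f"{arm3}[{arm6a}[{arm6b}]Man(a1-6)]Man(b1-4)" + _core(False))


# the characteristic large shortnose glycan NeuAc1dHex1Hex10HexNAc6:
# tetra-antennary with two Galα(Galβ)Galβ caps, one NeuAc-Gal cap, one bare
# antenna, and core fucose
_SHORTNOSE_BIG = nglycan([_STURGEON, _STURGEON, _SIAL, ""], fucose=True)
# catfish tetra-antennary NeuAc3Hex10HexNAc6: three NeuAc-branched caps plus
# one plain Gal antenna
_CATFISH_BIG = nglycan([_CATFISH, _CATFISH, _CATFISH, _GAL])


def build_presets() -> dict[str, SpeciesPreset]:
    """The five built-in species presets (keys: atlantic-salmon, arctic-char,
    shortnose-sturgeon, atlantic-sturgeon, channel-catfish)."""
    a2s2 = nglycan([_SIAL, _SIAL])
    a2s2f = nglycan([_SIAL, _SIAL], fucose=True)
    a2s1 = nglycan([_SIAL, _GAL])
    a2s0 = nglycan([_GAL, _GAL])
    a3s3 = nglycan([_SIAL, _SIAL, _SIAL])
    a2s3_disa = nglycan([_DISA, _SIAL])
    a3s4_disa = nglycan([_DISA, _SIAL, _SIAL])
    man5 = high_mannose(5)

    salmon = SpeciesPreset(
        species="atlantic-salmon",
        glycans=(
            PresetGlycan(a2s2, 50.0, True),       # dominant biantennary disialylated
            PresetGlycan(a2s1, 10.0),
            PresetGlycan(a2s2f, 5.0),
            PresetGlycan(a3s3, 25.0, True),       # abundant in salmon
            PresetGlycan(a2s3_disa, 1.62),        # di-SA total 2% with the next
            PresetGlycan(a3s4_disa, 0.38, True),  # 0.38% per the study
            PresetGlycan(man5, 3.0),
            PresetGlycan(a2s0, 5.0),
        ),
        oacetyl_weights=((0, 40.0), (1, 30.0), (2, 20.0), (3, 10.0)),
    )
    char = SpeciesPreset(
        species="arctic-char",
        glycans=(
            PresetGlycan(a2s2, 60.0, True),
            PresetGlycan(a2s1, 12.0),
            PresetGlycan(a2s2f, 5.0),
            PresetGlycan(a2s3_disa, 4.88),        # di-SA total 5% with the next
            PresetGlycan(a3s4_disa, 0.12, True),  # 0.12% per the study
            PresetGlycan(man5, 3.0),
            PresetGlycan(a2s0, 15.0),
        ),
        oacetyl_weights=((0, 25.0), (1, 20.0), (2, 15.0), (3, 15.0),
                         (4, 10.0), (5, 10.0), (6, 5.0)),
    )
    st_cap2f = nglycan([_STURGEON, _STURGEON], fucose=True)
    st_cap1 = nglycan([_STURGEON, _SIAL])
    shortnose = SpeciesPreset(
        species="shortnose-sturgeon",
        glycans=(
            PresetGlycan(_SHORTNOSE_BIG, 25.0, True),  # NeuAc1dHex1Hex10HexNAc6
            PresetGlycan(a2s2, 18.0, True),
            PresetGlycan(a3s3, 7.0),
            PresetGlycan(a2s2f, 10.0),
            PresetGlycan(st_cap2f, 10.0),
            PresetGlycan(st_cap1, 5.0),
            PresetGlycan(man5, 3.0),
            PresetGlycan(a2s1, 22.0),
        ),
        oacetyl_weights=((0, 90.0), (1, 10.0)),
    )
    atlantic_sturgeon = SpeciesPreset(
        species="atlantic-sturgeon",
        glycans=(
            PresetGlycan(a2s2, 40.0, True),
            PresetGlycan(a3s3, 25.0, True),
            PresetGlycan(st_cap1, 10.0),
            PresetGlycan(a2s2f, 2.0, True),    # core fucose 2% of the pool
            PresetGlycan(man5, 3.0),
            PresetGlycan(a2s1, 20.0),
        ),
        oacetyl_weights=((0, 80.0), (1, 20.0)),
    )
    cat_a2 = nglycan([_CATFISH, _CATFISH])          # NeuAc2Hex7HexNAc4
    cat_a2s1 = nglycan([_CATFISH, _GALGAL])         # NeuAc1Hex7HexNAc4
    cat_a2s0 = nglycan([_GALGAL, _GALGAL])          # Hex7HexNAc4
    catfish = SpeciesPreset(
        species="channel-catfish",
        glycans=(
            PresetGlycan(cat_a2, 45.0, True),       # most abundant catfish glycan
            PresetGlycan(cat_a2s1, 15.0, True),
            PresetGlycan(_CATFISH_BIG, 8.0, True),  # NeuAc3Hex10HexNAc6
            PresetGlycan(cat_a2s0, 20.0),
            PresetGlycan(man5, 3.0),
            PresetGlycan(high_mannose(8), 9.0),
        ),
        oacetyl_weights=((0, 70.0), (1, 20.0), (2, 10.0)),
    )
    return {p.species: p for p in
            (salmon, char, shortnose, atlantic_sturgeon, catfish)}


# ----------------------------------------------------------------------
# MS1 generation
# ----------------------------------------------------------------------

def _oacetyl_split(comp: MonosaccharideComposition, abundance: float,
                   preset: SpeciesPreset) -> list[tuple[MonosaccharideComposition, float]]:
    """Distribute a glycan's abundance over its native-mode O-acetyl ladder."""
    if comp.sialic == 0:
        return [(comp, abundance)]
    cap = preset.oacetyl_cap_per_sialic * comp.sialic
    rungs = [(n, w) for n, w in preset.oacetyl_weights if n <= cap]
    total = sum(w for _, w in rungs)
    from dataclasses import replace
    return [(replace(comp, oacetyl=n), abundance * w / total) for n, w in rungs]


def generate_ms1(preset: SpeciesPreset, mode: str = "permethylated+",
                 seed: int = 0,
                 noise: Optional[NoiseModel] = None,
                 isotope_depth: int = 4,
                 mz_range: tuple[float, float] = (600.0, 2000.0),
                 scale: float = 1000.0,
                 ) -> tuple[PeakList, GroundTruth]:
    """Simulate a centroided MS1 profile of a species preset.

    For each glycan, isotope clusters (to *isotope_depth*) are emitted at
    every charge state of the preset's mixing weights, keeping only ions
    inside *mz_range* (the TIM scan range); the Dp4 standard peak is spiked
    in permethylated mode.  Deterministic for a given (preset, mode, seed).
    """
    if mode not in ("permethylated+", "native-"):
        raise ValueError(f"mode must be 'permethylated+' or 'native-', got {mode!r}")
    noise = preset.noise if noise is None else noise
    rng = np.random.default_rng(seed)
    native = mode == "native-"
    derivatization = "native" if native else "permethylated"

    species_list: list[tuple[MonosaccharideComposition, float]] = []
    truth_glycans = []
    for g in preset.glycans:
        topo = parse_topology(g.topology)
        comp = topo.composition()
        if comp.oacetyl and not native:
            warnings.warn(
                f"{preset.species}: O-acetyl groups on {g.topology} are erased "
                "by permethylation; collapsing to the base composition")
            comp = comp.without_oacetyl()
        truth_glycans.append({
            "topology": g.topology,
            "composition": str(comp.without_oacetyl() if not native else comp),
            "abundance": g.abundance,
            "abundance_from_study": g.abundance_from_study,
        })
        if native:
            species_list.extend(_oacetyl_split(comp, g.abundance, preset))
        else:
            species_list.append((comp, g.abundance))

    charge_weights = [(z, w) for z, w in preset.charge_weights if w > 0]
    peaks: list[Peak] = []
    for comp, abundance in species_list:
        m0 = neutral_mass(comp, derivatization)
        iso = isotope_distribution(elemental_formula(comp, derivatization),
                                   isotope_depth)
        iso = iso / iso.sum()

        def cluster_in_range(z: int) -> bool:
            sign = -PROTON if native else NA
            lo = (m0 + z * sign) / z
            hi = (m0 + isotope_depth * NEUTRON_SHIFT + z * sign) / z
            return mz_range[0] <= lo and hi <= mz_range[1]

        # only in-window charge states carry signal; renormalize per glycan
        # so summed observed intensity stays proportional to true abundance
        usable = [(z, w) for z, w in charge_weights if cluster_in_range(z)]
        if not usable:
            continue
        wsum = sum(w for _, w in usable)
        for z, w in usable:
            base = abundance / 100.0 * (w / wsum) * scale
            for k, rel in enumerate(iso):
                if native:
                    mz = (m0 + k * NEUTRON_SHIFT - z * PROTON) / z
                else:
                    mz = (m0 + k * NEUTRON_SHIFT + z * NA) / z
                jitter = rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd else 0.0
                fac = rng.lognormal(0.0, noise.intensity_cv) if noise.intensity_cv else 1.0
                peaks.append(Peak(mz + jitter, base * rel * fac))

    dp4_mz = dp4_amount = None
    if not native:
        # standard response proportional to the spike fraction of the pool
        dp4_intensity = preset.dp4_spike_fraction * scale
        fac = rng.lognormal(0.0, noise.intensity_cv) if noise.intensity_cv else 1.0
        jitter = rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd else 0.0
        peaks.append(Peak(preset.dp4_mz + jitter, dp4_intensity * fac, 1))
        dp4_mz, dp4_amount = preset.dp4_mz, preset.dp4_amount

    n_spurious = rng.poisson(noise.spurious_rate * len(peaks)) if noise.spurious_rate else 0
    floor = 0.001 * scale
    for _ in range(n_spurious):
        peaks.append(Peak(rng.uniform(*mz_range), floor * rng.uniform(0.2, 1.0)))

    peaks.sort(key=lambda p: p.mz)
    pool = None
    if not native:
        pool = preset.dp4_amount / preset.dp4_spike_fraction ** 2
        for g in truth_glycans:
            g["amount"] = g["abundance"] / 100.0 * pool
    truth = GroundTruth(
        preset=preset.species, mode=mode, seed=seed, glycans=truth_glycans,
        total_intensity_scale=scale, dp4_mz=dp4_mz, dp4_amount=dp4_amount,
        dp4_spike_fraction=preset.dp4_spike_fraction if not native else None,
        pool_amount=pool)
    return PeakList(peaks, source=f"synthetic:{preset.species}:{seed}", mode=mode), truth


# ----------------------------------------------------------------------
# MSn generation
# ----------------------------------------------------------------------

def generate_msn(topology: GlycanTopology,
                 stage_path: Sequence[int] = (2, 3),
                 seed: int = 0,
                 dropout: float = 0.0,
                 spurious_rate: float = 0.0,
                 precursor_is_b: bool = True) -> FragmentObservation:
    """Simulate an MSn fragment list for a topology.

    *stage_path* lists the MSn stages traversed (e.g. ``(2, 3)`` for
    MS2 -> MS3); its length bounds the number of sequential cleavages.  Each
    predicted fragment survives with probability ``1 - dropout``; spurious
    fragments are added at *spurious_rate* per true fragment.
    """
    rng = np.random.default_rng(seed)
    max_cleavages = max(1, len(stage_path))
    predicted = predict_fragments(topology, max_cleavages, precursor_is_b)
    fragments = [f.mz for f in predicted if rng.uniform() >= dropout]
    if spurious_rate and predicted:
        lo = min(f.mz for f in predicted) * 0.5
        hi = max(f.mz for f in predicted)
        for _ in range(rng.poisson(spurious_rate * len(predicted))):
            fragments.append(float(rng.uniform(lo, hi)))
    fragments.sort()
    if precursor_is_b:
        precursor_mz = b_fragment_mz(topology.composition().without_oacetyl())
    else:
        precursor_mz = neutral_mass(topology.composition().without_oacetyl()) + NA
    return FragmentObservation(
        stage=max(stage_path) if stage_path else 2,
        precursor_mz=precursor_mz, precursor_charge=1,
        fragments=fragments,
        title=f"synthetic MS{max(stage_path) if stage_path else 2} of {topology}")


# ----------------------------------------------------------------------
# Digestion series
# ----------------------------------------------------------------------

def _stochastic_digest(topo: GlycanTopology, rule: DigestRule, p_site: float,
                       rng: np.random.Generator) -> tuple[GlycanTopology, int]:
    """Exhaustive digestion with per-site success probability *p_site*."""
    from .digestion import _removable_leaves
    work = topo.copy()
    removed = 0
    resisted: set[int] = set()
    while True:
        eligible = [(p, l) for p, l in _removable_leaves(work, rule)
                    if id(l) not in resisted]
        if not eligible:
            break
        progress = False
        for parent, leaf in eligible:
            if rng.uniform() < p_site:
                parent.children.remove(leaf)
                removed += 1
                progress = True
            else:
                resisted.add(id(leaf))
        if not progress:
            break
    return work, removed


def generate_digest_series(preset: SpeciesPreset,
                           rules: Sequence[DigestRule],
                           seed: int = 0,
                           mode: str = "permethylated+",
                           partial_probability: float = 1.0,
                           noise: Optional[NoiseModel] = None,
                           ) -> tuple[list[PeakList], list[GroundTruth]]:
    """Before/after MS1 peak lists for an ordered enzyme series.

    State 0 is undigested; state i applies ``rules[:i]`` exhaustively (with
    optional per-site partial-digestion probability) to every preset glycan,
    then re-simulates MS1.  Returns one (PeakList, GroundTruth) pair per
    state, sharing deterministic seeds derived from *seed*.
    """
    rng = np.random.default_rng(seed)
    states: list[list[GlycanTopology]] = [preset.topologies()]
    for rule in rules:
        prev = states[-1]
        nxt = []
        for topo in prev:
            if partial_probability >= 1.0:
                product, _ = apply_enzyme(topo, rule, exhaustive=True)
            else:
                product, _ = _stochastic_digest(topo, rule, partial_probability, rng)
            nxt.append(product)
        states.append(nxt)

    peaklists, truths = [], []
    for i, topos in enumerate(states):
        digested = SpeciesPreset(
            species=preset.species + (f"+{'+'.join(r.enzyme for r in rules[:i])}" if i else ""),
            glycans=tuple(
                PresetGlycan(t.serialize(), g.abundance, g.abundance_from_study)
                for t, g in zip(topos, preset.glycans)),
            oacetyl_weights=preset.oacetyl_weights,
            charge_weights=preset.charge_weights,
            noise=preset.noise,
            dp4_spike_fraction=preset.dp4_spike_fraction,
            dp4_amount=preset.dp4_amount,
            dp4_mz=preset.dp4_mz,
            oacetyl_cap_per_sialic=preset.oacetyl_cap_per_sialic)
        pl, gt = generate_ms1(digested, mode=mode, seed=(seed + 7919 * i) % (2**31),
                              noise=noise)
        peaklists.append(pl)
        truths.append(gt)
    return peaklists, truths
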