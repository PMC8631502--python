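"""Species-level glycan feature profiling.

Reduces an assigned glycan profile to the comparative feature set used for
cross-species serum glycomics: di-SA prevalence, core fucosylation,
high-mannose content, a sialylation-degree histogram, and (native mode only)
the O-acetylation ladder.  Feature prevalences are percentages of the total
retained glycan abundance.

Caveat carried into output: with MS1-only data any dHex is attributed to the
chitobiose core ("core fucosylation"); antenna fucose is indistinguishable
by mass alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .glycan_model import (
    MOTIF_LIBRARY,
    GlycanTopology,
    MonosaccharideComposition,
    match_motif,
)
from .msn import detect_disa

__all__ = [
    "ProfileEntry",
    "GlycanProfile",
    "feature_prevalence",
    "oacetyl_ladder",
    "compare_profiles",
    "average_replicates",
    "plot_features",
]

SIGNATURE_MOTIFS = ("diSA", "sturgeon-cap", "catfish-cap")


@dataclass(frozen=True)
class ProfileEntry:
    composition: MonosaccharideComposition
    abundance: float                       # relative, % of profile
    topology: Optional[GlycanTopology] = None
    amount: Optional[float] = None         # absolute, via internal standard


@dataclass
class GlycanProfile:
    """Assigned glycans with relative abundances for one sample."""

    entries: list[ProfileEntry]
    species: str = ""
    mode: str = "permethylated+"           # "permethylated+" | "native-"

    def __post_init__(self) -> None:
        total = sum(e.abundance for e in self.entries)
        if self.entries and abs(total - 100.0) > 0.01:
            raise ValueError(
                f"relative abundances must sum to 100 +- 0.01, got {total:.4f}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def is_native(self) -> bool:
        return self.mode.startswith("native")

    @classmethod
    def from_abundances(cls, abundances: dict[MonosaccharideComposition, float],
                        species: str = "", mode: str = "permethylated+",
                        topologies: Optional[dict] = None) -> "GlycanProfile":
        topologies = topologies or {}
        return cls(
            [ProfileEntry(c, a, topologies.get(c)) for c, a in abundances.items()],
            species=species, mode=mode)

    def renormalized(self) -> "GlycanProfile":
        total = sum(e.abundance for e in self.entries)
        if not total:
            return self
        return GlycanProfile(
            [replace(e, abundance=100.0 * e.abundance / total) for e in self.entries],
            self.species, self.mode)


# ----------------------------------------------------------------------

def feature_prevalence(profile: GlycanProfile) -> dict:
    """Structural-feature percentages of the total profile.

    Returns di-SA, core fucose, high-mannose, sialylated prevalences, a
    sialylation-degree histogram (weights summing to 100 over a non-empty
    profile), and in native mode an O-acetyl count histogram; native-only
    features on a permethylated profile come back as None ("not applicable").
    """
    features: dict = {
        "disa_pct": 0.0,
        "core_fucose_pct": 0.0,
        "high_mannose_pct": 0.0,
        "sialylated_pct": 0.0,
        "sialylation_histogram": {},
        "oacetyl_histogram": None,
    }
    if not profile.entries:
        return features
    sial_hist: dict[int, float] = {}
    oac_hist: dict[int, float] = {}
    for e in profile.entries:
        c = e.composition
        if (detect_disa(c) or 0) >= 1:
            features["disa_pct"] += e.abundance
        if c.dhex >= 1:
            features["core_fucose_pct"] += e.abundance
        if c.hexnac == 2:
            features["high_mannose_pct"] += e.abundance
        if c.sialic >= 1:
            features["sialylated_pct"] += e.abundance
        sial_hist[c.sialic] = sial_hist.get(c.sialic, 0.0) + e.abundance
        oac_hist[c.oacetyl] = oac_hist.get(c.oacetyl, 0.0) + e.abundance
    features["sialylation_histogram"] = dict(sorted(sial_hist.items()))
    if profile.is_native:
        features["oacetyl_histogram"] = dict(sorted(oac_hist.items()))
    return features


def oacetyl_ladder(profile: GlycanProfile,
                   base: MonosaccharideComposition) -> dict:
    """O-acetyl ladder of a native-mode profile for one base composition.

    Groups assignments differing from *base* only in O-acetyl count and
    reports per-rung abundances and the maximum rung observed.
    """
    if not profile.is_native:
        raise ValueError(
            "O-acetyl ladders exist only in native mode; permethylation "
            "removes O-acetyl groups")
    base = base.without_oacetyl()
    rungs: dict[int, float] = {}
    for e in profile.entries:
        if e.composition.without_oacetyl() == base:
            n = e.composition.oacetyl
            rungs[n] = rungs.get(n, 0.0) + e.abundance
    return {
        "base": base,
        "rungs": dict(sorted(rungs.items())),
        "max_oacetyl": max(rungs) if rungs else 0,
    }


# ----------------------------------------------------------------------

def _signature_flags(profile: GlycanProfile) -> dict[str, float]:
    """Abundance carrying each signature motif, from topology annotations."""
    out = {name: 0.0 for name in SIGNATURE_MOTIFS}
    for e in profile.entries:
        if e.topology is None:
            continue
        for name in SIGNATURE_MOTIFS:
            if match_motif(e.topology, MOTIF_LIBRARY[name]):
                out[name] += e.abundance
    return out


def compare_profiles(profiles: Sequence[GlycanProfile]) -> pd.DataFrame:
    """Species x feature matrix with signature-motif flags.

    Rows are profiles (indexed by species); scalar features are percentages.
    Motif columns (``motif_*``) are filled from topology annotations when
    present and NaN otherwise.
    """
    rows = []
    for p in profiles:
        f = feature_prevalence(p)
        row = {
            "species": p.species,
            "mode": p.mode,
            "disa_pct": f["disa_pct"],
            "core_fucose_pct": f["core_fucose_pct"],
            "high_mannose_pct": f["high_mannose_pct"],
            "sialylated_pct": f["sialylated_pct"],
        }
        has_topo = any(e.topology is not None for e in p.entries)
        sigs = _signature_flags(p) if has_topo else {m: np.nan for m in SIGNATURE_MOTIFS}
        for m in SIGNATURE_MOTIFS:
            row[f"motif_{m}_pct"] = sigs[m]
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")


def average_replicates(replicates: Sequence[GlycanProfile]) -> pd.DataFrame:
    """Mean +- SD of scalar features over biological replicates."""
    if not replicates:
        raise ValueError("no replicate profiles given")
    frames = compare_profiles(replicates)
    num = frames.drop(columns=["mode"])
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


def plot_features(matrix: pd.DataFrame, path: Optional[str] = None):
    """Grouped bar chart of the scalar feature percentages per species."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [c for c in ("disa_pct", "core_fucose_pct", "high_mannose_pct",
                        "sialylated_pct") if c in matrix.columns]
    ax = matrix[cols].plot.bar(rot=30, figsize=(8, 4))
    ax.set_ylabel("% of total N-glycan profile")
    ax.set_xlabel("")
    ax.legend([c.replace("_pct", "").replace("_", " ") for c in cols])
    fig = ax.get_figure()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
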