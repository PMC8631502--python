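"""Peak-list handling for direct-infusion MS1 profiles.

Covers the quantification workflow used with total ion mapping (TIM):
overlapping precursor windows, isotope-cluster collapse, charge-state
summation, the 3%-of-base-peak detection threshold, and normalization
against a co-injected permethylated maltotetraose (Dp4) standard.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .glycan_model import NEUTRON_SHIFT

__all__ = [
    "Peak",
    "PeakList",
    "TimWindow",
    "tim_windows",
    "collapse_isotope_clusters",
    "IsotopeCluster",
    "sum_charge_states",
    "threshold_filter",
    "quantify_vs_standard",
]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be nonnegative, got {self.intensity}")


@dataclass
class PeakList:
    """Centroided peak list with provenance metadata."""

    peaks: list[Peak]
    source: str = ""
    mode: str = "permethylated+"    # "permethylated+" | "native-"

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def sorted_by_mz(self) -> "PeakList":
        return PeakList(sorted(self.peaks, key=lambda p: p.mz), self.source, self.mode)

    @property
    def total_intensity(self) -> float:
        return sum(p.intensity for p in self.peaks)

    # -- CSV I/O: header `mz,intensity[,charge]` ------------------------
    @classmethod
    def read_csv(cls, path: str | Path, mode: str = "permethylated+") -> "PeakList":
        peaks = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "mz" not in reader.fieldnames \
                    or "intensity" not in reader.fieldnames:
                raise ValueError(f"{path}: expected CSV header 'mz,intensity[,charge]'")
            for lineno, row in enumerate(reader, start=2):
                try:
                    charge = row.get("charge")
                    peaks.append(Peak(
                        float(row["mz"]), float(row["intensity"]),
                        int(charge) if charge not in (None, "", "NA") else None))
                except (TypeError, ValueError) as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        return cls(peaks, source=str(path), mode=mode)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["mz", "intensity", "charge"])
            for p in self.peaks:
                writer.writerow([f"{p.mz:.5f}", f"{p.intensity:.4f}",
                                 "" if p.charge is None else p.charge])


# ----------------------------------------------------------------------
# TIM windows
# ----------------------------------------------------------------------

@dataclass
class TimWindow:
    start: float
    end: float
    intensity: float = 0.0

    @property
    def width(self) -> float:
        return self.end - self.start

    def contains(self, mz: float) -> bool:
        return self.start <= mz <= self.end


def tim_windows(range_start: float, range_end: float,
                width: float = 2.8, overlap: float = 0.8,
                peaks: Optional[Iterable[Peak]] = None) -> list[TimWindow]:
    """Overlapping precursor windows stepped by ``width - overlap``.

    The first window starts at *range_start*; windows are emitted until one
    ends at or beyond *range_end*.  With *peaks* given, each window carries
    the summed intensity of the peaks it contains.
    """
    if width <= overlap:
        raise ValueError(f"window width ({width}) must exceed overlap ({overlap})")
    if overlap < 0:
        raise ValueError("overlap must be nonnegative")
    step = width - overlap
    windows = []
    start = range_start
    while True:
        windows.append(TimWindow(start, start + width))
        if start + width >= range_end:
            break
        start += step
    if peaks is not None:
        pts = sorted((p.mz, p.intensity) for p in peaks)
        mzs = np.array([m for m, _ in pts])
        ints = np.array([i for _, i in pts])
        for w in windows:
            lo, hi = np.searchsorted(mzs, w.start), np.searchsorted(mzs, w.end, "right")
            w.intensity = float(ints[lo:hi].sum())
    return windows


# ----------------------------------------------------------------------
# Isotope-cluster collapse
# ----------------------------------------------------------------------

@dataclass
class IsotopeCluster:
    """A collapsed isotope envelope: one response per glycan ion species."""

    mz: float                 # m/z of the most intense member
    intensity: float          # summed over members
    charge: Optional[int]     # inferred from member spacing; None if unknown
    members: list[Peak] = field(default_factory=list)
    # intensity-weighted estimate of the lowest member's m/z from all member
    # positions (each shifted back by j*1.00336/z) — averages out jitter
    monoisotopic_mz: float = 0.0
    k_top: int = 0            # index of the most intense member from the lowest


def collapse_isotope_clusters(peaks: Sequence[Peak],
                              z_hypotheses: Sequence[int] = (1, 2, 3, 4),
                              tolerance: float = 0.05) -> list[IsotopeCluster]:
    """Group peaks spaced by 1.00336/z into single responses.

    Seeds are taken in decreasing intensity order.  For each seed every
    charge hypothesis is tried; members are collected at seed + j*1.00336/z
    (j = ..., -1, 0, 1, ...) within *tolerance*.  The winning hypothesis
    explains the most peaks (a subharmonic z' of the true z only reaches
    every (z/z')-th isotopologue), then has the smallest mean spacing
    residual, with remaining ties going to lower z.  Peaks that join no
    multi-peak cluster pass through as singletons with unknown charge
    (unless they carry one).
    """
    order = sorted(range(len(peaks)), key=lambda i: -peaks[i].intensity)
    mzs = np.array([p.mz for p in peaks])
    taken = np.zeros(len(peaks), bool)
    clusters: list[IsotopeCluster] = []

    for seed in order:
        if taken[seed]:
            continue
        best = None  # ((-n_members, residual, z), member_indices, k_offset)
        for z in z_hypotheses:
            if peaks[seed].charge is not None and peaks[seed].charge != z:
                continue
            spacing = NEUTRON_SHIFT / z
            members = [seed]
            # walk down then up from the seed
            for direction in (-1, +1):
                j = direction
                while True:
                    target = peaks[seed].mz + j * spacing
                    cand = np.where(~taken & (np.abs(mzs - target) <= tolerance))[0]
                    if len(cand) == 0:
                        break
                    pick = cand[np.argmin(np.abs(mzs[cand] - target))]
                    if pick in members:
                        break
                    members.append(int(pick))
                    j += direction
            if len(members) < 2:
                continue
            members_sorted = sorted(members, key=lambda i: peaks[i].mz)
            resid = np.mean([
                abs(peaks[m].mz - peaks[seed].mz
                    - round((peaks[m].mz - peaks[seed].mz) / spacing) * spacing)
                for m in members_sorted])
            key = (-len(members), round(float(resid), 9), z)
            if best is None or key < best[0]:
                best = (key, members_sorted)
        if best is None:
            taken[seed] = True
            clusters.append(IsotopeCluster(
                mz=peaks[seed].mz, intensity=peaks[seed].intensity,
                charge=peaks[seed].charge, members=[peaks[seed]],
                monoisotopic_mz=peaks[seed].mz, k_top=0))
            continue
        (_, _, z), members = best[0], best[1]
        for m in members:
            taken[m] = True
        member_peaks = [peaks[m] for m in members]
        # edge members far weaker than the envelope maximum are almost
        # certainly absorbed spurious peaks; a fake leading member would
        # shift the whole monoisotopic estimate down one neutron.  They
        # stay in the cluster's intensity but not in the m/z estimate.
        max_i = max(p.intensity for p in member_peaks)
        trimmed = list(member_peaks)
        # a real envelope rises from its monoisotopic peak (k0/k1 >~ 0.35
        # for glycans below ~5 kDa even after intensity noise), so a leading
        # member far weaker than its successor is not part of the envelope;
        # assignment searches the starting index for the cases this misses
        while len(trimmed) > 1 and trimmed[0].intensity < max(
                0.25 * trimmed[1].intensity, 0.05 * max_i):
            trimmed.pop(0)
        while len(trimmed) > 1 and trimmed[-1].intensity < 0.05 * max_i:
            trimmed.pop()
        top = max(trimmed, key=lambda p: p.intensity)
        k_of_top = trimmed.index(top)
        spacing = NEUTRON_SHIFT / z
        lowest = trimmed[0].mz
        offsets = [round((p.mz - lowest) / spacing) for p in trimmed]
        # unweighted mean: every member carries the same jitter, so this
        # shrinks the m/z error by sqrt(n_members)
        mono = float(np.mean(
            [p.mz - j * spacing for p, j in zip(trimmed, offsets)]))
        clusters.append(IsotopeCluster(
            mz=top.mz,
            intensity=sum(p.intensity for p in member_peaks),
            charge=z,
            members=member_peaks,
            monoisotopic_mz=mono,
            k_top=k_of_top,
        ))
    return clusters


# ----------------------------------------------------------------------
# Charge-state summation, thresholding, standard-based quantification
# ----------------------------------------------------------------------

def sum_charge_states(assignments: Iterable[tuple[object, float]]) -> dict:
    """Sum intensities of detections of the same composition across charge
    states (and collapsed isotopologues): ``[(composition, intensity), ...]``
    -> ``{composition: total}``."""
    totals: dict = {}
    for key, intensity in assignments:
        totals[key] = totals.get(key, 0.0) + intensity
    return totals


def threshold_filter(intensities: dict, fraction: float = 0.03) -> dict:
    """Keep entries with intensity >= fraction x the most intense entry."""
    if not intensities:
        return {}
    cutoff = fraction * max(intensities.values())
    return {k: v for k, v in intensities.items() if v >= cutoff}


def quantify_vs_standard(intensities: dict, standard_intensity: float,
                         standard_amount: float = 1.0,
                         spike_fraction: float = 0.05) -> dict:
    """Absolute amounts from the Dp4 internal-standard response.

    The standard is co-injected with *spike_fraction* of the analyte pool, so
    ``amount_i = (I_i / I_std) * standard_amount / spike_fraction``.
    """
    if standard_intensity <= 0:
        raise ValueError(
            "standard peak absent or zero intensity; absolute quantification "
            "is impossible — use relative-only mode")
    if not 0 < spike_fraction <= 1:
        raise ValueError(f"spike fraction must be in (0, 1], got {spike_fraction}")
    scale = standard_amount / (standard_intensity * spike_fraction)
    return {k: v * scale for k, v in intensities.items()}
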