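"""Binary occupancy trajectories and accessibility classification.

A locus bound across an ordered series of ChIP-seq conditions gets a binary
code such as ``"110"``: digit i is 1 iff the merged locus contains a summit
from condition i.  With k conditions there are ``2**k - 1`` possible codes
(the all-zero code cannot occur because loci are built from observed
summits): 7 groups for a three-day single-factor series, 15 for two factors
at two days.

The same module classifies loci by starting-state accessibility tier
(low / medium / high fragment counts in the fibroblast state) and by
open/closed chromatin trajectory between two ATAC-seq conditions
(PO permanently open, OC open-to-close, CO close-to-open).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import (
    GenomicInterval,
    MergedLocus,
    Summit,
    merge_summits,
    overlaps_any,
    write_intervals,
)

__all__ = [
    "OccupancyTrajectory",
    "TierThresholds",
    "assign_occupancy_codes",
    "enumerate_trajectories",
    "accessibility_tier",
    "chromatin_trajectory",
    "trajectory_summary",
    "write_trajectory_beds",
]


@dataclass
class OccupancyTrajectory:
    locus: MergedLocus
    code: str

    def __post_init__(self) -> None:
        if "1" not in self.code:
            raise ValueError("all-zero occupancy codes are not emitted")


@dataclass
class TierThresholds:
    """Raw-count boundaries for accessibility tiers.

    ``count < low_below`` is low, ``low_below <= count <= high_above`` is
    medium, ``count > high_above`` is high (both boundaries fall in the
    medium tier).
    """

    low_below: float = 15
    high_above: float = 30

    def __post_init__(self) -> None:
        if self.low_below > self.high_above:
            raise ValueError("low_below must be <= high_above")


def assign_occupancy_codes(
    conditions: Mapping[str, Sequence[Summit]] | Sequence[tuple[str, Sequence[Summit]]],
    max_dist: int = 100,
) -> list[OccupancyTrajectory]:
    """Merge summits from ordered conditions and assign binary codes.

    ``conditions`` maps condition label -> summits, in chronological /
    factor order; the code's digit order follows it.  Loci are
    ``merge_summits`` over the union of all conditions' summits (the summit
    ``source`` is overwritten with the condition label).
    """
    items = list(conditions.items()) if isinstance(conditions, Mapping) else list(conditions)
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate condition labels: {labels}")
    pooled: list[Summit] = []
    for lab, summits in items:
        pooled.extend(Summit(s.chrom, s.pos, lab) for s in summits)
    out = []
    for locus in merge_summits(pooled, max_dist=max_dist):
        present = locus.sources
        code = "".join("1" if lab in present else "0" for lab in labels)
        out.append(OccupancyTrajectory(locus, code))
    return out


def enumerate_trajectories(k: int) -> list[str]:
    """All non-zero binary codes of length k, in descending binary order."""
    if k < 1:
        raise ValueError("need at least one condition")
    return [format(v, f"0{k}b") for v in range(2**k - 1, 0, -1)]


def accessibility_tier(count: float, thresholds: TierThresholds | None = None) -> str:
    """Tier a locus by its raw fragment count in the reference condition."""
    if thresholds is None:
        thresholds = TierThresholds()
    if count < 0:
        raise ValueError(f"negative count: {count}")
    if count < thresholds.low_below:
        return "low"
    if count <= thresholds.high_above:
        return "medium"
    return "high"


def chromatin_trajectory(
    mef_peaks: Sequence[GenomicInterval],
    later_peaks: Sequence[GenomicInterval],
) -> list[tuple[GenomicInterval, str]]:
    """Label PO / OC / CO chromatin trajectories between two peak sets.

    The locus universe is the overlap-merged union of both peak sets; each
    universe locus is labelled PO (overlaps both), OC (reference/MEF only) or
    CO (later condition only).  Presence is >= 1 bp interval overlap.
    """
    universe = _merge_overlapping(list(mef_peaks) + list(later_peaks))
    in_mef = overlaps_any(universe, mef_peaks)
    in_later = overlaps_any(universe, later_peaks)
    out = []
    for locus, m, l in zip(universe, in_mef, in_later):
        label = "PO" if (m and l) else ("OC" if m else "CO")
        out.append((locus, label))
    return out


def _merge_overlapping(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals, merging any that share >= 1 bp."""
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def trajectory_summary(trajectories: Sequence[OccupancyTrajectory]) -> pd.DataFrame:
    """Per-code locus counts and fractions, descending binary code order."""
    if not trajectories:
        return pd.DataFrame(columns=["code", "n", "fraction"])
    k = len(trajectories[0].code)
    counts = pd.Series([t.code for t in trajectories]).value_counts()
    rows = [
        {"code": code, "n": int(counts.get(code, 0)),
         "fraction": counts.get(code, 0) / len(trajectories)}
        for code in enumerate_trajectories(k)
    ]
    df = pd.DataFrame(rows)
    return df[df["n"] > 0].reset_index(drop=True)


def write_trajectory_beds(
    trajectories: Sequence[OccupancyTrajectory], outdir, prefix: str = "loci"
) -> pd.DataFrame:
    """Write one BED per occupied code (``loci_110.bed``) plus a summary TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = trajectory_summary(trajectories)
    for code in summary["code"]:
        ivs = [
            t.locus.to_interval(name=t.code)
            for t in trajectories
            if t.code == code
        ]
        write_intervals(ivs, outdir / f"{prefix}_{code}.bed", format="bed")
    summary.to_csv(outdir / f"{prefix}_summary.tsv", sep="\t", index=False)
    if summary.empty:
        warnings.warn("no occupied trajectory codes to write")
    return summary
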