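"""STARR-seq consensus enhancer calling and input-normalized activity.

An episomal reporter peak is only trusted as a true enhancer when it is
called on the pooled (replicate-merged) reads *and* independently supported
by at least ``min_replicates`` individual replicates — the standard
reproducibility filter for STARR-seq.  Activity profiles at bound regions
are depth-normalized reporter coverage minus depth-normalized input
coverage, binned across a window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, overlaps_any
from .signal import FragmentSet, heatmap_matrix

__all__ = [
    "StarrCallSet",
    "call_consensus_enhancers",
    "input_normalized_signal",
    "overlap_fraction",
]


@dataclass
class StarrCallSet:
    """Per-replicate and pooled peak calls for one STARR-seq experiment."""

    replicate_peaks: list[list[GenomicInterval]]
    merged_peaks: list[GenomicInterval]
    min_replicates: int = 2

    def __post_init__(self) -> None:
        if len(self.replicate_peaks) == 0:
            raise ValueError("need at least one replicate peak set")
        if self.min_replicates > len(self.replicate_peaks):
            raise ValueError("min_replicates exceeds the number of replicates")


def call_consensus_enhancers(calls: StarrCallSet) -> list[GenomicInterval]:
    """Merged peaks supported by >= min_replicates distinct replicates.

    Support is >= 1 bp overlap with any peak of the replicate; a replicate
    counts once no matter how many of its peaks touch the merged peak.
    Output coordinates are the merged-peak coordinates (a subset of
    ``merged_peaks``), order preserved.
    """
    if len(calls.replicate_peaks) < 2:
        raise ValueError("consensus calling needs >= 2 replicates")
    support = np.zeros(len(calls.merged_peaks), dtype=int)
    for rep in calls.replicate_peaks:
        support += np.asarray(overlaps_any(calls.merged_peaks, rep), dtype=int)
    return [
        peak for peak, s in zip(calls.merged_peaks, support)
        if s >= calls.min_replicates
    ]


def input_normalized_signal(
    starr_coverage: FragmentSet,
    input_coverage: FragmentSet,
    loci: Sequence,
    window: int = 2000,
    n_bins: int = 200,
) -> np.ndarray:
    """Per-locus binned (fpkpm reporter - fpkpm input) activity profile.

    Both libraries are depth-normalized before subtraction, so doubling both
    depths leaves the profile unchanged and swapping the libraries flips its
    sign.  Default bin size 10 bp (window 2000 / 200 bins).
    """
    if not starr_coverage.fragments or not input_coverage.fragments:
        raise ValueError("both libraries must be non-empty")
    starr = heatmap_matrix(loci, starr_coverage, window=window, n_bins=n_bins)
    inp = heatmap_matrix(loci, input_coverage, window=window, n_bins=n_bins)
    return starr - inp


def overlap_fraction(
    query: Sequence[GenomicInterval], reference: Sequence[GenomicInterval]
) -> float:
    """Fraction of query intervals overlapping >= 1 reference interval."""
    if len(query) == 0:
        raise ValueError("query must be non-empty")
    return float(np.mean(overlaps_any(query, reference)))
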