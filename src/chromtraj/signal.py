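"""Coverage quantification, normalization and motif-accessibility deviations.

Two normalizations are supported, matching how time-course ChIP/ATAC
boxplots and heatmaps are usually prepared:

* **fpkpm** — fragments per kilobase of region per million library
  fragments, for ATAC signal and heatmap rows;
* **pseudo-count + quantile** — add 1 to raw counts and quantile-normalize
  columns, for ChIP libraries whose sizes differ too much for simple
  depth scaling.

``motif_deviation`` is a compact re-derivation of the chromVAR-style
accessibility deviation: for a motif-marked peak set m and sample s the
expected count is the set's share of total accessibility times the sample's
depth, the raw deviation is (observed - expected)/expected, and a z-score is
formed against background peak sets sampled to match the set's per-peak mean
accessibility (quantile-binned matching).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, MergedLocus

__all__ = [
    "FragmentSet",
    "SignalMatrix",
    "DeviationResult",
    "count_coverage",
    "normalize_fpkpm",
    "quantile_normalize",
    "accessibility_ratio",
    "heatmap_matrix",
    "motif_deviation",
]


@dataclass
class FragmentSet:
    """A sequencing library as genomic fragments plus its total depth."""

    sample: str
    fragments: list[GenomicInterval]
    library_size: int | None = None

    def __post_init__(self) -> None:
        if self.library_size is None:
            self.library_size = len(self.fragments)
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")


@dataclass
class SignalMatrix:
    """Loci x samples signal values with the normalization recorded."""

    values: pd.DataFrame
    normalization: str = "raw"
    pseudo_count: float = 0.0


def _locus_bounds(locus) -> tuple[str, int, int]:
    if isinstance(locus, MergedLocus):
        return locus.chrom, locus.start, locus.end
    return locus.chrom, locus.start, locus.end


def count_coverage(loci: Sequence, fragments: FragmentSet) -> np.ndarray:
    """Number of fragments overlapping each locus (>= 1 bp, half-open).

    bedtools ``multicov`` semantics: a fragment is counted for every locus
    it overlaps.
    """
    trees: dict[str, IntervalTree] = {}
    for i, locus in enumerate(loci):
        chrom, start, end = _locus_bounds(locus)
        trees.setdefault(chrom, IntervalTree()).addi(start, end, i)
    counts = np.zeros(len(loci), dtype=int)
    for frag in fragments.fragments:
        tree = trees.get(frag.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(frag.start, frag.end):
            counts[hit.data] += 1
    return counts


def normalize_fpkpm(count, locus_length, library_size) -> "float | np.ndarray":
    """Fragments per kbp of region per million library fragments."""
    locus_length = np.asarray(locus_length, dtype=float)
    if np.any(locus_length <= 0):
        raise ValueError("locus_length must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    out = np.asarray(count, dtype=float) / (locus_length / 1e3) / (library_size / 1e6)
    return float(out) if out.ndim == 0 else out


def quantile_normalize(matrix: SignalMatrix, pseudo_count: float = 1.0) -> SignalMatrix:
    """Pseudo-count then classic quantile normalization across samples.

    Every column is replaced by the mean of column-wise sorted values at its
    ranks; tied values receive the mean of the reference values over their
    rank range.  Afterwards all columns share an identical sorted vector.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = values.to_numpy(dtype=float) + pseudo_count
    order = np.sort(x, axis=0)
    reference = order.mean(axis=1)
    ref_cumsum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        # ties span ranks [min..max]; each member gets the mean of the
        # reference distribution over that whole rank range
        col = pd.Series(x[:, j])
        lo = col.rank(method="min").to_numpy().astype(int) - 1
        hi = col.rank(method="max").to_numpy().astype(int) - 1
        out[:, j] = (ref_cumsum[hi + 1] - ref_cumsum[lo]) / (hi - lo + 1)
    df = pd.DataFrame(out, index=values.index, columns=values.columns)
    return SignalMatrix(df, normalization="quantile", pseudo_count=pseudo_count)


def accessibility_ratio(day_signal, mef_signal, epsilon: float = 0.1) -> np.ndarray:
    """Per-locus (day + eps) / (MEF + eps) signal ratio on fpkpm values."""
    day = np.asarray(day_signal, dtype=float)
    mef = np.asarray(mef_signal, dtype=float)
    if np.any(day < 0) or np.any(mef < 0):
        raise ValueError("signals must be non-negative")
    return (day + epsilon) / (mef + epsilon)


def heatmap_matrix(
    loci: Sequence,
    fragments: FragmentSet,
    window: int = 2000,
    n_bins: int = 100,
) -> np.ndarray:
    """Per-locus binned fpkpm profile over a window centered at rep_pos.

    Each row covers ``[rep_pos - window/2, rep_pos + window/2)`` split into
    ``n_bins`` equal bins; a fragment contributes to every bin it overlaps.
    Bins falling before the chromosome start stay zero.  Values are fpkpm
    with the bin as the region.
    """
    if window % n_bins != 0:
        raise ValueError("window must be divisible by n_bins")
    bin_size = window // n_bins
    frag_by_chrom: dict[str, list[GenomicInterval]] = {}
    for f in fragments.fragments:
        frag_by_chrom.setdefault(f.chrom, []).append(f)
    trees = {
        chrom: _tree_from(frs) for chrom, frs in frag_by_chrom.items()
    }
    out = np.zeros((len(loci), n_bins))
    for i, locus in enumerate(loci):
        chrom, start, end = _locus_bounds(locus)
        rep = locus.rep_pos if isinstance(locus, MergedLocus) else (start + end) // 2
        w_start = rep - window // 2
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.overlap(max(w_start, 0), rep + window // 2):
            b_lo = max((hit.begin - w_start) // bin_size, 0)
            b_hi = min((hit.end - 1 - w_start) // bin_size, n_bins - 1)
            for b in range(b_lo, b_hi + 1):
                if w_start + b * bin_size >= 0:
                    out[i, b] += 1
    return out / (bin_size / 1e3) / (fragments.library_size / 1e6)


def _tree_from(frags: Sequence[GenomicInterval]) -> IntervalTree:
    t = IntervalTree()
    # unique payload per fragment: identical coordinates must not collapse
    for i, f in enumerate(frags):
        t.addi(f.start, f.end, i)
    return t


@dataclass
class DeviationResult:
    """Accessibility deviation of one motif set in one sample."""

    motif_set: str
    sample: str
    observed: float
    expected: float
    raw_deviation: float
    z: float | None
    n_background: int = 0


def motif_deviation(
    counts: "pd.DataFrame | SignalMatrix",
    motif_sets: Mapping[str, Sequence],
    n_background: int = 50,
    n_bins: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """chromVAR-style accessibility deviations per (motif set, sample).

    ``counts`` is a raw peaks x samples count frame; ``motif_sets`` maps a
    set label to peak row labels (or a boolean mask over rows).  Expected
    counts assume every peak draws reads proportionally to its total across
    samples; backgrounds are peak sets of matched size resampled from
    accessibility quantile bins, so z-scores correct for the set's overall
    accessibility level.  Returns a tidy frame with one row per
    (motif_set, sample); z is NaN (with a warning) if the background spread
    vanishes.
    """
    if isinstance(counts, SignalMatrix):
        counts = counts.values
    if n_background < 50:
        raise ValueError("need >= 50 background sets for a stable z")
    x = counts.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    peak_tot = x.sum(axis=1)
    samp_tot = x.sum(axis=0)
    grand = x.sum()
    frac = samp_tot / grand

    # accessibility-matched background pools: quantile bins of peak totals
    n_eff_bins = min(n_bins, max(1, len(np.unique(peak_tot))))
    bins = pd.qcut(peak_tot, q=n_eff_bins, labels=False, duplicates="drop")
    pools = {b: np.nonzero(bins == b)[0] for b in np.unique(bins)}

    rows = []
    index = counts.index
    for label, members in motif_sets.items():
        idx = _resolve_members(members, index)
        if len(idx) == 0:
            raise ValueError(f"motif set {label!r} is empty")
        raw = _raw_deviation(x, idx, peak_tot, frac)
        bg = np.empty((n_background, x.shape[1]))
        member_bins = bins[idx]
        for b_i in range(n_background):
            sampled = np.concatenate([
                rng.choice(pools[b], size=np.sum(member_bins == b), replace=True)
                for b in np.unique(member_bins)
            ])
            bg[b_i] = _raw_deviation(x, sampled, peak_tot, frac)
        mean_bg = bg.mean(axis=0)
        sd_bg = bg.std(axis=0, ddof=1)
        for s_i, sample in enumerate(counts.columns):
            if sd_bg[s_i] > 0:
                z = (raw[s_i] - mean_bg[s_i]) / sd_bg[s_i]
            else:
                warnings.warn(
                    f"zero background spread for set {label!r} sample {sample!r}; "
                    "z undefined"
                )
                z = np.nan
            exp = peak_tot[idx].sum() * frac[s_i]
            rows.append({
                "motif_set": label, "sample": sample,
                "observed": x[idx, s_i].sum(), "expected": exp,
                "raw_deviation": raw[s_i], "z": z,
                "n_background": n_background,
            })
    return pd.DataFrame(rows)


def _resolve_members(members, index) -> np.ndarray:
    arr = np.asarray(members)
    if arr.dtype == bool:
        if len(arr) != len(index):
            raise ValueError("boolean mask length mismatch")
        return np.nonzero(arr)[0]
    return index.get_indexer(pd.Index(arr))


def _raw_deviation(x, idx, peak_tot, frac) -> np.ndarray:
    observed = x[idx].sum(axis=0)
    expected = peak_tot[idx].sum() * frac
    return (observed - expected) / expected
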