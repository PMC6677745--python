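"""Co-binding classification and opening-attribution statistics.

Close-to-open (CO) loci are grouped by which of two factors binds them
(e.g. Sox2-only, Oct4-only, shared, neither), and the groups' day/MEF
accessibility ratios are compared with unpaired Wilcoxon rank-sum tests,
Holm-adjusted across the pairwise family — the standard way to ask which
factor the chromatin opening should be attributed to.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, overlaps_any

__all__ = [
    "classify_cobinding",
    "rank_sum_test",
    "holm_adjust",
    "opening_attribution",
    "AttributionReport",
]

EXACT_MAX_N = 12


def classify_cobinding(
    universe: Sequence[GenomicInterval],
    peaks_a: Sequence[GenomicInterval],
    peaks_b: Sequence[GenomicInterval],
    label_a: str = "A",
    label_b: str = "B",
) -> list[str]:
    """Label each universe locus by >= 1 bp overlap with two peak sets.

    Returns ``"{label_a}_only"``, ``"{label_b}_only"``, ``"shared"`` or
    ``"neither"`` per locus — mutually exclusive and exhaustive.
    """
    in_a = overlaps_any(universe, peaks_a)
    in_b = overlaps_any(universe, peaks_b)
    out = []
    for a, b in zip(in_a, in_b):
        if a and b:
            out.append("shared")
        elif a:
            out.append(f"{label_a}_only")
        elif b:
            out.append(f"{label_b}_only")
        else:
            out.append("neither")
    return out


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null enumeration when the pooled sample is small (n <= 12) and
    tie-free; otherwise the normal approximation with midranks and
    continuity correction.  Returns (U statistic of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class AttributionReport:
    """Per-class ratio summaries and Holm-adjusted pairwise comparisons."""

    per_class: pd.DataFrame  # class, n, median, q1, q3
    pairwise: pd.DataFrame   # class_a, class_b, statistic, p_raw, p_holm

    def to_json(self) -> str:
        return json.dumps({
            "per_class": self.per_class.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
        }, indent=2)

    def write(self, per_class_path, pairwise_path) -> None:
        self.per_class.to_csv(per_class_path, sep="\t", index=False)
        self.pairwise.to_csv(pairwise_path, sep="\t", index=False)


def opening_attribution(
    classes: Sequence[str],
    ratios: Sequence[float],
    min_n: int = 3,
    exclude: Sequence[str] = ("neither",),
) -> AttributionReport:
    """Compare accessibility ratios across co-binding classes.

    ``classes`` and ``ratios`` align per locus.  Classes with fewer than
    ``min_n`` loci are excluded from testing (with a warning); all pairwise
    rank-sum tests among the remaining classes are Holm-adjusted as one
    family.  Classes in ``exclude`` (default the unbound background) are
    summarized but not tested.
    """
    df = pd.DataFrame({"cls": list(classes), "ratio": np.asarray(ratios, dtype=float)})
    summary = (
        df.groupby("cls")["ratio"]
        .agg(n="size", median="median",
             q1=lambda v: v.quantile(0.25), q3=lambda v: v.quantile(0.75))
        .reset_index()
        .rename(columns={"cls": "class"})
    )
    eligible = []
    for cls, grp in df.groupby("cls"):
        if cls in exclude:
            continue
        if len(grp) < min_n:
            warnings.warn(f"class {cls!r} has n={len(grp)} < {min_n}; excluded from testing")
            continue
        eligible.append(cls)
    if len(eligible) < 2:
        raise ValueError("need >= 2 classes with enough loci to compare")
    rows = []
    for a, b in combinations(sorted(eligible), 2):
        stat, p = rank_sum_test(
            df.loc[df["cls"] == a, "ratio"], df.loc[df["cls"] == b, "ratio"]
        )
        rows.append({"class_a": a, "class_b": b, "statistic": stat, "p_raw": p})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_adjust(pairwise["p_raw"].to_numpy())
    return AttributionReport(per_class=summary, pairwise=pairwise)
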