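"""File-level orchestration of the three named analyses.

Each ``run_*`` function reads standard-format inputs (BED/narrowPeak
summits and peaks, BED fragments, FASTA genome), executes one analysis
stage and writes tab-separated outputs plus a JSON manifest into a run
directory.  The command-line entry points in :mod:`chromtraj.cli` are thin
wrappers over these functions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from . import __version__
from .attribution import classify_cobinding, opening_attribution
from .intervals import Summit, read_intervals, write_intervals
from .motifs import annotate_loci, default_pwms, motif_fractions
from .signal import FragmentSet, accessibility_ratio, count_coverage, normalize_fpkpm
from .starr import StarrCallSet, call_consensus_enhancers, overlap_fraction
from .trajectories import (
    TierThresholds,
    accessibility_tier,
    assign_occupancy_codes,
    chromatin_trajectory,
    write_trajectory_beds,
)

__all__ = ["run_trajectories", "run_opening", "run_starr", "write_manifest"]


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(outdir: Path, command: str, params: dict, inputs: Mapping[str, str]) -> None:
    manifest = {
        "tool": "chromtraj",
        "version": __version__,
        "command": command,
        "parameters": params,
        "input_checksums": {k: _checksum(v) for k, v in inputs.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _read_summits(path, source: str) -> list[Summit]:
    out = []
    for iv in read_intervals(path, format="bed"):
        pos = iv.summit if iv.summit is not None else iv.center
        out.append(Summit(iv.chrom, pos, source))
    return out


def run_trajectories(
    condition_files: Sequence[tuple[str, str]],
    outdir,
    genome_fasta: str | None = None,
    max_dist: int = 100,
    scan_window: int = 200,
) -> pd.DataFrame:
    """Binary occupancy codes over ordered conditions, plus motif fractions.

    ``condition_files`` is an ordered list of (label, summit BED path).
    Writes per-code BEDs, a code summary and — when a genome is given —
    per-code motif-class fractions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    conditions = [(label, _read_summits(path, label)) for label, path in condition_files]
    trajectories = assign_occupancy_codes(conditions, max_dist=max_dist)
    summary = write_trajectory_beds(trajectories, outdir)
    if genome_fasta is not None:
        genome = Fasta(genome_fasta)
        pwms = default_pwms()
        annotations = annotate_loci(
            [t.locus for t in trajectories], genome, pwms, window=scan_window
        )
        fractions = motif_fractions(annotations, [t.code for t in trajectories])
        fractions.to_csv(outdir / "motif_fractions.tsv", sep="\t", index=False)
    write_manifest(
        outdir, "trajectories",
        {"max_dist": max_dist, "scan_window": scan_window,
         "conditions": [lab for lab, _ in condition_files]},
        {lab: path for lab, path in condition_files},
    )
    return summary


def run_opening(
    mef_peaks_path,
    day_peaks_path,
    mef_fragments_path,
    day_fragments_path,
    factor_a_peaks_path,
    factor_b_peaks_path,
    outdir,
    label_a: str = "Sox2",
    label_b: str = "Oct4",
    epsilon: float = 0.1,
    tier_thresholds: TierThresholds | None = None,
) -> dict:
    """PO/OC/CO classification, tiers, and co-binding opening attribution.

    CO loci (closed in MEFs, open at the day condition) are classed by
    overlap with two factors' peaks and their day/MEF fpkpm ratios compared
    pairwise (rank-sum, Holm).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mef_peaks = read_intervals(mef_peaks_path)
    day_peaks = read_intervals(day_peaks_path)
    labelled = chromatin_trajectory(mef_peaks, day_peaks)
    traj_df = pd.DataFrame(
        [{"chrom": l.chrom, "start": l.start, "end": l.end, "label": lab}
         for l, lab in labelled]
    )
    traj_df.to_csv(outdir / "chromatin_trajectories.tsv", sep="\t", index=False)

    universe = [l for l, _ in labelled]
    mef_frags = FragmentSet("MEF", read_intervals(mef_fragments_path))
    day_frags = FragmentSet("day", read_intervals(day_fragments_path))
    mef_counts = count_coverage(universe, mef_frags)
    day_counts = count_coverage(universe, day_frags)
    lengths = [iv.width for iv in universe]
    mef_sig = normalize_fpkpm(mef_counts, lengths, mef_frags.library_size)
    day_sig = normalize_fpkpm(day_counts, lengths, day_frags.library_size)
    ratios = accessibility_ratio(day_sig, mef_sig, epsilon=epsilon)
    tiers = [accessibility_tier(c, tier_thresholds) for c in mef_counts]
    tier_df = pd.DataFrame({
        "chrom": [iv.chrom for iv in universe],
        "start": [iv.start for iv in universe],
        "end": [iv.end for iv in universe],
        "mef_count": mef_counts, "tier": tiers, "ratio": ratios,
        "trajectory": [lab for _, lab in labelled],
    })
    tier_df.to_csv(outdir / "accessibility_tiers.tsv", sep="\t", index=False)

    co_mask = [lab == "CO" for _, lab in labelled]
    co_loci = [l for l, keep in zip(universe, co_mask) if keep]
    if not co_loci:
        raise ValueError("no close-to-open loci: nothing to attribute")
    classes = classify_cobinding(
        co_loci,
        read_intervals(factor_a_peaks_path),
        read_intervals(factor_b_peaks_path),
        label_a=label_a, label_b=label_b,
    )
    co_ratios = ratios[co_mask]
    report = opening_attribution(classes, co_ratios)
    report.write(outdir / "attribution_per_class.tsv", outdir / "attribution_pairwise.tsv")
    write_manifest(
        outdir, "opening",
        {"epsilon": epsilon, "label_a": label_a, "label_b": label_b},
        {"mef_peaks": mef_peaks_path, "day_peaks": day_peaks_path,
         "mef_fragments": mef_fragments_path, "day_fragments": day_fragments_path,
         "factor_a": factor_a_peaks_path, "factor_b": factor_b_peaks_path},
    )
    return {"trajectories": traj_df, "tiers": tier_df, "report": report}


def run_starr(
    replicate_paths: Sequence[str],
    merged_path,
    outdir,
    min_replicates: int = 2,
    reference_path: str | None = None,
) -> dict:
    """Consensus enhancer calling plus optional overlap-fraction report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(replicate_paths) < 2:
        raise ValueError("consensus calling needs >= 2 replicate peak files")
    calls = StarrCallSet(
        [read_intervals(p) for p in replicate_paths],
        read_intervals(merged_path),
        min_replicates=min_replicates,
    )
    consensus = call_consensus_enhancers(calls)
    write_intervals(consensus, outdir / "consensus_enhancers.bed")
    result = {"n_consensus": len(consensus), "n_merged": len(calls.merged_peaks)}
    if reference_path is not None:
        reference = read_intervals(reference_path)
        result["reference_recall"] = overlap_fraction(reference, consensus)
        result["consensus_precision"] = (
            overlap_fraction(consensus, reference) if consensus else 0.0
        )
    with open(outdir / "starr_summary.json", "w") as fh:
        json.dump(result, fh, indent=2)
    inputs = {f"rep{i + 1}": p for i, p in enumerate(replicate_paths)}
    inputs["merged"] = merged_path
    write_manifest(outdir, "starr", {"min_replicates": min_replicates}, inputs)
    return result
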