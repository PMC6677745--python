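"""PWM motif scanning and per-locus motif-class annotation.

POU-family binding sites come in distinct architectural classes: the
monomeric octamer (ATGCAAAT), the composite SoxOct element bound by a
Sox2/POU heterodimer, the palindromic MORE (ATGCATATGCAT) bound by POU
homodimers, and a MORE variant with a 1-bp spacer.  Loci are annotated for
each class by log-odds PWM scanning of a fixed window around the locus
center; perfectly palindromic matrices are scanned on the plus strand only
so a single physical site is never counted twice.

Scores are log2 odds against a uniform 0.25 background with a small
pseudo-probability floor; ``N`` bases contribute 0 (neutral), so runs of N
can never create matches.  Each PWM carries an absolute score threshold,
by default 85% of its maximum attainable score — a stringency knob whose
empirical false-positive rate on random sequence is checked in the test
suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, MergedLocus

__all__ = [
    "Pwm",
    "Match",
    "CONSENSUS",
    "pwm_from_consensus",
    "default_pwms",
    "is_palindromic",
    "reverse_complement",
    "scan_sequence",
    "annotate_loci",
    "motif_fractions",
    "read_meme_motifs",
    "read_matrix_pwm",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default consensus strings per motif class.  Octamer, PORE and MORE are the
#: canonical published sequences; SoxOct and MORE+1 are configurable
#: placeholder consensus (the exact database PWMs vary by motif-db version).
CONSENSUS: dict[str, str] = {
    "octamer": "ATGCAAAT",
    "SoxOct": "CATTGTTATGCAAAT",
    "MORE": "ATGCATATGCAT",
    "MORE_plus1": "ATGCATNATGCAT",
    "Sox_single": "CATTGTT",
    "PORE": "ATTTGAAATGCAAAT",
}

PSEUDO_FLOOR = 1e-3


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """Position weight matrix with an absolute log-odds match threshold.

    ``matrix`` is width x 4 (A, C, G, T) of per-position probabilities; each
    column (position) sums to 1.  ``palindromic`` matrices are scanned on the
    plus strand only.
    """

    name: str
    matrix: np.ndarray
    score_threshold: float
    palindromic: bool = False
    _logodds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be width x 4 (A,C,G,T)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        floored = np.maximum(self.matrix, PSEUDO_FLOOR)
        lo = np.log2(floored / 0.25)
        # 5th column scores N as 0 (neutral)
        self._logodds = np.column_stack([lo, np.zeros(self.width)])
        if self.score_threshold > self.max_score + 1e-9:
            raise ValueError("threshold exceeds the maximum attainable score")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(np.log2(np.maximum(self.matrix, PSEUDO_FLOOR) / 0.25).max(axis=1).sum())

    def reverse_complemented(self) -> "Pwm":
        rc = self.matrix[::-1, ::-1]
        return Pwm(self.name, rc, self.score_threshold, self.palindromic)


@dataclass(frozen=True)
class Match:
    offset: int
    strand: str
    score: float


def pwm_from_consensus(
    consensus: str,
    match_prob: float = 0.85,
    name: str | None = None,
    threshold_frac: float = 0.85,
) -> Pwm:
    """Build a PWM from an IUPAC {A,C,G,T,N} consensus string.

    The consensus base receives ``match_prob``; the other three share the
    remainder equally; ``N`` positions are uniform.  The match threshold is
    ``threshold_frac`` of the maximum attainable score.  Palindromicity is
    auto-detected from the consensus.
    """
    consensus = consensus.upper()
    if not 0.25 < match_prob < 1:
        raise ValueError("match_prob must be in (0.25, 1): 0.25 is uninformative")
    cols = []
    for ch in consensus:
        if ch == "N":
            cols.append([0.25] * 4)
        elif ch in _BASE_INDEX:
            col = [(1 - match_prob) / 3] * 4
            col[_BASE_INDEX[ch]] = match_prob
            cols.append(col)
        else:
            raise ValueError(f"invalid consensus character: {ch!r}")
    matrix = np.array(cols)
    pwm = Pwm(name or consensus, matrix, score_threshold=-math.inf,
              palindromic=is_palindromic(consensus))
    pwm.score_threshold = threshold_frac * pwm.max_score
    return pwm


def default_pwms(
    classes: Sequence[str] = ("octamer", "SoxOct", "MORE", "MORE_plus1", "Sox_single"),
    match_prob: float = 0.85,
    threshold_frac: float = 0.85,
) -> list[Pwm]:
    """The default consensus-derived PWM panel for POU/Sox motif classes."""
    return [
        pwm_from_consensus(CONSENSUS[c], match_prob, name=c, threshold_frac=threshold_frac)
        for c in classes
    ]


def is_palindromic(motif: "str | Pwm") -> bool:
    """True iff the motif equals its own reverse complement.

    Odd-width motifs over unambiguous DNA can never be perfect
    reverse-complement palindromes unless the center base is N.
    """
    if isinstance(motif, Pwm):
        return bool(np.allclose(motif.matrix, motif.matrix[::-1, ::-1], atol=1e-9))
    s = motif.upper()
    return reverse_complement(s) == s


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T,N -> 0..4; any other character is treated as N."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(enc: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    w = logodds.shape[0]
    n = len(enc) - w + 1
    scores = np.zeros(n)
    for j in range(w):
        scores += logodds[j, enc[j : j + n]]
    return scores


def scan_sequence(seq: str, pwm: Pwm) -> list[Match]:
    """All threshold-passing PWM matches in a sequence, sorted by offset.

    Non-palindromic PWMs are scanned on both strands (the minus strand by
    scoring the reverse-complemented matrix against the forward sequence);
    palindromic PWMs on the plus strand only, so each palindromic site
    counts once.  Sequences shorter than the PWM yield no matches.
    """
    if len(seq) < pwm.width:
        return []
    enc = encode_sequence(seq)
    matches = []
    fwd = _window_scores(enc, pwm._logodds)
    for off in np.nonzero(fwd >= pwm.score_threshold)[0]:
        matches.append(Match(int(off), "+", float(fwd[off])))
    if not pwm.palindromic:
        rev = _window_scores(enc, pwm.reverse_complemented()._logodds)
        for off in np.nonzero(rev >= pwm.score_threshold)[0]:
            matches.append(Match(int(off), "-", float(rev[off])))
    matches.sort(key=lambda m: (m.offset, m.strand))
    return matches


def _fetch_window(genome, chrom: str, center: int, window: int) -> str:
    start = max(0, center - window // 2)
    end = center + window // 2
    if isinstance(genome, Mapping):
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} missing from genome")
        return str(genome[chrom][start:end]).upper()
    # pyfaidx.Fasta or anything with the same slicing interface
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} missing from genome")
    return str(genome[chrom][start:end]).upper()


def annotate_loci(
    loci: Sequence["MergedLocus | GenomicInterval"],
    genome,
    pwms: Sequence[Pwm],
    window: int = 200,
) -> pd.DataFrame:
    """Per-locus motif-class presence over centered scan windows.

    ``genome`` is a ``pyfaidx.Fasta`` (or any chrom->sequence mapping).  The
    scan window is ``window`` bp centered on the locus representative
    position (clipped at the chromosome start).  The returned frame has one
    boolean column per PWM plus derived ``any`` (>= 1 class), ``none`` and
    ``all`` (every class) categories.
    """
    names = [p.name for p in pwms]
    if len(set(names)) != len(names):
        raise ValueError("PWM names must be unique")
    rows = []
    for locus in loci:
        chrom = locus.chrom
        center = locus.rep_pos if isinstance(locus, MergedLocus) else locus.center
        seq = _fetch_window(genome, chrom, center, window)
        rows.append({p.name: bool(scan_sequence(seq, p)) for p in pwms})
    df = pd.DataFrame(rows, columns=names)
    df["any"] = df[names].any(axis=1)
    df["none"] = ~df["any"]
    df["all"] = df[names].all(axis=1)
    return df


def both_present(annotations: pd.DataFrame, x: str, y: str) -> pd.Series:
    """Loci where motif classes x and y are concurrently present."""
    return annotations[x] & annotations[y]


def motif_fractions(
    annotations: pd.DataFrame,
    codes: Sequence[str],
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fraction of loci per trajectory code carrying each motif class.

    ``codes`` aligns with the annotation rows.  Empty groups are omitted
    with a warning.  For every group, fraction(any) + fraction(none) = 1.
    """
    if columns is None:
        columns = [c for c in annotations.columns]
    df = annotations[list(columns)].copy()
    df["code"] = list(codes)
    rows = []
    for code, grp in df.groupby("code", sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby never yields empties
            warnings.warn(f"empty trajectory group {code!r}: fraction undefined")
            continue
        for col in columns:
            rows.append({
                "code": code, "class": col,
                "fraction": float(grp[col].mean()), "n": len(grp),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PWM file formats
# ---------------------------------------------------------------------------


def read_meme_motifs(path, threshold_frac: float = 0.85) -> list[Pwm]:
    """Read PWMs from MEME minimal format (letter-probability matrices)."""
    pwms: list[Pwm] = []
    name = None
    rows: list[list[float]] = []
    expecting = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                parts = line.split()
                name = parts[1] if len(parts) > 1 else f"motif_{len(pwms) + 1}"
            elif line.startswith("letter-probability matrix"):
                rows = []
                expecting = 1
            elif expecting and line and line[0] in "0123456789.":
                rows.append([float(x) for x in line.split()[:4]])
            elif expecting and rows:
                pwms.append(_finish_meme(name, rows, threshold_frac))
                rows, expecting = [], 0
    if expecting and rows:
        pwms.append(_finish_meme(name, rows, threshold_frac))
    return pwms


def _finish_meme(name, rows, threshold_frac) -> Pwm:
    matrix = np.array(rows)
    matrix = matrix / matrix.sum(axis=1, keepdims=True)
    pwm = Pwm(name or "motif", matrix, -math.inf)
    pwm.palindromic = is_palindromic(pwm)
    pwm.score_threshold = threshold_frac * pwm.max_score
    return pwm


def read_matrix_pwm(path, name: str | None = None, threshold_frac: float = 0.85) -> Pwm:
    """Read a single PWM from a plain tab-separated width x 4 matrix."""
    matrix = np.loadtxt(path)
    if matrix.ndim == 1:
        matrix = matrix.reshape(1, -1)
    if matrix.shape[1] != 4 and matrix.shape[0] == 4:
        matrix = matrix.T
    matrix = matrix / matrix.sum(axis=1, keepdims=True)
    pwm = Pwm(name or str(path), matrix, -math.inf)
    pwm.palindromic = is_palindromic(pwm)
    pwm.score_threshold = threshold_frac * pwm.max_score
    return pwm
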