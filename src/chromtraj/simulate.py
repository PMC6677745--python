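"""Synthetic genome, binding and accessibility generator with ground truth.

The generator emulates the statistical structure of a POU-factor
reprogramming time course so that every downstream analysis can be tested
against a machine-readable truth table:

* a random genome with exact-consensus motif instances planted at recorded,
  well-spaced positions, one of five classes — octamer, SoxOct, MORE,
  MORE+1, single Sox site — plus motif-free decoy loci;
* factor- and day-specific binding that follows the dimerization rules of
  the system: the reprogramming-competent POU factor binds SoxOct elements
  at all time points and recruits Sox2 there as a heterodimer; the
  Sox2-dimerization-defective mutant binds SoxOct early but loses it by the
  later day while retaining residual MORE binding, and it *blocks* Sox2 from
  the composite site; the MORE-preferring paralog homodimerizes on MORE and
  largely avoids SoxOct, leaving the Sox half-site available to Sox2 alone;
* accessibility from a logistic opening model in which Sox2 binding is the
  dominant term and POU binding an augmenting one,
  ``P(open) = logistic(b0 + bS*Sox2 + bO*POU + bOS*both)``,
  with negative-binomial (overdispersed) fragment-count emission — open
  loci draw high counts, closed loci low, so the low/medium/high tier
  thresholds partition loci non-trivially;
* STARR-seq replicate/merged peak calls over a true-enhancer set with a
  stated per-replicate sensitivity and false-positive rate.

Everything is driven by one config object and one seed; identical inputs
produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval, Summit, write_intervals
from .motifs import CONSENSUS, reverse_complement
from .signal import FragmentSet

__all__ = [
    "FactorRules",
    "OpeningModelParams",
    "ScenarioConfig",
    "Scenario",
    "generate_genome",
    "simulate_binding",
    "simulate_accessibility",
    "simulate_starr",
    "simulate_scenario",
    "write_fasta",
    "default_factor_rules",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FactorRules:
    """Per-(factor, day, motif class) binding probabilities and Sox2 rules.

    ``pou_probs[(factor, day, cls)]`` is the probability that the POU factor
    binds a locus of that class on that day.  Sox2 behaviour at SoxOct
    elements depends on the POU partner: it co-binds with probability
    ``sox2_cobind`` when a heterodimerization-competent partner is bound,
    is blocked down to ``sox2_blocked`` when an incompetent partner occupies
    the site, and binds the Sox half-site alone with ``sox2_solo_soxoct``
    when the POU factor is absent.  At single Sox sites it binds with
    ``sox2_single`` regardless of partner; elsewhere ``sox2_background``.
    """

    pou_probs: dict[tuple[str, str, str], float]
    heterodimer_competent: dict[str, bool]
    sox2_cobind: float = 0.9
    sox2_blocked: float = 0.05
    sox2_solo_soxoct: float = 0.6
    sox2_single: float = 0.8
    sox2_background: float = 0.05

    def pou_prob(self, factor: str, day: str, cls: str) -> float:
        try:
            p = self.pou_probs[(factor, day, cls)]
        except KeyError:
            raise KeyError(
                f"no binding rule for factor={factor!r} day={day!r} class={cls!r}"
            ) from None
        if not 0 <= p <= 1:
            raise ValueError(f"binding probability out of [0,1]: {p}")
        return p


@dataclass
class OpeningModelParams:
    """Logistic chromatin-opening model and count-emission parameters.

    ``beta0`` is the baseline log-odds of a locus being open; ``betaS`` /
    ``betaO`` the Sox2 / POU binding effects; ``betaOS`` the extra
    co-binding (heterodimer) effect.  Closed loci emit negative-binomial
    fragment counts with mean ``closed_mean``; open loci with mean
    ``open_mean`` scaled by the locus's opening propensity relative to the
    fully co-bound configuration, so accessibility is graded the way ATAC
    signal is: a co-bound open locus reaches the full ``open_mean`` while a
    singly bound or baseline-open locus sits lower.  ``graded_amplitude``
    in [0, 1] sets how much of the open mean is propensity-scaled (0
    recovers a flat two-state emission).  ``dispersion`` is the NB alpha
    (variance = mu + alpha * mu^2).
    """

    beta0: float = -2.0
    betaS: float = 2.0
    betaO: float = 0.5
    betaOS: float = 1.0
    open_mean: float = 40.0
    closed_mean: float = 5.0
    dispersion: float = 0.3
    graded_amplitude: float = 0.9

    def __post_init__(self) -> None:
        if not (self.open_mean > self.closed_mean > 0):
            raise ValueError("need open_mean > closed_mean > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    def p_open(self, sox2_bound, pou_bound) -> np.ndarray:
        s = np.asarray(sox2_bound, dtype=float)
        o = np.asarray(pou_bound, dtype=float)
        logit = self.beta0 + self.betaS * s + self.betaO * o + self.betaOS * s * o
        return 1.0 / (1.0 + np.exp(-logit))

    def p_open_max(self) -> float:
        """Largest opening probability over the four binding configurations."""
        combos = [(0, 0), (0, 1), (1, 0), (1, 1)]
        return float(max(self.p_open(s, o) for s, o in combos))

    def open_emission_mean(self, p_open) -> np.ndarray:
        """NB mean of an *open* locus, graded by its opening propensity."""
        rel = np.asarray(p_open, dtype=float) / self.p_open_max()
        return self.open_mean * ((1.0 - self.graded_amplitude)
                                 + self.graded_amplitude * rel)


def default_factor_rules(
    factors: Sequence[str] = ("Oct4", "Oct4defSox2", "Oct6"),
    days: Sequence[str] = ("day1", "day5"),
) -> FactorRules:
    """The default reprogramming scenario's dimerization-driven rules."""
    base = {
        "Oct4": {
            "SoxOct": {"day1": 0.85, "day5": 0.90},
            "MORE": {"day1": 0.20, "day5": 0.20},
            "MORE_plus1": {"day1": 0.20, "day5": 0.20},
            "octamer": {"day1": 0.50, "day5": 0.50},
            "Sox_single": {"day1": 0.05, "day5": 0.05},
            "none": {"day1": 0.10, "day5": 0.05},
        },
        "Oct4defSox2": {
            "SoxOct": {"day1": 0.85, "day5": 0.02},
            "MORE": {"day1": 0.40, "day5": 0.40},
            "MORE_plus1": {"day1": 0.35, "day5": 0.35},
            "octamer": {"day1": 0.50, "day5": 0.40},
            "Sox_single": {"day1": 0.05, "day5": 0.05},
            "none": {"day1": 0.10, "day5": 0.05},
        },
        "Oct6": {
            "SoxOct": {"day1": 0.10, "day5": 0.10},
            "MORE": {"day1": 0.90, "day5": 0.90},
            "MORE_plus1": {"day1": 0.80, "day5": 0.80},
            "octamer": {"day1": 0.50, "day5": 0.50},
            "Sox_single": {"day1": 0.05, "day5": 0.05},
            "none": {"day1": 0.10, "day5": 0.05},
        },
    }
    probs = {
        (f, d, cls): base[f][cls][d]
        for f in factors for d in days for cls in base[f]
    }
    competent = {"Oct4": True, "Oct4defSox2": False, "Oct6": False}
    return FactorRules(probs, {f: competent[f] for f in factors})


@dataclass
class ScenarioConfig:
    """One-stop configuration for the default synthetic scenario."""

    chrom_name: str = "chr1"
    chrom_length: int = 2_000_000
    motif_counts: dict[str, int] = field(default_factory=lambda: {
        "SoxOct": 800, "MORE": 600, "octamer": 400,
        "MORE_plus1": 200, "Sox_single": 500, "none": 500,
    })
    min_spacing: int = 200
    factors: tuple[str, ...] = ("Oct4", "Oct4defSox2", "Oct6")
    days: tuple[str, ...] = ("day1", "day5")
    summit_jitter: int = 20
    opening: OpeningModelParams = field(default_factory=OpeningModelParams)
    locus_window: int = 400
    fragment_length: int = 100
    peak_min_count: int = 8
    starr_sensitivity: float = 0.8
    starr_fp_rate: float = 0.05
    starr_replicates: int = 3

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["factors"], d["days"] = list(self.factors), list(self.days)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "opening" in d and isinstance(d["opening"], dict):
            d["opening"] = OpeningModelParams(**d["opening"])
        for key in ("factors", "days"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Genome with planted motifs
# ---------------------------------------------------------------------------


def generate_genome(
    config: ScenarioConfig, seed: int
) -> tuple[str, pd.DataFrame]:
    """Random genome with exact-consensus motif instances planted.

    Background bases are i.i.d. uniform ACGT.  Instances are placed in
    disjoint slots so any two are >= ``min_spacing`` bp apart (one motif per
    scan window); non-palindromic motifs land on a random strand (the
    reverse complement is inserted for minus-strand instances); ``N``
    positions in a consensus get a random concrete base.  Class ``none``
    plants nothing but records a motif-free decoy locus.

    Returns the sequence and a truth table (locus_id, chrom, start, end,
    class, strand, center) sorted by position.
    """
    rng = np.random.default_rng(seed)
    length = config.chrom_length
    seq = rng.integers(0, 4, size=length, dtype=np.int8)

    items: list[str] = []
    for cls, count in config.motif_counts.items():
        if cls != "none" and cls not in CONSENSUS:
            raise ValueError(f"unknown motif class: {cls!r}")
        items.extend([cls] * count)
    max_width = max(
        (len(CONSENSUS[c]) for c in config.motif_counts if c != "none"), default=1
    )
    slot = config.min_spacing + max_width
    n_slots = length // slot
    if len(items) > n_slots:
        raise ValueError(
            f"cannot pack {len(items)} loci with spacing {config.min_spacing} "
            f"into {length} bp"
        )
    order = rng.permutation(len(items))
    slots = np.sort(rng.choice(n_slots, size=len(items), replace=False))

    rows = []
    for rank, slot_idx in enumerate(slots):
        cls = items[order[rank]]
        if cls == "none":
            width = 1
            start = slot_idx * slot + rng.integers(0, max_width)
            strand = "+"
        else:
            consensus = CONSENSUS[cls]
            width = len(consensus)
            start = slot_idx * slot + int(rng.integers(0, max_width - width + 1))
            strand = "+"
            planted = consensus
            if reverse_complement(consensus) != consensus and rng.random() < 0.5:
                strand = "-"
                planted = reverse_complement(consensus)
            enc = np.array(
                [
                    "ACGT".index(ch) if ch != "N" else int(rng.integers(0, 4))
                    for ch in planted
                ],
                dtype=np.int8,
            )
            seq[start : start + width] = enc
        rows.append({
            "chrom": config.chrom_name, "start": int(start),
            "end": int(start + width), "class": cls, "strand": strand,
        })
    truth = pd.DataFrame(rows).sort_values("start").reset_index(drop=True)
    truth.insert(0, "locus_id", [f"L{i:05d}" for i in range(len(truth))])
    truth["center"] = (truth["start"] + truth["end"]) // 2
    sequence = bytes(_BASES[seq]).decode("ascii")
    return sequence, truth


def write_fasta(sequence: str, path, chrom_name: str = "chr1", width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom_name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Binding
# ---------------------------------------------------------------------------


def simulate_binding(
    truth: pd.DataFrame,
    rules: FactorRules,
    factors: Sequence[str],
    days: Sequence[str],
    seed: int,
    jitter: int = 20,
) -> tuple[pd.DataFrame, dict[tuple[str, str], list[Summit]], dict[tuple[str, str], list[Summit]]]:
    """Per-condition POU and Sox2 binding states and summits.

    Each locus binds independently with the (factor, day, class) rule
    probability; Sox2 follows the dimerization logic in ``FactorRules``.
    Bound loci emit a summit at the motif center plus uniform +/- ``jitter``
    bp.  Returns (binding table with boolean columns
    ``pou_{factor}_{day}`` / ``sox2_{factor}_{day}``, POU summit dict,
    Sox2 summit dict keyed by (factor, day)).
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    classes = truth["class"].to_numpy()
    centers = truth["center"].to_numpy()
    chroms = truth["chrom"].to_numpy()
    binding = pd.DataFrame(index=truth["locus_id"])
    pou_summits: dict[tuple[str, str], list[Summit]] = {}
    sox2_summits: dict[tuple[str, str], list[Summit]] = {}
    for factor in factors:
        competent = rules.heterodimer_competent[factor]
        for day in days:
            p = np.array([rules.pou_prob(factor, day, c) for c in classes])
            pou = rng.random(n) < p
            p_sox = np.full(n, rules.sox2_background)
            is_soxoct = classes == "SoxOct"
            p_sox[is_soxoct & pou] = (
                rules.sox2_cobind if competent else rules.sox2_blocked
            )
            p_sox[is_soxoct & ~pou] = rules.sox2_solo_soxoct
            p_sox[classes == "Sox_single"] = rules.sox2_single
            sox = rng.random(n) < p_sox
            binding[f"pou_{factor}_{day}"] = pou.astype(bool)
            binding[f"sox2_{factor}_{day}"] = sox.astype(bool)
            pou_summits[(factor, day)] = _emit_summits(
                chroms, centers, pou, f"{factor}_{day}", rng, jitter
            )
            sox2_summits[(factor, day)] = _emit_summits(
                chroms, centers, sox, f"Sox2_{factor}_{day}", rng, jitter
            )
    return binding, pou_summits, sox2_summits


def _emit_summits(chroms, centers, bound, source, rng, jitter) -> list[Summit]:
    idx = np.nonzero(bound)[0]
    offsets = rng.integers(-jitter, jitter + 1, size=len(idx))
    return [
        Summit(chroms[i], max(0, int(centers[i] + off)), source)
        for i, off in zip(idx, offsets)
    ]


# ---------------------------------------------------------------------------
# Accessibility
# ---------------------------------------------------------------------------


@dataclass
class AccessibilityCondition:
    """One condition's simulated ATAC readout plus its truth."""

    name: str
    open_state: np.ndarray      # bool per locus
    p_open: np.ndarray
    counts: np.ndarray          # emitted fragment count per locus
    fragments: FragmentSet
    peaks: list[GenomicInterval]


def _nb_counts(rng, mean, dispersion: float, size: int) -> np.ndarray:
    r = 1.0 / dispersion
    p = r / (r + np.asarray(mean, dtype=float))
    return rng.negative_binomial(r, p, size=size)


def simulate_accessibility(
    truth: pd.DataFrame,
    sox2_bound: np.ndarray,
    pou_bound: np.ndarray,
    params: OpeningModelParams,
    seed: int,
    name: str = "condition",
    locus_window: int = 400,
    fragment_length: int = 100,
    peak_min_count: int = 8,
) -> AccessibilityCondition:
    """Simulate one condition's accessibility from binding states.

    Opens each locus with the logistic model probability, emits NB fragment
    counts (open vs closed mean), and scatters fragments uniformly in the
    ``locus_window`` around the locus center.  Peaks are loci whose emitted
    count exceeds ``peak_min_count``.  A fibroblast/MEF reference is
    obtained by passing all-False binding states (baseline log-odds only).
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    p_open = params.p_open(sox2_bound, pou_bound)
    open_state = rng.random(n) < p_open
    counts = np.where(
        open_state,
        _nb_counts(rng, params.open_emission_mean(p_open), params.dispersion, n),
        _nb_counts(rng, params.closed_mean, params.dispersion, n),
    )
    chroms = truth["chrom"].to_numpy()
    centers = truth["center"].to_numpy()
    frags: list[GenomicInterval] = []
    half = locus_window // 2
    for i in range(n):
        if counts[i] == 0:
            continue
        lo = max(0, centers[i] - half)
        starts = rng.integers(lo, centers[i] + half - fragment_length, size=counts[i])
        frags.extend(
            GenomicInterval(chroms[i], int(s), int(s) + fragment_length)
            for s in starts
        )
    peaks = [
        GenomicInterval(chroms[i], max(0, centers[i] - half), centers[i] + half,
                        name=truth["locus_id"].iloc[i])
        for i in range(n) if counts[i] > peak_min_count
    ]
    return AccessibilityCondition(
        name=name, open_state=open_state, p_open=p_open, counts=counts,
        fragments=FragmentSet(name, frags), peaks=peaks,
    )


def fit_opening_model(
    sox2_bound, pou_bound, open_state
) -> dict[str, float]:
    """Refit the logistic opening model to binary binding/openness truth.

    Maximum-likelihood logistic regression of open_state on Sox2 binding,
    POU binding and their interaction; returns the estimated ``beta0``,
    ``betaS``, ``betaO``, ``betaOS``.
    """
    import statsmodels.api as sm

    s = np.asarray(sox2_bound, dtype=float)
    o = np.asarray(pou_bound, dtype=float)
    y = np.asarray(open_state, dtype=float)
    X = np.column_stack([np.ones_like(s), s, o, s * o])
    fit = sm.Logit(y, X).fit(disp=0)
    b = fit.params
    return {"beta0": float(b[0]), "betaS": float(b[1]),
            "betaO": float(b[2]), "betaOS": float(b[3])}


def opening_recovery_experiment(
    params: OpeningModelParams,
    n_loci: int = 3000,
    n_seeds: int = 100,
    seed: int = 1,
    p_sox: float = 0.5,
    p_pou: float = 0.5,
) -> pd.DataFrame:
    """Repeatedly simulate opening truth and refit the logistic model.

    Binding states are independent Bernoulli draws so all four
    configurations are well represented; each replicate draws open states
    from the model and refits.  Returns one row of coefficient estimates
    per replicate seed.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        s = rng.random(n_loci) < p_sox
        o = rng.random(n_loci) < p_pou
        open_state = rng.random(n_loci) < params.p_open(s, o)
        rows.append(fit_opening_model(s, o, open_state))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# STARR
# ---------------------------------------------------------------------------


def simulate_starr(
    enhancers: Sequence[GenomicInterval],
    chrom_length: int,
    seed: int,
    n_replicates: int = 3,
    sensitivity: float = 0.8,
    fp_rate: float = 0.05,
    chrom_name: str = "chr1",
    peak_width: int = 300,
) -> tuple[list[list[GenomicInterval]], list[GenomicInterval]]:
    """Replicate and pooled STARR-seq peak calls over a true-enhancer set.

    Each true enhancer is called in each replicate with probability
    ``sensitivity`` and in the pooled call with probability
    ``1 - (1 - sensitivity)**n_replicates``; false-positive peaks are
    injected per replicate and in the pooled set at ``fp_rate`` times the
    number of true enhancers, at random positions.
    """
    if not 0 <= sensitivity <= 1:
        raise ValueError("sensitivity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_fp = int(round(fp_rate * len(enhancers)))
    replicate_peaks = []
    for _ in range(n_replicates):
        called = [e for e in enhancers if rng.random() < sensitivity]
        replicate_peaks.append(called + _random_peaks(rng, n_fp, chrom_length, chrom_name, peak_width))
    p_merged = 1.0 - (1.0 - sensitivity) ** n_replicates
    merged = [e for e in enhancers if rng.random() < p_merged]
    merged = merged + _random_peaks(rng, n_fp, chrom_length, chrom_name, peak_width)
    return replicate_peaks, merged


def _random_peaks(rng, n, chrom_length, chrom_name, width) -> list[GenomicInterval]:
    if n <= 0:
        return []
    starts = rng.integers(0, chrom_length - width, size=n)
    return [GenomicInterval(chrom_name, int(s), int(s) + width) for s in sorted(starts)]


# ---------------------------------------------------------------------------
# Full scenario
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """All artifacts of one simulated study, with ground truth."""

    config: ScenarioConfig
    seed: int
    sequence: str
    truth: pd.DataFrame
    binding: pd.DataFrame
    pou_summits: dict[tuple[str, str], list[Summit]]
    sox2_summits: dict[tuple[str, str], list[Summit]]
    atac: dict[str, AccessibilityCondition]   # keys "MEF" and "<factor>_<day>"
    starr_truth: list[GenomicInterval]
    starr_replicates: list[list[GenomicInterval]]
    starr_merged: list[GenomicInterval]

    def locus_intervals(self, window: int | None = None) -> list[GenomicInterval]:
        w = window or self.config.locus_window
        return [
            GenomicInterval(
                row.chrom, max(0, row.center - w // 2), row.center + w // 2,
                name=row.locus_id,
            )
            for row in self.truth.itertuples()
        ]


def simulate_scenario(
    config: ScenarioConfig | None = None,
    seed: int = 1,
    rules: FactorRules | None = None,
) -> Scenario:
    """Run the full default scenario: genome, binding, ATAC, STARR.

    Child seeds for each stage derive from one ``SeedSequence`` so stages
    are independent but jointly reproducible.
    """
    config = config or ScenarioConfig()
    rules = rules or default_factor_rules(config.factors, config.days)
    ss = np.random.SeedSequence(seed)
    n_conditions = len(config.factors) * len(config.days)
    children = ss.spawn(3 + n_conditions + 1)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    sequence, truth = generate_genome(config, child_seeds[0])
    binding, pou_summits, sox2_summits = simulate_binding(
        truth, rules, config.factors, config.days, child_seeds[1],
        jitter=config.summit_jitter,
    )
    n = len(truth)
    atac: dict[str, AccessibilityCondition] = {}
    atac["MEF"] = simulate_accessibility(
        truth, np.zeros(n, bool), np.zeros(n, bool), config.opening,
        child_seeds[2], name="MEF", locus_window=config.locus_window,
        fragment_length=config.fragment_length,
        peak_min_count=config.peak_min_count,
    )
    k = 3
    for factor in config.factors:
        for day in config.days:
            name = f"{factor}_{day}"
            atac[name] = simulate_accessibility(
                truth,
                binding[f"sox2_{factor}_{day}"].to_numpy(),
                binding[f"pou_{factor}_{day}"].to_numpy(),
                config.opening, child_seeds[k], name=name,
                locus_window=config.locus_window,
                fragment_length=config.fragment_length,
                peak_min_count=config.peak_min_count,
            )
            k += 1

    # true enhancers: composite SoxOct loci (the class with reporter activity);
    # windows capped at min_spacing so truth regions are pairwise disjoint and
    # per-enhancer calls stay independent
    half = min(config.locus_window, config.min_spacing) // 2
    soxoct_loci = truth[truth["class"] == "SoxOct"]
    starr_truth = [
        GenomicInterval(row.chrom, max(0, row.center - half), row.center + half,
                        name=row.locus_id)
        for row in soxoct_loci.itertuples()
    ]
    starr_replicates, starr_merged = simulate_starr(
        starr_truth, config.chrom_length, child_seeds[k],
        n_replicates=config.starr_replicates,
        sensitivity=config.starr_sensitivity, fp_rate=config.starr_fp_rate,
        chrom_name=config.chrom_name,
    )
    return Scenario(
        config=config, seed=seed, sequence=sequence, truth=truth,
        binding=binding, pou_summits=pou_summits, sox2_summits=sox2_summits,
        atac=atac, starr_truth=starr_truth,
        starr_replicates=starr_replicates, starr_merged=starr_merged,
    )


def write_scenario(scenario: Scenario, outdir) -> Path:
    """Write the scenario as FASTA / BED / TSV files plus the config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(scenario.sequence, outdir / "genome.fa", scenario.config.chrom_name)
    scenario.truth.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    scenario.binding.to_csv(outdir / "truth_binding.tsv", sep="\t")
    for (factor, day), summits in scenario.pou_summits.items():
        _write_summits(summits, outdir / f"summits_{factor}_{day}.bed")
    for (factor, day), summits in scenario.sox2_summits.items():
        _write_summits(summits, outdir / f"summits_Sox2_{factor}_{day}.bed")
    for name, cond in scenario.atac.items():
        write_intervals(cond.fragments.fragments, outdir / f"atac_fragments_{name}.bed")
        write_intervals(cond.peaks, outdir / f"atac_peaks_{name}.bed")
    for r, peaks in enumerate(scenario.starr_replicates, start=1):
        write_intervals(peaks, outdir / f"starr_rep{r}.bed")
    write_intervals(scenario.starr_merged, outdir / "starr_merged.bed")
    write_intervals(scenario.starr_truth, outdir / "starr_truth.bed")
    scenario.config.to_yaml(outdir / "config.yaml")
    return outdir


def _write_summits(summits: Sequence[Summit], path) -> None:
    ivs = [GenomicInterval(s.chrom, s.pos, s.pos + 1, name=s.source) for s in summits]
    write_intervals(ivs, path)
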