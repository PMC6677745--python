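# Methods

This note documents the models, conventions and numerical choices behind
`chromtraj`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and interval logic

All coordinates are 0-based half-open (BED convention). Overlap means
sharing at least one base (`a.start < b.end and b.start < a.end`), matching
`bedtools intersect -wa -u` semantics; no minimum-overlap fraction is
applied anywhere. narrowPeak summits are `start + offset` (column 10); an
offset of −1 is treated as "no summit", and such peaks fall back to their
midpoint when a point position is needed.

Summit merging is single-linkage: two summits join the same locus iff they
are connected by a chain of pairwise distances ≤ `max_dist` (default
100 bp). On a line this is a sorted sweep — a new locus opens when the gap
to the previous summit exceeds `max_dist` — and is verified in the tests
against a graph connected-components oracle. A merged locus's
representative position is the floor of its envelope midpoint; the
alternative (summit of the strongest member peak) would require peak
scores, which summit files do not always carry. Resizing to a fixed width
places the anchor at `start + width//2` (deterministic tie-break for even
widths) and, at a chromosome's left edge, clips at zero while extending
right so the output width is preserved; callers holding a genome may
re-clip the right edge.

## Occupancy trajectories and accessibility classes

A locus's binary code has one digit per ordered condition; the all-zero
code cannot occur because loci are built from observed summits, leaving
2^k − 1 possible groups (7 for k = 3, 15 for k = 4). Condition order is
the caller's contract: chronological within factor, factors in the order
supplied.

Accessibility tiers use raw fragment counts over the peak interval itself
(not normalized): `< 15` low, `15–30` medium (both boundaries inclusive),
`> 30` high. Whether a fixed window around the summit would be more
appropriate than the peak interval is an open modelling question; the peak
interval was chosen and the thresholds are exposed (`TierThresholds`), so
the sensitivity is easy to probe.

PO / OC / CO chromatin trajectories are defined on the overlap-merged
union of a reference (fibroblast) and a later ATAC peak set; each universe
locus gets exactly one label, so the three classes partition the universe.

## Motif model

PWMs are probability matrices with a pseudo-probability floor of 1e-3 per
cell; scores are log₂ odds against a uniform 0.25 background. `N` bases
score 0 (neutral), so N-runs can never create a match. The default panel
is consensus-derived (consensus base probability 0.85):

| class | consensus | palindromic |
|---|---|---|
| octamer | ATGCAAAT | no |
| SoxOct | CATTGTTATGCAAAT | no |
| MORE | ATGCATATGCAT | yes |
| MORE+1 | ATGCATNATGCAT | yes (center N) |
| Sox_single | CATTGTT | no |

The SoxOct and MORE+1 strings are configurable placeholders — database
PWMs for these classes vary by motif-database version — and any MEME
minimal or plain-matrix PWM can be substituted. The match threshold
defaults to 85% of each PWM's maximum attainable score; at that stringency
only near-exact matches pass (a single mismatch already fails for every
default PWM) and the measured false-positive rate per class on 10,000
random 200-bp windows is below 5% (worst class: the short Sox_single
motif, ~2%). Perfect reverse-complement palindromes are scanned on the
plus strand only, so one physical palindromic site yields one match;
non-palindromic PWMs are scanned on both strands by scoring the
reverse-complemented matrix against the forward sequence. Scan windows are
200 bp centered on the locus representative position. Note that composite
SoxOct instances necessarily contain an exact octamer (and an exact
Sox_single) substring, so class annotations are not mutually exclusive —
fractions are reported per class, plus derived any/none/all/both
categories.

## Signal quantification

Two normalizations, recorded on every matrix:

* **FPKPM** — fragments per kbp of region per million library fragments —
  for ATAC signal, ratios and profile heatmaps.
* **pseudo-count + quantile** — add 1, then classic quantile
  normalization (each column replaced by the mean of column-sorted values
  at its ranks) — for ChIP matrices with large library-size differences.
  Ties receive the mean of the reference distribution over their full rank
  range; this matches the tie rule of the classic R implementation and
  agrees exactly with independent references on tie-free data, but it
  means columns share an identical sorted vector only when they are
  tie-free (tied entries share one averaged value).

Day/reference accessibility ratios are `(day + ε)/(ref + ε)` on FPKPM
values with ε = 0.1 — the guard bounds ratios at zero-reference loci while
preserving ordering; ε is configuration-exposed because the choice is a
convention, not a fit.

Motif-accessibility deviations follow the chromVAR idea in compact form.
For a peak set *m* and sample *s*, with T_p the peak's total over samples,
N_s the sample's total and N the grand total: E = (Σ_{p∈m} T_p)·N_s/N,
raw = (X − E)/E, and z = (raw − mean_bg)/sd_bg over ≥ 50 background peak
sets drawn from accessibility-matched quantile bins (10 bins of the
per-peak totals, sampling with replacement within bins). GC matching is
not performed; the backgrounds correct for overall accessibility level
only, which is the dominant confounder in the synthetic setting where base
composition is uniform by construction.

## Statistics

Rank-sum comparisons are two-sided Mann–Whitney U: exact null enumeration
when the pooled sample is ≤ 12 and tie-free, otherwise the normal
approximation with midranks and continuity correction (verified against
full enumeration in the tests). Multiple testing across one analysis
panel's pairwise family uses Holm's step-down. Classes with fewer than 3
loci are excluded from testing with a warning; the unbound background
class is summarized but not tested.

## The synthetic generator

The generator emulates the statistical skeleton of a reprogramming time
course, not its sequencing physics.

**Genome.** One 2-Mb chromosome of i.i.d. uniform bases. 3000 loci are
planted in disjoint slots ≥ 200 bp apart: 800 SoxOct, 600 MORE, 400
octamer, 200 MORE+1, 500 single-Sox and 500 motif-free decoys.
Non-palindromic instances land on a random strand; consensus `N` positions
get a random base. Planted instances are exact consensus strings, which is
why scanning recovers ≥ 99% of them — real motif instances are degenerate,
so recovery rates on real data will be lower and threshold-dependent.

**Binding.** Each locus binds each (factor, day) independently with a
class-specific probability encoding the dimerization biology: the
competent factor high on SoxOct at both days (0.85/0.90); the
Sox2-dimerization-defective mutant high on SoxOct at day 1 (0.85) but
nearly absent by day 5 (0.02) with residual MORE binding (0.40); the
MORE-preferring paralog high on MORE (0.90) and low on SoxOct (0.10).
Sox2 co-binds POU-bound SoxOct loci with 0.9 when the partner is
heterodimer-competent, is blocked to 0.05 when an incompetent partner
occupies the site, binds the free Sox half-site alone with 0.6, and binds
single Sox sites with 0.8. Bound loci emit a summit at the motif center
± 20 bp uniform jitter.

**Accessibility.** Openness is Bernoulli with
P(open) = logistic(β₀ + β_S·Sox2 + β_O·POU + β_OS·both), defaults
β₀ = −2, β_S = 2, β_O = 0.5, β_OS = 1: Sox2 is the dominant opener and
POU augments. The reference (MEF) condition has all binding terms zero, so
its loci open at the baseline rate logistic(−2) ≈ 0.12 — closed in the
main, but not degenerate, which keeps the PO and OC classes populated.
Fragment counts are negative-binomial (dispersion α = 0.3,
variance = μ + αμ²). A closed locus has mean 5. An open locus has mean
40 scaled by its opening propensity relative to the fully co-bound
configuration, with 10% of the mean unscaled
(`graded_amplitude = 0.9`): accessibility is graded, as ATAC signal is,
rather than two-state. This grading matters: the closed-to-open class is
defined by a day-condition peak call, and conditioning on a peak truncates
exactly the low tail that separates co-binding classes — under a purely
two-state emission the class medians collapse and no attribution is
possible, which no ATAC data set behaves like. The synthetic peak-call
threshold (emitted count > 8, between the closed mean and the graded open
means) and the amplitude were fixed by a small power analysis so the
planted ordering (shared > Sox2-only > POU-only) is detected with
comfortable margins at the default scenario size, then frozen. Fragments
are 100 bp, placed uniformly in a 400-bp window around the locus center.

**STARR.** True enhancers are the SoxOct-class loci, as 200-bp windows
(capped at the minimum planted spacing so truth regions are pairwise
disjoint and per-enhancer calls stay independent — a requirement of the
binomial recall oracle). Each replicate calls a true enhancer with
sensitivity 0.8; the pooled call set contains it with probability
1 − (1 − s)³; false positives are injected at 5% of the truth count as
random 300-bp peaks. Expected consensus recall is therefore
(3s²(1−s) + s³)·(1 − (1−s)³) ≈ 0.889 at s = 0.8.

**Determinism.** One seed drives a `SeedSequence` whose children seed each
stage; identical (config, seed) gives byte-identical FASTA/BED/TSV output
files.

**What passing tests do not show.** Loci are independent (no linked
enhancers, no domains); background sequence is uniform (no GC bias, hence
no GC-matched deviations); binding has no occupancy strength, only
presence; no read-level artifacts (duplicates, mappability, fragment-size
mixtures; no FASTQ). Recovery results on this generator demonstrate that
the analysis logic is correct, not that real ChIP/ATAC noise is handled.

## Problem sizes

Default analysis runs use the 3000-locus scenario on a 2-Mb genome; the
logistic-recovery experiment refits 100 independent simulations of 3000
loci; motif-scan specificity is measured on 10,000 random 200-bp windows.
These sizes give binomial/regression standard errors small enough that
every directional claim is tested with margin while a full run (test suite
plus acceptance script) completes in well under a minute of compute.

## Known limitations

* The consensus-derived PWMs are idealized; on real peak sets, motif
  fractions shift with the PWM source and threshold choice.
* The tier thresholds (15/30 raw counts) are meaningful only at
  sequencing depths comparable to the scenario's emission means; real
  libraries need rescaled thresholds.
* `motif_deviation` implements expected-fraction deviations with
  accessibility-matched backgrounds only — no GC correction, variability
  scores or dimensionality reduction.
* Exact rank-sum enumeration is limited to small tie-free samples;
  tied or larger samples use the midrank normal approximation.
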