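# Methods

## Overview

`ksdater` implements the classical Ks-based protocol for detecting and
dating whole-genome duplication (WGD) events in a transcriptome assembly,
plus the assembly-completeness statistics that normally accompany it.  The
chain is:

1. **Paralog pairs** — all-by-all nucleotide similarity hits filtered at
   E-value ≤ 1e-5, identity ≥ 40%, alignment length ≥ 150 bp (inclusive
   thresholds); self-hits dropped, reciprocal rows merged keeping the
   smaller E-value.
2. **Gene families** — connected components of the pair graph (single
   linkage on a similarity graph is exactly connected components).
3. **Node Ks** — per family, pairwise Ks values from a protein-guided codon
   alignment; agglomerative single-linkage clustering of the Ks matrix;
   each of the m−1 merges contributes one value (the median of the
   cross-cluster pairwise Ks at that merge).  This de-multiplication keeps
   a family of m near-simultaneous duplicates from contributing
   m(m−1)/2 correlated points.
4. **Age distribution** — node values with 0 < Ks < 2 (zero values are
   removed as identical transcripts / splice variants; values ≥ 2 are too
   saturated to be informative), histogrammed at width 0.05.
5. **Mixture model** — 1..10 normal components fitted to **ln(Ks)** by EM
   with 100 random + 10 k-means starts; component count selected by BIC
   (AIC reported alongside).
6. **Dating** — a component's location back-transforms as
   median Ks = exp(μ), and T = Ks / (2r) with r = 6.1 × 10⁻⁹ synonymous
   substitutions/site/year (angiosperm average).  The divisor 2 reflects
   two lineages accumulating substitutions independently since the
   duplication.

## Why the mixture is fitted on ln(Ks)

The protocol is often described loosely as "fitting normal distributions to
the Ks distribution", but the component table it produces reports ln-scale
means and a *back-transformed median*.  exp(μ) is the median of a lognormal
— that identity only makes sense if the normal components live on the log
scale.  We therefore fit normals to ln(Ks), equivalent to lognormal
components on the Ks scale.  This choice is load-bearing: it makes
exp(−1.383) = 0.251 → 0.251/(2·6.1e-9) = 20.6 Mya reproduce the reference
arithmetic exactly.  (One quirk: a median of 1.332 computes to 109.2 Mya by
the same formula, while 109.0 is sometimes quoted; the formula is
authoritative here.)

## Ks estimators

**NG86** (Nei–Gojobori 1986) is implemented as the transparent baseline:
synonymous sites counted per codon position as the synonymous fraction of
non-stop single-nucleotide changes; differences averaged with equal weight
over all stop-free shortest substitution pathways; Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p), undefined (flagged, never clamped) at p ≥ 3/4.
When every pathway between two codons passes through a stop (possible only
for 2–3-step pairs), the raw differences are split proportionally to the
pair's mean synonymous-site fraction and the estimate is flagged
`pathway_fallback`.  The test suite checks NG86 against an independent
exhaustive pathway enumerator, exactly.

**YN00** (Yang–Nielsen 2000 style) is the production estimator:

- codon frequencies from the F3×4 model, pooled over both sequences;
- κ (transition/transversion rate ratio) estimated from
  fourfold-degenerate and nondegenerate codon positions (classes compared
  only where both codons agree) under the Kimura two-parameter model,
  class estimates combined by site-count weighting, initial value 2,
  iterated to |Δκ| < 1e-6 (≤100 iterations);
- site counts weight each possible change by κ (transitions) and the
  target-codon frequency, normalized per position so S + N = 3L holds
  exactly;
- pathway contributions weighted by the product over steps of
  κ^{is-transition} × π(target codon);
- synonymous and nonsynonymous distances each corrected with the Kimura
  two-parameter formula using their own transition/transversion split.

With κ fixed at 1 and uniform codon frequencies this construction reduces
*exactly* to NG86's site counts — the limiting case the tests assert.
PAML's `yn00` binary applies additional internal roundings and slightly
different frequency bookkeeping, so third-decimal disagreement with it is
possible; correctness here is established through the limiting case and
through simulation recovery, not digit-matching.

Codon alignments are built by globally aligning the translated proteins
(BLOSUM62, gap open 10, gap extend 0.5 — recorded in output metadata) and
back-translating each aligned residue to its source codon.  Columns with a
gap or an N on either side never contribute to any count.  Both estimators
are symmetric in their inputs to machine precision.

## CDS extraction and protein filters

The best protein hit (max bitscore; ties by E-value, then subject id)
defines a unigene's coding span.  The query span is cut out,
reverse-complemented when qstart > qend, trimmed at the 3′ end to a whole
number of codons (the source protocol does not state the trimming side;
3′ was chosen and is logged), and translated with the standard nuclear
code.  A single terminal stop is trimmed before quality rules apply — a
natural ORF end is not a defect.  Proteins shorter than 50 residues
(strictly; 50 is kept) or containing an internal stop are rejected with a
per-id reason.  Codons containing N translate to X, not stop.

## Assembly QC

- **N50**: sort lengths descending; the first length at which the running
  sum reaches half the total.  Property-tested against a brute-force
  oracle.  (Note: N50 is *not* monotone under truncating one sequence —
  shrinking the total can raise it — so no such invariant is asserted.)
- **AT content**: (A+T)/(A+C+G+T), N excluded from the denominator.
- **Coverage depth**: cleaned-read bases / assembled unigene bases.
- **OHR** (Ortholog Hit Ratio): query bases covered by the best protein
  hit, |qend−qstart|+1, divided by 3× the matched protein's length
  ("bases in the hit region" is a query-nucleotide quantity, hence the
  query-side numerator).  OHR ≥ 1 is classed full-length even when > 1.
  Coverage classes are reported both cumulatively (>0.75, >0.5) and as
  disjoint 0.1-wide bins.

## Mixture fitting internals

EM on ln(Ks) with responsibilities/moment updates; convergence when the
relative log-likelihood improvement drops below 1e-8 or at 1000
iterations.  Random starts draw K means from sample quantiles at uniform
random positions plus jitter of 0.1×SD; k-means starts run Lloyd's
algorithm (scikit-learn, single init) and take cluster moments.  Start s
uses the deterministic seed (seed + s).  Floors: variance 1e-4 (ln scale),
weight 1e-8; a component pinned at both floors marks the start degenerate
and it is discarded.  The best *converged* start by log-likelihood wins;
components are reported sorted by ascending mean.  Free-parameter count
p = 3K − 1 (K means, K standard deviations, K−1 free weights) enters
AIC = −2ℓ + 2p and BIC = −2ℓ + p·ln n; criterion ties break toward the
smaller K.  The multi-start schedule is vectorized across starts; the
winning start is re-run solo to expose its iteration-by-iteration
likelihood trace, which tests assert is non-decreasing.

Components with ln-scale SD above 0.4 are labelled "background"
(continuous small-scale duplication spread over time, e.g. an SD of 0.83
versus 0.07 for a discrete burst); the label is descriptive metadata and
configurable — nothing is silently filtered, and only discrete-event
components receive dates in reports.

## The synthetic-data generator

Sequences evolve by a mechanistic proposal–acceptance process: point
mutations proposed uniformly over sites with transition:transversion ratio
κ:1; proposals creating stops rejected; nonsynonymous proposals accepted
with probability ω, synonymous always.  Multiple hits and
back-substitutions occur naturally, so the multiple-hit corrections are
genuinely exercised rather than fitted to planted counts.  The proposal
intensity is calibrated per configuration (n_codons, target, ω, κ,
estimator) by a 1000-replicate pilot at unit intensity, run under its own
deterministic seed and cached, so that the *expected estimated* Ks equals
the target.  The calibration is estimator-aware because NG86 and YN00
differ systematically under transition bias (κ = 2 moves them apart by
roughly 5–10%); pinning the expectation of one estimator necessarily
biases the other, so each recovery test calibrates to the estimator it
evaluates.  Family simulation uses a ladder of duplications at stated
pair-divergences, sharing one reference calibration (measured at Ks 0.3)
scaled linearly in branch length.

Defaults mirror the study conditions: 500-codon CDSs, ω = 0.2, κ = 2,
n = 529 node-Ks values for age-distribution samples, lognormal components
at the reference fit's parameters, truncation to (0, 2) by resampling.

What the generator does **not** emulate: indels (substitution-only keeps
back-translation exact and the codon bookkeeping honest), read-level
noise/assembly artifacts, alternative splicing, GC-biased gene conversion,
rate variation among sites or lineages.  Passing tests therefore
demonstrate correctness of the estimators, the clustering decomposition
and the mixture/dating arithmetic under the substitution model's
assumptions — not robustness to real-data pathologies such as fragmented
or chimeric transcripts.

## Numerical and reproducibility choices

- One global seed per run; per-stage seeds derived by stable hashing of
  (seed, stage name), all below 2³¹.
- Pairs whose alignment or Ks estimation fails inside a family get
  distance +∞ (family membership is a similarity-graph property and is
  preserved); clustering uses a large finite sentinel, summaries keep the
  true ∞ and such nodes fall outside the (0, 2) age window.
- Saturated distances are flagged undefined, never clamped.
- Histogram bins are half-open [low, high); out-of-range values are a
  hard error because range filtering is the upstream stage's contract.
- Thresholds are inclusive at their stated values.

## Problem sizes used by tests and the acceptance script

Chosen so a full run completes comfortably on one CPU: mixture
model-selection tests fit K = 1..3 or 1..4 (the library default remains
1..10); estimator-recovery tests use 200 replicates per target at 500
codons; the BIC-consistency check uses 20 seeds at n = 529; the
end-to-end recovery simulates 150 families of 300-codon CDSs.  The
acceptance script re-runs the refit at n = 529 with the full 100+10-start
schedule and the end-to-end pipeline at the same sizes.

## Known limitations

- At high divergence (Ks near the old-event range ~1.3) with 300-codon
  sequences, correction nonlinearity and κ-estimation noise give recovered
  event dates an upward scatter of roughly 5–10% across seeds; the
  recovery tolerance (15%) reflects estimator physics, not sloppiness.
- κ estimates from a single ~500-codon pair are noisy (SD ≈ 0.5 at
  moderate divergence); they are approximately unbiased in the mean.
- The component table's weights are not part of the reference fit's
  printout; refit simulations assume equal weights (documented where
  used).
- Single-linkage families chain: one spurious hit can merge two true
  families.  This is inherent to the protocol, not corrected here.
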