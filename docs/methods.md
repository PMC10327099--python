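# Methods

## The estimator

A diploid sample that is truly homozygous for the alternate allele at a
site should contribute no reference reads there. If a fraction *c* of the
sample's reads originates from other individuals' DNA, a contaminating
read carries the reference allele with probability *p*, the population
reference allele frequency at that site (*p* = 1 − *q*, with *q* the
alternate AF). The reference allele balance at a hom-alt site,
AB_ref = RR/(RR + AR), therefore has expectation

    E[AB_ref] = (1 − c)·0 + c·(p² + pq) = c·p .

Inverting the adjustment site by site and averaging over the *m* retained
hom-alt sites gives the point estimator

    CHARR = (1/m) Σ_j RR_j / (p_j · (AR_j + RR_j)) .

The per-sample likelihood of the read counts,

    L(c) = Π_j (1 − c·p_j)^{AR_j} (c·p_j)^{RR_j} ,

is maximized by grid search over c ∈ {0, 0.001, …, 0.1}. When
1 − c·p_j ≈ 1 (true throughout the grid) the maximizer has the closed
form Σ_j RR_j / Σ_j p_j(AR_j + RR_j), which differs from CHARR only in
averaging order; the two agree closely at realistic contamination levels
and the package computes all three (`charr`, `grid_mle`, and the
closed form carried on `MleResult`).

Numerical conventions: 0·log 0 ≡ 0 so the log-likelihood is finite (0) at
c = 0 for a contamination-free sample; grid ties break toward the smaller
c; an empty retained set produces a flagged (`insufficient`) result with
`charr = nan` rather than an error, so batch runs never abort.

## Variant selection

Defaults (all configurable via `FilterConfig`):

| gate | default | note |
|---|---|---|
| autosomes only | on | contigs 1–22 after stripping a `chr` prefix |
| biallelic | required | multi-allelic records are marked, never split |
| variant type | SNV | indels work adequately; selectable |
| GQ | ≥ 20 | inclusive |
| DP | 20–100 | inclusive both ends |
| genotype | hom-alt | |
| ref AF window | 0.10 < p < 0.90 | strict; a symmetric cutoff ≥ 5 % is the floor for accuracy |
| sufficiency | ≥ 500 sites | below it the estimate is flagged, not suppressed |

The AF window exists because the estimator divides by *p*: at tiny *p* a
single noise read contributes 1/(p·DP) and can dominate the mean. No
per-site winsorization is applied; the window is the only guard.

Records are assigned exactly one fate in a fixed precedence order
(non-autosomal → multi-allelic → type → GQ → DP → genotype → AF missing →
AF window → retained), so `FilterReport` counts always partition the
input. Records with absent FORMAT fields are rejected (missing GQ at the
GQ gate, missing DP/AD at the DP gate) rather than imputed: every
estimator term needs RR, AR, and the quality gates.

The companion QC statistic `het_hom_ratio` counts het vs hom-alt calls
among records passing the quality gates. It rises when contamination
converts hom-alt calls to het — exactly the regime where the estimator
itself is biased downward — and is reported alongside every estimate.

## The simulator

The simulator replaces a read-level mixing pipeline with its
allele-count equivalent; the estimator consumes only GT/AD/DP/GQ, so
read positions, mapping and base qualities would add nothing testable.

Stated world (defaults of `SimScenario`):

- **Cohort**: 30 samples in 6 strata of 5 (strata emulate ancestry groups
  and only constrain two-way pairing; no per-stratum AF differentiation).
- **Sites**: alt AFs i.i.d. Beta(0.2, 0.2) truncated to [0.05, 0.95] by
  resampling — a U-shaped spectrum resembling segregating sites in a
  small diverse cohort. Truth genotypes are Hardy-Weinberg:
  dosage ~ Binomial(2, q).
- **Rates**: 0.5 %, 1 %, 2 %, 5 %, 10 %.
- **Reads**: DP ~ Poisson(30). Each read is contaminant with probability
  c; in `two_way` mode the contaminant is a fixed partner (a permutation
  in which every sample is original once and contaminant once, never
  within its own stratum), in `n_way` mode a fresh uniform draw among the
  other 29 samples per read. The read's allele comes from the origin's
  *true* genotype (physical DNA, not the called genotype) and is flipped
  to the other allele with probability `seq_error = 0.001`. Per-read
  draws are collapsed into binomials with the exact marginal allele
  probability — identical in distribution, orders of magnitude faster.
- **Calling**: flat-prior per-read maximum likelihood over the three
  diploid genotypes (P(ref read) = 1−e, ½, e under hom-ref/het/hom-alt),
  GQ = min(99, 10·log₁₀(L_best/L_second)). This is the simplest caller
  that produces the hom-alt → het conversion responsible for deflation at
  high contamination.
- **Reproducibility**: one `numpy` Generator seeded from
  `SimScenario.seed`; draws occur in a documented order (AFs, site keys,
  truth, pairing, then reads per rate in listed order), so emitted VCFs
  and truth tables are byte-identical across runs.

Two-way pairing is built by rotation: shuffle members within strata,
shuffle stratum blocks, rotate by a random offset k with
max-stratum ≤ k ≤ n − max-stratum. Such a k exists iff no stratum holds
more than half the cohort (also the feasibility condition for any valid
pairing, by Hall's theorem); rejection-sampling permutations, by
contrast, essentially never terminates at two strata of n/2.

## What a green simulation test does and does not establish

The generator emulates allele-count statistics of contamination, not real
sequencing: no mapping error, no base-quality structure, no indel
realignment, no reference bias, no linkage between sites, and a caller
far simpler than production callers. Green tests establish that the
estimator recovers the generative c of this model and that the deflation
mechanism (hom-alt → het conversion) behaves qualitatively as in real
pipelines; they do not certify accuracy on real callsets.

Two quantitative consequences of the simplifications, measured and kept
(not tuned away):

1. **Low-c inflation.** The biallelic error model routes *every* base
   error at a hom-alt site into a reference read, so
   E[CHARR] ≈ c + e·E[1/p] ≈ c + 0.004 at defaults. At c ≤ 0.01 this
   dominates, and the mean estimate misses truth by far more than the
   15 % recovery tolerance the test suite asserts (those cases fail, by
   design of the stated world). Real pipelines do not show this because
   an error hits the specific reference base only ~⅓ of the time and
   quality-aware callers down-weight it.
2. **High-c deflation.** With DP ≈ 30 the flat-prior caller plus the
   GQ ≥ 20 gate keeps hom-alt calls only up to RR ≲ 0.1·DP − 0.7, a
   harsher truncation than a production caller's. At c = 0.10 the
   measured downward bias is ≈ 16–17 % (pure truncation ≈ 21 % minus the
   error inflation above) — same mechanism and direction as the ~10 %
   deflation seen in read-level pipelines, larger in magnitude.

## Allele-frequency sources

`p` is always derived as 1 − q from a stored alternate AF. Two sources
are supported: the callset's own `INFO/AF`, or an external sites table
(TSV: contig, pos, ref, alt, af). Joins are exact on
(contig, pos, ref, alt) after contig normalization and allele
uppercasing; a table entry with swapped ref/alt is deliberately a miss,
because a silent swap would replace p by 1 − p and corrupt the estimate.
Lookup misses reject the record (`af_missing`), never default.
Equivalence with other implementations' AF handling is not guaranteed.

## Known limitations

- Reference blocks (gVCF) are ignored entirely; only variant records
  contribute, which matches the estimator's definition.
- High contamination (> 5–10 %) deflates the estimate; use
  `het_hom_ratio` to flag such samples rather than trusting the point
  value.
- The simulator's AF spectrum, depth model and caller are idealizations
  (see above); absolute biases measured on it transfer to real data only
  qualitatively.
- Multi-allelic sites are dropped, not decomposed; cohorts rich in
  multi-allelics lose those sites from the estimate.
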