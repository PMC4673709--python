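# Methods

## Pooled-hybridization observation model

All copy-number inference in this package rests on one model of pooled
DNA.  Hybridizing population DNA against a single-copy reference, a
segment present at population-average copy-number *c* per haploid
genome yields an expected probe log2 ratio of log2(*c*).  Under a
one-extra-copy model for duplication carriers, a duplication at allele
frequency *q* gives *c* = 1 + *q* and a deletion gives *c* = 1 − *q*;
inverting, an amplified segment with mean log2 ratio *m* is read as
*c* = 2^*m* and *q* = clip(*c* − 1, 0, 1), and a deleted segment as
*q* = clip(1 − *c*, 0, 1).  Clipping matters in practice: fixed
duplications occasionally measure *c* slightly above 2 (e.g. 2.19), and
the clipped frequency of 1 — fixation — is the intended reading.  The
synthetic generator (`synthetic.simulate_acgh`) implements exactly this
model plus iid Gaussian probe noise; probes over a fixed deletion
(log2 0) are clamped at a configurable floor, −8 by default, mimicking
the finite background intensity of real arrays.

What the generator deliberately does not emulate: probe GC/sequence
bias, cross-hybridization, dye bias, spatial artefacts, or
genotype-level (rather than pooled-mean) signal.  Tests that pass on
synthetic data therefore validate the algorithmic chain under the
stated noise model, not robustness to array-specific artefacts.

The per-probe noise level is a free parameter; the default
`probe_sd = 0.25` was chosen once as a realistic magnitude for 50-mer
oligonucleotide arrays and is not derived from any published value.

## Segmentation and calling

Segmentation is bottom-up agglomerative, per chromosome: every probe
starts as its own segment; the adjacent pair with the greatest
similarity — the largest Welch (unequal-variance) two-sample *t*-test
p-value — is merged, neighbours are re-tested, and merging stops when
no adjacent pair reaches `p_merge`.  Ties in the maximal p-value break
to the leftmost pair, making the procedure deterministic.

Numerical choices:

- Singleton segments have undefined sample variance, and two-probe
  segments estimate it from one degree of freedom.  Every segment
  variance is therefore floored at a global robust noise variance,
  (1.4826 · MAD of first differences / √2)², before the Welch test.
  The floor only raises p-values, so any pair left unmerged is also
  unmergeable under the raw Welch test — the stopping condition is
  conservative, and is verified in the tests against independent
  re-computation of every surviving adjacent pair.  Without the floor,
  a pair of coincidentally similar adjacent probes can freeze into a
  permanent micro-segment, a known artefact of greedy agglomeration.
- Welch degrees of freedom use max(n − 1, 1) per segment; a pair with
  zero pooled standard error gets p = 1 when the means agree exactly
  and p = 0 otherwise (so noiseless steps split, and constant profiles
  merge completely).

A segment is labeled amplified when mean ≥ `m_min`, a one-sample
*t*-test against 0 gives p ≤ `p_class`, and it spans at least
`min_probes` probes; deleted symmetrically.  The thresholds are
user-set by design; the defaults `p_merge = 1e-3`, `m_min = 0.2`,
`p_class = 1e-3`, `min_probes = 3` were fixed once so that simulated
duplications at q ∈ {0.25, 0.5, 1} under probe_sd 0.25 are recovered
with median frequency error < 0.1, and are not tuned per dataset.
There is no interactive inspection step: threshold selection is
explicit configuration.

Calls carry two intervals: the inner interval (first to last internal
probe — the minimum span) and the outer interval extending to, but
excluding, the adjacent flanking probes (or to the chromosome end when
none exists).  The true breakpoint lies between them; with sparse
probes that uncertainty can be tens of kb.

Quantile normalization across arrays replaces each profile's sorted
values with the across-profile mean order statistics, averaging tied
ranks.  Applied to a single profile it is the identity; whether the
original analyses normalized within or across arrays is not
documented, and across-array normalization is the variant implemented.

## qPCR quantification

A run is four groups of unpaired technical replicates — reference DNA
with reference primers (R/R′), reference DNA with test primers (R/T′),
test DNA with reference primers (T/R′), test DNA with test primers
(T/T′).  With group means on the Ct scale,

    ΔΔCt = (T/T′ − T/R′) − (R/T′ − R/R′),   ratio = (1 + E)^(−ΔΔCt).

E is the amplification efficiency of the reference, from the
least-squares slope *b* of Ct on log10 concentration of a per-plate
dilution series: E = 10^(−1/*b*) − 1 (perfect doubling at
*b* = −3.3219).  Positive or implausibly shallow slopes (|*b*| < 0.1)
raise a calibration error; E marginally above 1 is clipped at 1.1 with
a warning.  One shared E is applied to all four groups; per-primer
efficiencies are out of scope.

Confidence intervals are percentile bootstrap: each of 10,000
iterations resamples Ct values with replacement within each group
(preserving group size), recomputes the ratio, and the CI is the
2.5/97.5 % quantiles of the sorted bootstrap ratios, from one seeded
generator per call.

**Known limitation.** With the standard design of three replicates per
group, the percentile bootstrap undercovers: the bootstrap variance of
a mean of *n* draws is (n−1)/n² σ² against the true σ²/n, an SE ratio
of √(2/3) ≈ 0.82 at n = 3.  Simulated coverage of the nominal 95 %
interval is ≈ 0.85 at 3 replicates/group, ≈ 0.91 at 10 and ≈ 0.95 at
30.  The procedure is implemented as specified (it is the field's
standard reporting practice); consumers should read the 3-replicate
CIs as optimistic.

## Single-worm frequency estimation

Only adult males are assayed (females of an outcrossing strain carry
nonclonal eggs).  For X-linked loci males are hemizygous and the
positive fraction estimates *q* directly.  For autosomal loci the
assay scores carriers, so under Hardy–Weinberg the non-carrier
fraction is (1 − q)² and q̂ = 1 − √(1 − k/n).  Boundary counts need no
special casing (k = 0 → q̂ = 0; k = n → q̂ = 1) and no continuity
correction is applied.  The implied copy-number is ĉ = 1 + q̂
(duplication) or 1 − q̂ (deletion).  Estimates are rounded to two
decimals by default, matching the precision such assay tables are
reported at; pass `decimals=None` for raw values.  CIs are exact
Clopper–Pearson intervals on the carrier fraction mapped through the
(monotone) carrier-to-allele transform.

For a given positive fraction the autosomal estimate never exceeds the
X-linked one (1 − √(1−f) ≤ f), a property the tests exercise.

## Catalog, convergence and breakpoint arithmetic

Coordinates are 1-based inclusive throughout; spans are
end − start + 1, and BED export converts to 0-based half-open.
Feature annotation counts any feature overlapping a call by ≥ 1 bp — a
partially deleted gene is a deleted gene.  Catalog summaries use the
conventional median (mean of the two central order statistics for even
counts).

Convergent CNVs are same-chromosome, same-type calls from independent
populations that overlap.  The default mode reports maximal sets with a
non-empty common intersection (for intervals, exactly the maximal
cliques of the overlap graph, found by a sweep over candidate
point-covering sets and verified in tests against exhaustive subset
enumeration); a connected-components mode is available when a chain of
pairwise overlaps without a common point is of interest.  The shared
region is [max member start, min member end] with inclusive length —
the arithmetic that reproduces the printed shared-region sizes
(17,333 bp; 3,934 bp; 629 bp; 272,054 bp) exactly, where exclusive
arithmetic is off by one on all four.  Clusters mixing duplications
with deletions are never formed.

Repeat-mediated breakpoints: for a tandem duplication formed by
unequal crossing-over between two homologous flanking repeats, the
chimeric repeat at the junction begins as the downstream repeat and
ends as the upstream repeat.  At each informative site (aligned
position where the repeats differ) the chimera is classified as
downstream- or upstream-type; the crossover lies in the open interval
between the last downstream-type site and the first upstream-type
site.  A chimera matching neither repeat at a site raises an error
listing the offending positions; more than one switch means the
product is not a simple single-crossover chimera and is rejected.
Distinct chimeras whose intervals fall in different inter-site gaps
demonstrate independent crossover events.

## Population genetics

- Full-sib inbreeding: F_t = (1 + 2F_{t−1} + F_{t−2})/4 from
  F₀ = F₋₁ = 0; fifteen generations give 0.961.  The tests check the
  recursion against a gene-dropping Monte-Carlo pedigree simulation.
- Neutral fixation time: 4N_e generations, the diffusion expectation
  for a new neutral mutation conditional on fixation (the
  unconditional absorption time, dominated by quick losses, is not the
  quantity of interest).  At N_e = 50 the Wright–Fisher engine
  reproduces it within 5 % over 2 × 10⁵ replicates.
- Mutation pressure: with gain rate μ and no loss,
  p_t = 1 − (1 − μ)^t (≈ 2 % at μ = 10⁻⁴ after 200 generations); with
  loss δ the update p ← p + μ(1 − p) − δp is iterated and approaches
  μ/(μ + δ).  Gain is treated as recurrent and irreversible when
  δ = 0.
- Wright–Fisher engine: genic (haploid) selection,
  p′ = p(1 + s)/(1 + ps), gain/loss applied deterministically before
  the binomial draw of 2N_e gametes; boundaries absorb only when
  μ = δ = 0.  Diploid dominance is out of scope.  The
  drift-compatibility test reports the Monte-Carlo probability that a
  neutral allele starting at p₀ reaches the observed frequency by
  generation t, with its binomial standard error; it agrees with the
  exact one-generation binomial computation.

## Comparative statistics

The rank-sum test uses midranks, the tie-corrected variance
Var[W] = n₁n₂/12 · (N + 1 − Σ(t³ − t)/(N(N−1))), and a continuity
correction of ½ toward zero.  The normal approximation's accuracy was
mapped exhaustively against the permutation distribution: for untied
samples with both groups ≥ 3 and pooled n ≤ 10, the two-sided p is
within 0.05 of exact everywhere and the one-sided p within 0.016 in
the tails (exact ≤ 0.25).  Agreement degrades for size-2 groups and
near the centre of the discrete distribution, and heavy ties can make
the one-sided approximation arbitrarily poor; the tests assert the
property only on its verified domain.  Printed span-comparison Z
values against external span datasets are treated as demonstration
inputs, since the comparison samples are not available to recompute
them.

Pearson's r compares copy-number estimates between assay methods; over
the internally consistent rows of the packaged single-worm table the
single-worm and qPCR copy-numbers correlate at r ≥ 0.9.

## Packaged tables

The package ships TSV transcriptions of the underlying study's printed
summary tables: 25 duplications, 25 deletions (coordinates, spans,
copy-numbers, feature counts) and 16 single-worm assay rows.  Rendering
of the source concatenates digit groups, so feature-count fields that
do not parse uniquely are stored as NA rather than guessed (most
duplication rows; one deletion row).  Two duplication rows had a stop
coordinate inconsistent by 1–2 bp with the printed span; the printed
span is kept and the stop set to start + span − 1, flagged
`coordinate_adjusted`.  Three single-worm rows are internally
inconsistent (positives exceeding the sample, or a printed frequency
that does not equal the estimator applied to the printed counts) and
carry explicit flags; flagged rows are excluded from exact
row-reproduction checks.  Loaders verify SHA-256 checksums of the
packaged files.

## Problem sizes and reproducibility

Simulation-based checks run at sizes chosen for tight Monte-Carlo
error at interactive cost: 100-seed breakpoint-recovery and
frequency-recovery sweeps on 100–200-probe profiles; 500 replications
for bootstrap coverage; 2 × 10⁵ Wright–Fisher replicates for the
conditional fixation time; 4 × 10⁴ pedigree replicates for the
inbreeding oracle.  Every stochastic component takes an explicit seed;
the pipeline derives per-stage substreams from a single root seed via
named spawn keys, so any stage can be re-run in isolation and full runs
are bit-for-bit reproducible.  Plotting is deliberately omitted:
trajectory, convergence and neutrality outputs are emitted as TSV/JSON
tables for downstream figure-making.
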