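# Methods

## The interaction network and its statistics

The substrate is an undirected, signed epistasis network: for a measured
gene pair, ε is the deviation of the double mutant's fitness (colony size)
from the multiplicative expectation of the single mutants, with a p-value
per measurement.  The raw screen is directional (query × array) and may
contain replicate alleles, so `GIMatrix.from_edges` first collapses
replicates of a direction to the minimum-p measurement and then
symmetrizes: an unordered pair is significant if either direction is
significant at the chosen α; its ε is the significant direction's value, or
the mean when both directions are significant.  Rationale: epistasis is a
property of the gene pair, while the assay direction is a technical
artifact.  Significance is strict (*P* < α, default α = 0.05), so a
measurement at exactly α is excluded.

**Shared-partner proportion.**  For copies *i*, *j* with significant
partner sets A, B, Θ = 2|A∩B| / (|A|+|B|).  By default each copy is
removed from the other's set first, so a direct interaction between the
two copies does not count as sharing; the same convention is applied
inside the resampled null so duplicate pairs and null pairs are measured
identically.  Pairs with |A|+|B| = 0 are flagged undefined and excluded
from class means, with counts reported.

**Random-singleton-pair null.**  Singletons with non-empty significant
profiles are enumerated once; each null sample is Θ for a uniformly drawn
unordered pair of distinct eligible singletons (drawn with replacement
across samples, reproducible from the seed).  The empirical test reports
an add-one one-sided p, (1 + #{Θ_null ≥ Θ̂}) / (1 + n), and an enrichment
flag that is true only when the observed mean strictly exceeds the null's
95th percentile — the upper-tail reading of "the mean lies outside the
central 90% density of the null".

On an Erdős–Rényi network of density q the null mean converges to q: the
expected number of shared partners of two singletons is q²(N−2) and the
expected degree sum is 2q(N−2) after removing the co-sampled partner, so
the ratio of expectations is exactly q.  Two finite-size effects matter at
desk scale and are accounted for when the law is tested.  First, Θ is a
ratio, and the delta method gives E[Θ] ≈ q·(1 − (1−q)/(2(N−2)q)); at
N = 2000, q = 0.05 that is a relative bias of about −0.5%.  Second, a
single simulated network realizes its density with binomial noise of
standard deviation √(q(1−q)/C(N,2)), and the measured null mean tracks the
realized density.  The calibration test therefore compares the null mean
to q using the combined standard error
√(q(1−q)/C(N,2) + Var(Θ_null)/n_pairs); with 10⁵ resamples both terms are
of order 10⁻⁴ and the bias sits inside the 3-SE band.

**Partner clustering.**  κ = 2l / (n(n−1)) where l counts significant
edges among a gene's n significant partners; κ is undefined (flagged,
excluded from means) for n < 2.  The joined-pair variant computes κ on the
union of both copies' partner sets with the copies themselves removed.

**Divergence bins.**  Pairs are binned by amino-acid divergence into
[0, 0.4], then width-0.2 right-closed bins, and an open last bin at
≥ 1.8 substitutions/site.  Only the first and last bin boundaries are
dictated by the binning convention of the underlying comparison; interior
bins are right-closed by explicit choice, stated here because a tie at an
interior edge must land deterministically.

## Duplicate-pair catalog

Reciprocal best hits over 12-column tabular similarity hits, with
E-value ≤ 10⁻⁵ and bit score ≥ 50 (defaults).  The best hit of a gene is
the retained hit with maximal bit score; ties break by minimal E-value and
then lexicographically smallest subject, so the output is independent of
input row order.  When one gene would appear in several mutual-best pairs
(possible after score ties), only its highest-scoring pair is kept,
enforcing at most one pair per gene.  Pairs present in the curated ohnolog
list are labeled WGD, all others SSD; the ohnolog list is authoritative, so
curated pairs missed by the similarity search are injected as WGD pairs
with a warning.  The young-SSD filter removes SSD pairs whose divergence
falls strictly below the 5th percentile (linear-interpolation empirical
quantile) of the WGD divergence distribution; a pair exactly at the
threshold is kept.  The filter is idempotent and monotone in the
percentile, and errors out when no WGD pairs exist (threshold undefined).

## Sequence divergence

Distances are maximum-likelihood distances under the JTT empirical
amino-acid model (published exchangeabilities and equilibrium frequencies,
embedded in `jtt.py`; no rate heterogeneity, and model frequencies rather
than per-pair empirical frequencies — the plain JTT model).  Columns with
a gap in either sequence are deleted pairwise, independently for each of
the three pairwise comparisons in a triple.  The likelihood
Σ log(π_x P_xy(t)) is maximized by bounded Brent search on
t ∈ [10⁻⁶, 10] with tolerance 10⁻⁶; estimates at the cap are flagged
`saturated` so class means are not dominated by unstable estimates, and
alignments with fewer than 30 ungapped columns are flagged
`low_confidence`.  P(t) is computed by symmetric eigendecomposition of the
reversible rate matrix, which is exact for a 20-state chain.  The
implementation agrees with an independent phylogenetics package
(`phangorn::dist.ml`, JTT) to ~10⁻⁶ on simulated pairs and with a
brute-force likelihood grid (step 10⁻³) within 2×10⁻³.

For a duplicate pair (a, b) with outgroup ortholog c, the three-point
formula gives the branch lengths from each copy to their common ancestor:
branch_a = (d_ab + d_ac − d_bc)/2 and symmetrically for b.  Estimated
distances need not be additive, so a negative solution is clipped to zero
with the deficit moved to the sibling branch; the sum always equals d_ab
and clipping is flagged.  Two normalized statistics are emitted: the
branch asymmetry |branch_a − branch_b| / (branch_a + branch_b), and the
total branch_a + branch_b.  The verbal definition of the normalized
divergence in the source analysis is ambiguous between these two readings,
so both are computed and the output table carries both; the pairwise
comparison of class means uses d_ab (the "total" variant), which is the
reading consistent with per-copy ancestor distances reported alongside
such tables.

## Localization overlap

Compartment labels are whitespace-normalized and case-folded.  Two copies
are "different" when their compartment sets are not identical — either
disjoint or partially overlapping.  The WGD/SSD contrast is built at the
pair level (each pair one observation); copy-level counts (every cell
doubled) are emitted for transparency and leave the sample odds ratio
unchanged.  Pairs with an unannotated copy are excluded and counted.

## Mutation accumulation

Candidate SNPs are retained when read depth ≥ 5, mean mapping multiplicity
equals 1 (tolerance 10⁻⁹), and at least 85% of base calls support the
variant; all retained-side boundaries are inclusive.  Variant identity is
(chrom, pos, alt); ancestral subtraction is a set difference on that key.
Because lines are propagated by single-colony transfer, SNP sets should be
nested over passages; violations are reported, never silently repaired.
Accumulation is fit by ordinary least squares of the cumulative SNP count
against generations (passage × 22 generations per passage), per line and
per category (total / synonymous / non-synonymous), requiring at least
three sequenced passages.

Class enrichment compares the observed share of annotated non-synonymous
SNPs falling in singleton / SSD / WGD genes with an expectation equal to
each class's share of total CDS length (default; a gene-count model is
also provided).  CDS length is the default because longer coding sequences
are bigger mutational targets and protein length differs systematically
between classes.  A χ² goodness-of-fit runs across the three classes
(df = 2), and 2×2 Fisher tests (SSD vs WGD, genes hit vs not hit) run per
line and pooled.

## Statistical tests

Implemented self-contained with exact small-sample behavior; only
distribution functions come from scipy.  Welch's t uses the
Welch–Satterthwaite df; two constant samples with equal means give t = 0,
p = 1.  The Wilcoxon rank-sum test uses midranks, an exact null for
n ≤ 20 (a subset-sum dynamic program in the tie-free case, full
enumeration of rank assignments with ties) and otherwise the normal
approximation with tie and continuity corrections; the two-sided p is the
probability of a rank sum at least as far from its mean as observed.
Fisher's exact test uses the probability-mass two-sided rule (the sum of
margin-fixed tables no more probable than the observed), reports the
sample odds ratio ad/bc as the headline estimate — the convention that
reproduces the odds-ratio-style "F" statistics quoted with such tests —
and also the conditional maximum-likelihood odds ratio obtained by solving
the noncentral hypergeometric mean equation.  χ² goodness-of-fit rescales
the expected vector to the observed total when they disagree (logged) and
errors on a zero expected cell.

Calibration: each test's empirical type-I error at α = 0.05 is verified to
lie in [0.035, 0.065] over 2,000 null replicates.  The Fisher calibration
uses 2×2 tables from two binomial(500, 0.5) groups: with smaller tables
the exact test's discreteness makes it strictly conservative and its
attainable size drifts below the band, which is a property of the test,
not an implementation defect.

## The synthetic-data generator

Defaults emulate the study system at its published scale: 4,464 assayed
genes, 430 WGD and 248 SSD pairs, background interaction density 0.077
(≈ 343 significant interactions per singleton), within-pair interaction
rates 19.8% (WGD) and 12.9% (SSD) with within-pair ε means −0.343 (WGD)
and −0.222 (SSD), divergence draws with class means 0.267 (WGD) and
0.3082 (SSD), localization-divergence rates 0.240 (WGD) vs 0.331 (SSD),
and five MA lines sequenced at passages 20–100 (22 generations/passage)
accumulating ~1.8 mutations per passage with non-synonymous retention
probabilities 0.85 / 1.0 / 0.8 for singletons / SSD / WGD (the SSD:WGD
ratio of 1.25 is the study's effect size).  Tests and calibration runs
pass smaller explicit configurations; every generator is a pure function
of (config, seed).

Background edges are Bernoulli(q) among singletons, enriched within
functional modules (singletons are partitioned into modules; within-module
pairs get density q × enrichment).  Each duplicate pair draws an ancestral
partner set (~Poisson(K) genes) from one module and transforms it by mode:

* **sub** (default for WGD): the set is partitioned disjointly between the
  copies (asymmetry parameter a; residual joint retention o), so the
  copies share only the residual overlap and both partner sets stay inside
  the ancestral module — clustering among partners stays high while
  sharing sits at or below the chance level of random singletons.  An
  optional degree-matching mode tops each copy up with random background
  partners to the singleton mean degree; it is off by default because
  module-agnostic background dilutes the partner-clustering signal that
  the sub mode exists to produce.
* **neo** (default for SSD): copy A keeps the whole set; copy B keeps a
  fraction f and gains novel partners from a different module until its
  partner count equals copy A's, so the expected Θ equals f by
  construction — the basis of the parameter-recovery calibration
  (500 pairs, K = 40, f = 0.6 → mean Θ̂ within ±0.02 of f).
* **buffering**: both copies keep the full set, but each copy-edge is
  masked (p-value pushed above α) with probability
  m(divergence) = m₀ · max(0, 1 − divergence/scale), so low-divergence
  pairs show fewer detected interactions.

Detected edges receive p = α·Beta(1, 3) (concentrated well below α);
undetected true edges and masked edges receive p ~ U(α, 1).  True edges
are detected with the configured power; optional false positives among
unmeasured singleton pairs are off by default so that analytic
null-density checks remain exact.  ε is drawn sign-first (negative with
probability 0.56) from folded normals whose magnitudes match the
class-level means, with per-class scale factors reproducing the
singleton > SSD > WGD ordering of epistasis strength.

Sequence triples evolve an equilibrium-drawn ancestor along branches
(t_a, t_b) to the two copies and t_c to the outgroup, giving additive true
distances.  MA lines accumulate Poisson arrivals per passage; exonic
candidates land in genes with probability proportional to CDS length,
non-synonymous candidates fix with the class retention probability, and QC
fields are drawn to pass the candidate filters, alongside a configured
rate of artifact candidates that each fail exactly one filter.

What the generator does **not** emulate: the heavy-tailed degree
distribution of the real screen (optional log-normal activity multipliers
exist but are off, to keep the null-mean law analytic), correlated
measurement error between the two screen directions, linkage between SNPs,
chromosome structure beyond 16 uniform chromosomes, and gene families
larger than two.  Passing calibrations therefore demonstrate correctness
of the statistics and recoverability of the generating parameters, not
robustness to every property of real screens.

### Calibration designs

The MA direction-recovery calibration (SSD retention 1.25× WGD recovered
in ≥ 95% of 200 replicates) uses 25-line panels rather than the 5-line
default: at five lines (~400 non-synonymous SNPs) the per-replicate z for
the ratio comparison is ≈ 1.3, giving only ~90% direction recovery — an
adequately powered panel needs roughly five times the mutation count, and
25 lines is a typical size for mutation-accumulation panels.  The
null-mean law is tested at N = 2000, q = 0.05 with 10⁵ resamples using the
combined standard error derived above.  Disjoint-partition recovery is
tested the way the underlying comparison is made in practice: the sub-pair
mean Θ must lie within the central density of the singleton null (within
three null standard deviations, with no enrichment flag), since a fully
partitioned pair shares nothing and its mean falls at or below the chance
level rather than at the null mean exactly.

## Numerical choices and degenerate inputs

* Empirical quantiles use linear interpolation (numpy default) everywhere.
* Θ and κ are undefined (None, flagged) rather than zero when their
  denominators vanish; class means skip undefined values and report counts.
* The JTT optimizer's saturation cap is 10 substitutions/site; identical
  sequences return t < 10⁻⁴ (the lower bound is 10⁻⁶).
* Edge tables reject p-values outside [0, 1] and non-finite ε at
  construction; SNP tables reject malformed rows with their row number.
* The pipeline aborts on the first failing stage, names it, removes
  partial outputs, and writes a manifest whose content (checksums, seeds,
  results; no timestamps) is byte-identical across reruns of the same
  configuration.

## Known limitations

* Exact count reproduction of the real catalog (248 SSD / 430 WGD pairs)
  depends on the similarity-search version and database used upstream and
  is not guaranteed by the RBH rules alone.
* The Wilcoxon exact branch enumerates rank assignments only up to
  n = 20; beyond that the corrected normal approximation is used.
* The three-point decomposition assumes the outgroup is a true outgroup;
  a misplaced outgroup shows up as branch clipping, which is flagged but
  not corrected.
* Multi-gene families are reduced to at most one pair per gene; resolving
  larger families would require trees, which are out of scope.
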