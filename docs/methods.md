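# Methods

This note records the models behind each component, the defaults and
why, the numerical choices, and what the simulation-based tests do and
do not establish about real data.

## Data model and panel normalization

A haplotype table is individuals × loci integer repeat counts with a
population label per individual. Missing values are an explicit
sentinel (`NA`, empty, `.`, `-`) and are never coerced to 0, which is
not a possible repeat count. Repeat counts outside [5, 50] are treated
as typing errors. Intermediate (non-integer) alleles such as 13.2 are
rejected by default; an opt-in flag drops such records instead, for
panels where a locus (often DYS458) segregates intermediate alleles.

Normalization applies the two standard Yfiler conventions: the
multicopy DYS385a/b pair is removed (the kit cannot assign alleles to
copies, so the locus is unusable for per-locus statistics), and
DYS389II is re-expressed as DYS389II − DYS389I because the II amplicon
physically contains the I repeat stretch. A record with
DYS389II ≤ DYS389I is biologically impossible and rejected. The table
carries a `normalized` flag and normalizing twice is an error, since
double subtraction would silently corrupt the data. Statistics that
assume the 15-locus panel refuse un-normalized input.

## Diversity statistics

Gene diversity follows Nei's unbiased estimator
`h_l = n(1 − Σ p_a²)/(n − 1)`; "average gene diversity" is read as the
across-locus mean of `h_l` (the across-locus SD is reported with it).
The alternative reading — heterozygosity of whole haplotypes — is a
separate function (`haplotype_gene_diversity`), so both are available.
`h_l` equals the probability that two draws *without* replacement
differ, which is the brute-force pair-counting oracle used in tests.

Vp is the across-locus mean of the unbiased (n−1) sample variance of
repeat counts, on complete haplotypes only; incomplete records are
excluded as a whole rather than locus-wise so every locus sees the
same sample. Unbiasedness matches the estimator-recovery identity
Var(repeat) = μT used in the dating calibration.

Carrier frequencies are reported as exact proportions plus an
integer-rounded percentage for display; the table itself cannot know
the survey denominator, so carrier counts are supplied separately.

## Rst and the permutation test

Rst treats repeat counts as a quantitative character. The default
statistic is the sums-of-squares ratio

    Rst = (SSD_total − SSD_within) / SSD_total,

with per-locus sums of squared deviations summed across loci before
forming the ratio, so more variable loci contribute proportionally.
This form is exactly 0 for identically composed samples and exactly 1
for fixed differences, but, like any R²-type ratio, has a positive
null expectation of roughly 1/(N−1). The alternative
`method="components"` uses mean-square-based unbiased variance
components (the AMOVA/Arlequin convention); it has null expectation 0
and can be slightly negative by sampling. The two orderings agree;
only fine-scale calibration differs. Negative values are reported as
computed but floored at 0 before MDS embedding, where a negative
distance has no geometric meaning.

Significance comes from reassigning individuals to the two groups with
group sizes preserved. The p-value uses the add-one correction
`p = (1 + #{Rst* ≥ Rst})/(1 + B)` so it can never be 0 — necessary
when comparing against a Bonferroni threshold (α/m with
m = k(k−1)/2). For N ≤ ~20 the full assignment distribution can be
enumerated exactly (`exact=True`); tests verify the Monte-Carlo path
against that enumeration and the enumeration against an independent
re-derivation. Permutations are vectorized across assignments, so
10,000 permutations per pair cost milliseconds. Each population pair
draws from an independently spawned seed stream, making the matrix
independent of pair evaluation order.

## Classical MDS

Torgerson scaling: double-center the squared distance matrix,
eigendecompose, keep the top-k positive-eigenvalue axes. Fit is
summarized by Kruskal stress-1 `√(Σ(d̂−d)²/Σd²)` and by the squared
Pearson correlation between input and embedded distances. An exactly
Euclidean input embeds with stress 0 and R² = 1 (tested); requesting
more axes than positive eigenvalues warns and truncates; an all-zero
matrix yields coincident points with stress 0. An optional SMACOF
(stress-majorization) polish, initialized at the classical solution,
is provided for qualitative comparison with iterative MDS programs.
Stress values printed by specific commercial MDS implementations are
configuration-dependent (metric vs ordinal, normalization of stress)
and are not reproduction targets for any principled reimplementation.

## Median-joining networks

The construction follows the Bandelt–Forster–Röhl algorithm. Weighted
distances `d(u,v) = Σ_l w_l |u_l − v_l|` use integer locus weights
proportional to inverse repeat variance on a 1–10 scale (the least
variable polymorphic locus gets 10; monomorphic loci, having no
signal, get the cap). The ε-relaxed minimum spanning network includes
a link iff its weight is within ε of the level at which its endpoints
join in the Kruskal filtration; at ε = 0 this is the union of all
minimum spanning trees, verified in tests against exhaustive
spanning-tree enumeration. For each node with two network neighbors
the per-locus median of the triple (unique for three integers) is a
candidate inferred haplotype; novel medians whose connection cost to
their triple is within ε of the minimum are added, and the loop
repeats to a fixed point. Median vectors left with degree ≤ 1 after
rebuilding are pruned iteratively, so surviving medians always have
degree ≥ 2. ε defaults to 0, the usual default of network software.

All iteration orders are lexicographic in the haplotype vectors, so
the network is a deterministic function of the input set (and
invariant under record order, which GUI network programs are not).
Edge lengths shown and used for group separation are always the
unweighted step counts Σ|Δ|; weights affect only link selection. One
subtlety, verified on small instances: a direct link present in the
observed-only spanning network can be superseded in the final network
by a chain of strictly cheaper links through median vectors, in which
case the path between those two haplotypes is longer than their direct
distance. This is inherent to median augmentation, not an artifact.

Group separation between two sets of populations is the minimum over
node pairs (one bearing each group) of the shortest-path step length —
0 when the groups share a haplotype. Exports are GraphML (re-readable
by the package) and DOT, with multiplicity, population composition and
median-vector status on nodes and step counts on edges.

## Founder-based dating

The founder defaults to the per-locus modal haplotype; ties go to the
allele minimizing total step distance to the sample, then to the
smaller repeat. Any root can be supplied instead (in simulations the
true founder is known and is what estimator-recovery tests use, so
they probe the statistic rather than founder inference).

- **rho**: mean total step distance from the root; age `ρ/Σμ`;
  `SD(ρ) = √(ρ/n)` under the star approximation (verified to track the
  replicate SD within a factor of 1.5).
- **weighted rho**: each locus dates the founder independently,
  `t_l = d̄_l/μ_l`, and the age is the unweighted across-locus mean of
  these per-locus ages. This up-weights divergence at slow loci — a
  mutation at a 0.0004/generation marker witnesses more time than one
  at a 0.006 marker. The statistic is reported on the rho scale as
  `ρ_w = T·L·μ̄`, which reduces exactly to ρ under equal rates. (The
  seemingly natural inverse-variance combination of the per-locus ages
  with weights ∝ μ_l collapses algebraically to plain rho dating and
  therefore cannot be what a "weighted" estimator means.)
- **ASD ("quadratic") dating**: `T = Σ_l ASD_l/Σ_l μ_l` with ASD the
  mean squared distance from the root. Under the symmetric single-step
  model the squared displacement has expectation exactly μT whatever
  the number of back mutations, so this estimator stays linear in time
  where rho saturates.

Rho's bias deserves a number: the per-locus displacement after
Poisson(μT) ±1 steps is Skellam-distributed, and E|D| < μT by the
multi-hit fraction — about 5% at μT = 0.1 and 16% at μT = 0.4. Over
replicates this deficit is many Monte-Carlo standard errors, so rho
dating should be interpreted as a lower bound at deep timescales; the
test suite asserts rho against the exact Skellam expectation (green)
and demonstrates that ASD's bias is far smaller where μT > 0.5.

SDs for the weighted and ASD ages come from a seeded nonparametric
bootstrap over individuals (default 1,000 resamples), since no simple
closed form covers them. Ages are reported at 25 and 30
years/generation by default, the conventional bracketing values for
male generation intervals; years = generations × generation time
identically, so the two columns differ by the factor 1.2.

## The SMM simulator

The simulator emulates 15-locus integer haplotype tables: per locus,
mutation counts on a lineage of length t are Poisson(μ_l t), each
mutation ±1 with probability ½. Star mode makes all n lineages
independent from the founder — the regime where founder dating is
unbiased by construction. Kingman mode draws an n-coalescent and drops
mutations on branches; by default the tree is rescaled so the root
depth equals the configured TMRCA exactly, separating "estimator
error" from "genealogy depth randomness". Split mode derives two
population founders from a common ancestor (split_time generations of
drift on each side) and evolves each population below its founder —
the calibration harness for Rst. Default founder is 20 repeats at
every locus, a typical mid-range Y-STR allele; outputs are clipped to
the validated [5, 50] range, an event of negligible probability at
realistic μT. All modes are bit-reproducible under a fixed seed and
emit tables that pass io validation unchanged.

The bundled rate set is **synthetic**: invented but realistic per-locus
values on the Yfiler-minus-DYS385 panel (0.0003–0.0063, total
≈ 0.034/haplotype/generation). Real dating must use a user-supplied,
provenance-labelled rate table; published rate databases are updated
over time, which is why rates are an input rather than a constant.

What the simulator does *not* emulate — and therefore what passing
tests do not establish about real data: population growth or
bottlenecks, migration between demes after a split, locus-specific
range constraints or multi-step mutations, genotyping error, and
non-random sampling of men within populations. Estimator recovery on
stars shows correctness of the statistics, not realism of the star
assumption for any particular population.

## Problem sizes and runtime

Calibration tests use 200 replicates per condition (n = 50 lineages,
15 loci, μ = 0.002) for estimator recovery, 500 null pairs at 199
permutations for type-I calibration, and exhaustive enumeration up to
8 individuals or 6 haplotypes — sizes at which Monte-Carlo error is
small relative to the asserted tolerances while the whole suite runs
in well under a minute for the statistical parts. Pairwise permutation
testing is the only super-linear cost in production use; 10,000
permutations across a 17-population design takes seconds.

## Known limitations

- Rho and weighted rho assume a star genealogy; on correlated
  genealogies (shared internal branches) they underestimate TMRCA.
  The Kingman mode exists precisely to quantify that regime.
- The modal-founder rule can differ from the true founder in small or
  deep samples, shrinking all three estimators; dating reports are
  conditional on the root choice, which is therefore recorded.
- The SSD-ratio Rst is positively biased near the null (~1/(N−1));
  use `method="components"` when the expectation matters more than the
  fixed endpoints.
- Classical MDS reproduces metric structure; printed stress values
  from other MDS programs are not comparable across configurations.
- The median-joining search enumerates neighbor triples; for panels
  with hundreds of distinct haplotypes the network remains computable
  but the quasi-median explosion inherent to the method can add many
  vectors at ε > 0. ε = 0 is the safe default.
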