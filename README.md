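# ystrpop

Population-genetic analysis of Y-chromosome short tandem repeat (Y-STR)
haplotypes: the statistical toolkit used to trace paternal lineages —
for example a Y haplogroup carried across an island dispersal — from
tables of integer repeat counts.

It is written for population geneticists and genetic genealogists who
have per-individual Y-STR profiles (e.g. 17-locus Yfiler panels) with
population labels, and who want, from a single normalized table:

- **diversity**: haplogroup carrier frequencies, Nei's average gene
  diversity, Vp (mean across-locus repeat variance), haplotype
  reiteration and cross-population sharing;
- **population structure**: pairwise Rst distances on repeat scores,
  permutation significance with Bonferroni correction, and classical
  multidimensional scaling of the distance matrix;
- **genealogy**: median-joining haplotype networks with loci weighted
  inversely to their repeat variance;
- **dating**: founder-based TMRCA estimates by the rho statistic,
  weighted rho, and second-moment (ASD, "quadratic") dating, reported
  at 25 and 30 years/generation;
- **calibration**: a stepwise-mutation-model (SMM) simulator on star or
  Kingman-coalescent genealogies, used throughout the test suite to
  validate every estimator.

## The statistics

With repeat counts `x_il` for individual `i` at locus `l`, root
(founder) haplotype `r`, and per-locus mutation rates `μ_l`:

- Nei gene diversity per locus: `h_l = n(1 − Σ_a p_a²)/(n − 1)` over
  allele frequencies `p_a`; the reported GD is the mean of `h_l` across
  the 15-locus panel.
- `Vp = mean_l Var(x_·l)` (unbiased variance, complete haplotypes only).
- `Rst = (SSD_total − SSD_within)/SSD_total`, per-locus sums of squared
  deviations summed across loci before the ratio; significance by
  permuting individuals between populations (group sizes preserved),
  `p = (1 + #{Rst* ≥ Rst})/(1 + B)`.
- `ρ = mean_i Σ_l |x_il − r_l|`, with `SD(ρ) = √(ρ/n)`;
  age `T = ρ / Σ_l μ_l` on a star genealogy.
- weighted rho: per-locus ages `t_l = mean_i|x_il − r_l| / μ_l`
  averaged across loci, so divergence at slow loci testifies to more
  time; reported as `ρ_w = T · L · μ̄` (equal rates reduce `ρ_w` to `ρ`).
- ASD dating: `T = Σ_l mean_i (x_il − r_l)² / Σ_l μ_l`; the second
  moment of a symmetric single-step walk grows linearly in time even
  with back mutations, which makes this estimator preferable at depths
  where `ρ` saturates.

Panel conventions for Yfiler data are applied on normalization:
DYS385a/b dropped (copies indistinguishable) and DYS389II stored as
DYS389II − DYS389I.

## Worked example

```python
from ystrpop import (SplitConfig, SimulationConfig, simulate_split,
                     diversity_summary, RstPermutation, date_population,
                     MedianJoiningNetwork, group_separation,
                     synthetic_rate_table)

cfg = SplitConfig(
    pop_a=SimulationConfig(n=20, tmrca=60, population_label="Island_A"),
    pop_b=SimulationConfig(n=20, tmrca=60, population_label="Island_B"),
    split_time=300.0, seed=11,
)
table = simulate_split(cfg)               # two diverged island samples
print(diversity_summary(table).round(4))

est = RstPermutation(n_permutations=10_000, random_state=0).fit(table)
print("Rst =", round(est.distances_.loc["Island_A", "Island_B"], 4),
      " p =", round(est.p_values_.loc["Island_A", "Island_B"], 5))

ages = date_population(table, synthetic_rate_table(), random_state=0)
net = MedianJoiningNetwork().fit(table)
```

prints

```
             n frequency  nei_gd  nei_gd_sd      vp  n_distinct_haplotypes  modal_share
population
Island_A    20      None  0.1765     0.1334  0.1046                     17         0.15
Island_B    20      None  0.2063     0.1387  0.1221                     17         0.10

Rst = 0.6395  p = 0.0001
```

Both islands are 20-man samples with modest internal diversity
(GD ≈ 0.18–0.21, Vp ≈ 0.10–0.12 repeat units²); 300 generations of
independent drift put 64% of the total repeat variance *between* the
islands, and no permutation of individuals reaches the observed Rst
(p = 1/10001). The dating report (here at 25 years/generation, rates
from the bundled synthetic table) recovers ages near the simulated
60-generation within-island depth:

```
population  n        method  statistic_value  generations   years  sd_years
  Island_A 20           rho             1.50        43.35 1083.82    197.88
  Island_A 20  weighted_rho             1.38        39.84  996.05    180.06
  Island_A 20 asd_quadratic             1.60        46.24 1156.07    183.02
  Island_B 20           rho             1.80        52.02 1300.58    216.76
  Island_B 20  weighted_rho             2.10        60.64 1516.07    307.40
  Island_B 20 asd_quadratic             1.90        54.91 1372.83    196.29
```

and the median-joining network summarizes the genealogy: 46 nodes
(12 inferred median vectors), 56 edges, with the two islands' nearest
haplotypes 7 mutational steps apart
(`group_separation(net.graph_, {"Island_A"}, {"Island_B"})`).

The same analyses run from the shell via the `ystrpop` command
(`simulate`, `diversity`, `rst`, `mds`, `network`, `tmrca`, and a
YAML-driven `pipeline` that writes all outputs plus a run manifest).

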