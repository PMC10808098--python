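"""Per-population frequency and diversity statistics.

Implements haplogroup carrier frequency, Nei's average gene diversity
(across-locus mean of unbiased per-locus heterozygosity, with the
whole-haplotype reading available separately), Vp (mean across-locus
repeat-count variance, an intra-haplogroup diversity measure), and
haplotype reiteration / cross-population sharing summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientSampleError, UndefinedStatisticError
from .io import HaplotypeTable, filter_complete

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiversitySummary:
    """One population's diversity panel (one row of the summary table)."""

    population: str
    n: int
    frequency: float | None
    nei_gd: float | None
    nei_gd_sd: float | None
    vp: float | None
    n_distinct_haplotypes: int
    modal_share: float


def haplogroup_frequency(carriers: int, total: int) -> tuple[float, int]:
    """Carrier proportion and its integer-percent display form.

    Returns ``(proportion, percent)`` where percent is rounded to the
    nearest integer (half away from zero), matching how frequencies are
    conventionally printed on maps.
    """
    if total <= 0:
        raise UndefinedStatisticError("frequency undefined for total = 0")
    if not 0 <= carriers <= total:
        raise UndefinedStatisticError(
            f"carriers must lie in [0, total]; got {carriers}/{total}"
        )
    proportion = carriers / total
    percent = int(np.floor(proportion * 100 + 0.5))
    return proportion, percent


def _per_locus_gene_diversity(column: pd.Series) -> float:
    """Unbiased Nei gene diversity h = n(1 − Σp²)/(n − 1) at one locus."""
    values = column.dropna()
    n = len(values)
    if n < 2:
        raise InsufficientSampleError("gene diversity needs n >= 2 typed samples")
    counts = values.value_counts().to_numpy(dtype=float)
    p = counts / n
    return n * (1.0 - float(np.sum(p**2))) / (n - 1)


def nei_average_gene_diversity(table: HaplotypeTable) -> tuple[float, float]:
    """Nei's average gene diversity over the 15-locus panel.

    Per locus l, h_l = n(1 − Σ_i p_i²)/(n − 1) over allele frequencies
    p_i; the statistic is the mean of h_l across loci and its standard
    deviation across loci (population SD over the fixed locus panel).
    """
    table.require_normalized("nei_average_gene_diversity")
    if len(table) < 2:
        raise InsufficientSampleError("gene diversity needs n >= 2")
    h = np.array(
        [_per_locus_gene_diversity(table.data[l]) for l in table.panel], dtype=float
    )
    return float(h.mean()), float(h.std())


def haplotype_gene_diversity(table: HaplotypeTable) -> float:
    """Whole-haplotype Nei diversity: n(1 − Σ q_k²)/(n − 1) over the
    frequencies q_k of distinct complete haplotypes.

    This is the alternative reading of "gene diversity based on Y-STR
    loci"; the per-locus average is the primary statistic.
    """
    complete = filter_complete(table)
    n = len(complete)
    if n < 2:
        raise InsufficientSampleError("haplotype diversity needs n >= 2 complete")
    counts = (
        complete.repeats().apply(tuple, axis=1).value_counts().to_numpy(dtype=float)
    )
    q = counts / n
    return n * (1.0 - float(np.sum(q**2))) / (n - 1)


def vp_mean_variance(table: HaplotypeTable) -> float:
    """Vp: mean across loci of the unbiased sample variance of repeat counts.

    Only complete haplotypes (all 15 loci present) enter; the filter is
    applied internally so incomplete records never bias the variances.
    """
    complete = filter_complete(table)
    if len(complete) < 2:
        raise InsufficientSampleError("Vp needs >= 2 complete haplotypes")
    X = complete.matrix().astype(float)
    return float(X.var(axis=0, ddof=1).mean())


def haplotype_sharing_summary(
    table: HaplotypeTable,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Haplotype reiteration within populations and sharing across them.

    Returns
    -------
    per_population : DataFrame
        One row per population: n complete, n distinct, n reiterated
        (multiplicity ≥ 2) and the modal haplotype's share.
    reiterated : DataFrame
        One row per (population, haplotype) with multiplicity ≥ 2.
    sharing : DataFrame
        Symmetric population × population matrix counting distinct
        haplotypes observed in both populations (diagonal = distinct
        haplotypes within the population). Empty off-diagonal for an
        all-singleton table.
    """
    table.require_normalized("haplotype_sharing_summary")
    complete = filter_complete(table)
    pops = complete.population_names
    haps = complete.repeats().apply(tuple, axis=1)
    by_pop = {p: haps[complete.populations == p] for p in pops}

    rows = []
    reiterated_rows = []
    for p in pops:
        counts = by_pop[p].value_counts()
        n = int(counts.sum())
        modal = int(counts.iloc[0]) if n else 0
        rows.append(
            {
                "population": p,
                "n": n,
                "n_distinct": int(len(counts)),
                "n_reiterated": int((counts >= 2).sum()),
                "modal_share": modal / n if n else 0.0,
            }
        )
        for hap, mult in counts[counts >= 2].items():
            reiterated_rows.append(
                {"population": p, "haplotype": hap, "multiplicity": int(mult)}
            )

    sharing = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    sets = {p: set(by_pop[p]) for p in pops}
    for i, a in enumerate(pops):
        sharing.loc[a, a] = len(sets[a])
        for b in pops[i + 1 :]:
            shared = len(sets[a] & sets[b])
            sharing.loc[a, b] = shared
            sharing.loc[b, a] = shared

    per_population = pd.DataFrame(rows).set_index("population")
    reiterated = pd.DataFrame(
        reiterated_rows, columns=["population", "haplotype", "multiplicity"]
    )
    return per_population, reiterated, sharing


def diversity_summary(
    table: HaplotypeTable,
    carriers: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-population diversity table (Supplementary-Table-4 shaped).

    Parameters
    ----------
    table : HaplotypeTable
        Normalized table of haplogroup carriers.
    carriers : dict, optional
        ``population -> (carriers, total_typed)`` counts for the
        haplogroup frequency column; populations absent from the dict get
        no frequency (the haplotype table alone cannot know the survey
        denominator).
    """
    table.require_normalized("diversity_summary")
    per_pop, _, _ = haplotype_sharing_summary(table)
    rows = []
    for pop in table.population_names:
        sub = table.for_population(pop)
        try:
            gd, gd_sd = nei_average_gene_diversity(sub)
        except InsufficientSampleError:
            gd = gd_sd = None
        try:
            vp = vp_mean_variance(sub)
        except InsufficientSampleError:
            vp = None
        freq = None
        if carriers and pop in carriers:
            freq, _ = haplogroup_frequency(*carriers[pop])
        stats = (
            per_pop.loc[pop]
            if pop in per_pop.index
            else pd.Series({"n_distinct": 0, "modal_share": 0.0})
        )
        rows.append(
            DiversitySummary(
                population=pop,
                n=len(sub),
                frequency=freq,
                nei_gd=gd,
                nei_gd_sd=gd_sd,
                vp=vp,
                n_distinct_haplotypes=int(stats["n_distinct"]),
                modal_share=float(stats["modal_share"]),
            )
        )
    frame = pd.DataFrame([r.__dict__ for r in rows]).set_index("population")
    return frame


def write_diversity_summary(frame: pd.DataFrame, path) -> None:
    """One TSV row per population mirroring the DiversitySummary fields."""
    frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g", encoding="utf-8")


__all__ = [
    "DiversitySummary",
    "haplogroup_frequency",
    "nei_average_gene_diversity",
    "haplotype_gene_diversity",
    "vp_mean_variance",
    "haplotype_sharing_summary",
    "diversity_summary",
    "write_diversity_summary",
]
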