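"""Founder-based TMRCA estimation from Y-STR haplotypes.

Three estimators, all measuring haplotype divergence from a founder
(root) haplotype under the symmetric single-step mutation model:

rho
    ρ = mean over individuals of the total absolute repeat difference
    from the root, Σ_l |x_il − root_l|. E[ρ] = T·Σ_l μ_l on a star
    genealogy, so T̂ = ρ/Σμ. SD(ρ) = sqrt(ρ/n) under the star
    approximation. At large T·μ per locus, multiple hits at one locus
    partially cancel, so ρ under-counts mutations and under-estimates T.

weighted rho
    Each locus yields its own age t_l = d̄_l/μ_l (d̄_l = mean founder
    distance at locus l); the age is the across-locus average
    T̂ = (1/L) Σ_l t_l, which up-weights distances observed at slow
    loci — a mutation at a slow marker testifies to more elapsed time.
    The statistic is reported as ρ_w = T̂·L·μ̄ = Σ_l d̄_l·(μ̄/μ_l), so
    equal rates reduce ρ_w to ρ exactly.

ASD ("quadratic") dating
    ASD_l = mean squared repeat difference from the root. Under a
    symmetric ±1 random walk the second moment grows linearly in time
    regardless of back mutations (E[D²] = μT exactly), so
    T̂ = Σ_l ASD_l / Σ_l μ_l is back-mutation robust — the property
    that makes second-moment ("quadratic") dating preferable at depths
    where rho saturates.

Ages are converted to years at user-chosen generation times
(conventionally 25 and 30 years/generation). SDs for the weighted and
ASD ages come from a seeded nonparametric bootstrap over individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import ValidationError
from .io import HaplotypeTable, MutationRateTable, filter_complete


@dataclass(frozen=True)
class FounderHaplotype:
    """Root haplotype used to measure divergence."""

    repeats: tuple[int, ...]
    panel: tuple[str, ...]
    selection_rule: str = "modal"

    def vector(self) -> np.ndarray:
        return np.asarray(self.repeats, dtype=np.int64)


@dataclass(frozen=True)
class AgeEstimate:
    """One (method, generation time) TMRCA estimate."""

    method: str
    statistic_value: float
    generations: float
    generation_time: float
    years: float
    sd_years: float | None = None
    sd_generations: float | None = None

    def __post_init__(self) -> None:
        if self.generation_time <= 0:
            raise ValidationError("generation time must be positive")


def modal_founder(table: HaplotypeTable) -> FounderHaplotype:
    """Per-locus modal haplotype with documented tie-breaking.

    Ties on the count are broken toward the allele minimizing the total
    step distance to all haplotypes at that locus, then toward the
    smaller repeat.
    """
    complete = filter_complete(table)
    if len(complete) == 0:
        raise ValidationError("modal founder needs >= 1 complete haplotype")
    X = complete.matrix()
    repeats = []
    for col in X.T:
        alleles, counts = np.unique(col, return_counts=True)
        best = alleles[counts == counts.max()]
        if len(best) > 1:
            totals = np.array([np.abs(col - a).sum() for a in best])
            best = best[totals == totals.min()]
        repeats.append(int(best.min()))
    return FounderHaplotype(
        repeats=tuple(repeats), panel=complete.panel, selection_rule="modal"
    )


def _distances(table: HaplotypeTable, root: FounderHaplotype) -> np.ndarray:
    complete = filter_complete(table)
    if len(complete) == 0:
        raise ValidationError("dating needs >= 1 complete haplotype")
    if tuple(complete.panel) != tuple(root.panel):
        raise ValidationError("founder panel does not match table panel")
    return np.abs(complete.matrix() - root.vector()[None, :])  # (n, L)


def rho_statistic(
    table: HaplotypeTable, root: FounderHaplotype
) -> tuple[float, float]:
    """ρ and its star-approximation SD sqrt(ρ/n)."""
    D = _distances(table, root)
    n = D.shape[0]
    if n == 1:
        warnings.warn("TMRCA is undefined for a single haplotype (n = 1)",
                      stacklevel=2)
    rho = float(D.sum(axis=1).mean())
    return rho, float(np.sqrt(rho / n))


def weighted_rho(
    table: HaplotypeTable, root: FounderHaplotype, rates: MutationRateTable
) -> dict:
    """Weighted rho: equal-weight average of per-locus ages.

    Returns a dict with ``rho_w``, ``age_generations`` and the
    ``per_locus_ages`` vector (ordered like the panel).
    """
    D = _distances(table, root)
    mu = rates.for_panel(root.panel)
    d_bar = D.mean(axis=0)  # per-locus mean founder distance
    per_locus_ages = d_bar / mu
    age = float(per_locus_ages.mean())
    L = len(mu)
    mu_bar = float(mu.mean())
    rho_w = age * L * mu_bar  # = Σ_l d̄_l (μ̄/μ_l); equals ρ when rates are equal
    return {
        "rho_w": float(rho_w),
        "age_generations": age,
        "per_locus_ages": per_locus_ages,
    }


def asd_quadratic_age(
    table: HaplotypeTable, root: FounderHaplotype, rates: MutationRateTable
) -> dict:
    """Second-moment (ASD) age: T = Σ_l ASD_l / Σ_l μ_l."""
    D = _distances(table, root)
    mu = rates.for_panel(root.panel)
    asd = (D.astype(float) ** 2).mean(axis=0)
    age = float(asd.sum() / mu.sum())
    return {"asd": float(asd.sum()), "age_generations": age, "per_locus_asd": asd}


def to_years(age_generations: float, generation_time: float) -> tuple[float, int]:
    """Age in years (exact product, plus integer-rounded display form)."""
    if generation_time <= 0:
        raise ValidationError("generation time must be positive")
    if age_generations < 0:
        raise ValidationError("age must be non-negative")
    years = age_generations * generation_time
    return years, int(round(years))


def _bootstrap_sd(
    D: np.ndarray,
    mu: np.ndarray,
    estimator: str,
    n_bootstrap: int,
    rng: np.random.Generator,
) -> float:
    """SD in generations of the weighted-rho or ASD age, resampling rows."""
    n = D.shape[0]
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    if estimator == "weighted_rho":
        d_bar = D[idx].mean(axis=1)  # (B, L)
        ages = (d_bar / mu).mean(axis=1)
    elif estimator == "asd":
        asd = (D[idx].astype(float) ** 2).mean(axis=1)
        ages = asd.sum(axis=1) / mu.sum()
    else:
        raise ValueError(estimator)
    return float(ages.std(ddof=1))


class FounderAgeEstimator(BaseEstimator):
    """All three founder-based TMRCA estimators on one sample.

    Parameters
    ----------
    rates : MutationRateTable or dict
        Per-locus per-generation mutation rates covering the panel.
    generation_times : tuple of float
        Years per generation at which ages are reported (25 and 30 are
        the conventional bracketing choices).
    founder : "modal" or sequence of int
        Root rule: the per-locus modal haplotype (default) or a
        user-supplied repeat vector.
    n_bootstrap : int
        Bootstrap resamples for the weighted/ASD age SDs.
    random_state : int or None
        Bootstrap seed.

    Attributes
    ----------
    founder_ : FounderHaplotype
    estimates_ : list of AgeEstimate
    report_ : DataFrame
        One row per (method, generation time).
    """

    def __init__(
        self,
        rates=None,
        generation_times=(25.0, 30.0),
        founder="modal",
        n_bootstrap: int = 1000,
        random_state: int | None = None,
    ):
        self.rates = rates
        self.generation_times = generation_times
        self.founder = founder
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def _resolve_rates(self) -> MutationRateTable:
        if isinstance(self.rates, MutationRateTable):
            return self.rates
        if isinstance(self.rates, dict):
            return MutationRateTable(rates=dict(self.rates), source_label="dict")
        raise ValidationError("rates (MutationRateTable or dict) are required")

    def fit(self, X, y=None):
        if not isinstance(X, HaplotypeTable):
            raise TypeError("FounderAgeEstimator.fit expects a HaplotypeTable")
        X.require_normalized("TMRCA dating")
        complete = filter_complete(X)
        rates = self._resolve_rates()

        if isinstance(self.founder, str) and self.founder == "modal":
            root = modal_founder(complete)
        else:
            root = FounderHaplotype(
                repeats=tuple(int(r) for r in self.founder),
                panel=complete.panel,
                selection_rule="user-supplied",
            )
        mu = rates.for_panel(root.panel)
        D = _distances(complete, root)
        n = D.shape[0]
        rng = np.random.default_rng(self.random_state)

        rho, rho_sd = rho_statistic(complete, root)
        rho_age = rho / mu.sum()
        rho_age_sd = rho_sd / mu.sum()

        wres = weighted_rho(complete, root, rates)
        ares = asd_quadratic_age(complete, root, rates)
        if n >= 2:
            w_sd = _bootstrap_sd(D, mu, "weighted_rho", self.n_bootstrap, rng)
            a_sd = _bootstrap_sd(D, mu, "asd", self.n_bootstrap, rng)
        else:
            w_sd = a_sd = None

        estimates = []
        for g in self.generation_times:
            for method, stat, age, sd in (
                ("rho", rho, rho_age, rho_age_sd),
                ("weighted_rho", wres["rho_w"], wres["age_generations"], w_sd),
                ("asd_quadratic", ares["asd"], ares["age_generations"], a_sd),
            ):
                years, _ = to_years(age, g)
                estimates.append(
                    AgeEstimate(
                        method=method,
                        statistic_value=stat,
                        generations=age,
                        generation_time=g,
                        years=years,
                        sd_years=None if sd is None else sd * g,
                        sd_generations=sd,
                    )
                )
        self.founder_ = root
        self.n_ = n
        self.estimates_ = estimates
        self.report_ = pd.DataFrame([e.__dict__ for e in estimates])
        return self


def date_population(
    table: HaplotypeTable,
    rates,
    generation_times=(25.0, 30.0),
    founder="modal",
    n_bootstrap: int = 1000,
    random_state: int | None = None,
) -> pd.DataFrame:
    """Per-population TMRCA report (one row per population × method ×
    generation time), Table-1 shaped."""
    table.require_normalized("date_population")
    frames = []
    streams = np.random.SeedSequence(random_state).spawn(
        len(table.population_names)
    )
    for pop, stream in zip(table.population_names, streams):
        sub = filter_complete(table.for_population(pop))
        if len(sub) == 0:
            warnings.warn(f"population {pop}: no complete haplotypes, skipped",
                          stacklevel=2)
            continue
        est = FounderAgeEstimator(
            rates=rates,
            generation_times=generation_times,
            founder=founder,
            n_bootstrap=n_bootstrap,
            random_state=int(stream.generate_state(1)[0] % (2**31)),
        ).fit(sub)
        frame = est.report_.copy()
        frame.insert(0, "population", pop)
        frame.insert(1, "n", est.n_)
        frames.append(frame)
    if not frames:
        raise ValidationError("no population could be dated")
    return pd.concat(frames, ignore_index=True)


def write_age_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g",
                  encoding="utf-8", na_rep="NA")


__all__ = [
    "FounderHaplotype",
    "AgeEstimate",
    "modal_founder",
    "rho_statistic",
    "weighted_rho",
    "asd_quadratic_age",
    "to_years",
    "FounderAgeEstimator",
    "date_population",
    "write_age_report",
]
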