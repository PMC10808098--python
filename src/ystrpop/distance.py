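"""Pairwise Rst distances, permutation significance, Bonferroni correction.

Rst is the microsatellite analog of Fst: repeat counts are treated as a
quantitative character and the among-population share of their variance
is the distance. The default convention follows the sums-of-squares
ratio

    Rst = (SSD_total − SSD_within) / SSD_total

with per-locus sums of squared deviations summed across the panel
before the ratio is formed, so loci with more variance contribute more.
A switchable ``method="components"`` uses unbiased AMOVA variance
components (mean-square based), which may be slightly negative by
sampling.

Significance is assessed by permuting individuals between the two
populations (group sizes preserved) and recomputing Rst; the p-value
carries the add-one correction p = (1 + #{Rst* ≥ Rst}) / (1 + B) so it
is never exactly 0 — necessary when comparing against a Bonferroni
threshold. For small samples the permutation distribution can be
enumerated exhaustively.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import InsufficientSampleError, UndefinedStatisticError
from .io import HaplotypeTable, filter_complete

_TIE_EPS = 1e-12  # float tolerance when counting permuted Rst >= observed


def _as_matrix(pop) -> np.ndarray:
    if isinstance(pop, HaplotypeTable):
        return filter_complete(pop).matrix().astype(float)
    X = np.asarray(pop, dtype=float)
    if X.ndim != 2:
        raise ValueError("population sample must be a 2-D (n, loci) array")
    return X


def _ssd_parts(X: np.ndarray, n_a: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-locus total SSD, pooled sums, squared-value sums for batch work."""
    N = X.shape[0]
    total_sum = X.sum(axis=0)
    sumsq = (X**2).sum(axis=0)
    ssd_total = sumsq - total_sum**2 / N
    return ssd_total, total_sum, sumsq


def _rst_from_assignment(
    X: np.ndarray, in_a: np.ndarray, n_a: int, method: str
) -> np.ndarray:
    """Rst for a batch of group assignments.

    ``in_a`` is a (B, N) 0/1 matrix selecting group A members; returns a
    length-B vector of Rst values.
    """
    N, _ = X.shape
    n_b = N - n_a
    ssd_total, total_sum, sumsq = _ssd_parts(X, n_a)
    sum_a = in_a @ X  # (B, L)
    sum_b = total_sum[None, :] - sum_a
    ssd_within = sumsq[None, :] - sum_a**2 / n_a - sum_b**2 / n_b  # (B, L)
    if method == "ssd":
        tot = ssd_total.sum()
        if tot <= 0:
            raise UndefinedStatisticError(
                "Rst undefined: zero total repeat variance across the panel"
            )
        return 1.0 - ssd_within.sum(axis=1) / tot
    if method == "components":
        ssd_among = ssd_total[None, :] - ssd_within
        ms_within = ssd_within / (N - 2)
        ms_among = ssd_among / 1.0  # k - 1 = 1 for a pair
        n_prime = N - (n_a**2 + n_b**2) / N  # = (N - Σn²/N)/(k-1)
        sigma_a = (ms_among - ms_within) / n_prime
        denom = (sigma_a + ms_within).sum(axis=1)
        if np.any(np.abs(denom) <= 0):
            raise UndefinedStatisticError(
                "Rst undefined: zero total variance components"
            )
        return sigma_a.sum(axis=1) / denom
    raise ValueError(f"unknown Rst method {method!r}")


def rst_pair(pop_a, pop_b, method: str = "ssd") -> float:
    """Rst between two population samples of repeat counts.

    Parameters
    ----------
    pop_a, pop_b : HaplotypeTable or (n, L) array
        Normalized, complete haplotypes; each n ≥ 2.
    method : {"ssd", "components"}
        Sums-of-squares ratio (default) or unbiased AMOVA variance
        components (Arlequin-like; may be slightly negative).
    """
    A, B = _as_matrix(pop_a), _as_matrix(pop_b)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise InsufficientSampleError("Rst needs n >= 2 complete haplotypes per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("populations typed on different panels")
    X = np.vstack([A, B])
    in_a = np.zeros((1, X.shape[0]))
    in_a[0, : A.shape[0]] = 1.0
    return float(_rst_from_assignment(X, in_a, A.shape[0], method)[0])


def permutation_test(
    pop_a,
    pop_b,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
    method: str = "ssd",
    exact: bool = False,
) -> tuple[float, float]:
    """Permutation p-value for Rst between two populations.

    Individuals are reassigned to the two groups with group sizes
    preserved. Returns ``(rst_observed, p_value)`` with the add-one
    correction p = (1 + #{Rst* ≥ Rst}) / (1 + B), reproducible under a
    fixed seed. With ``exact=True`` all C(N, n_a) assignments are
    enumerated instead and p = #{Rst* ≥ Rst} / M (the observed
    assignment is among them, so p > 0).
    """
    A, B = _as_matrix(pop_a), _as_matrix(pop_b)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise InsufficientSampleError("Rst needs n >= 2 complete haplotypes per group")
    X = np.vstack([A, B])
    N, n_a = X.shape[0], A.shape[0]
    observed_assign = np.zeros((1, N))
    observed_assign[0, :n_a] = 1.0
    observed = float(_rst_from_assignment(X, observed_assign, n_a, method)[0])

    if exact:
        M = comb(N, n_a)
        if M > 200_000:
            raise ValueError(
                f"exact enumeration of {M} assignments is infeasible; "
                "use Monte Carlo permutations"
            )
        assign = np.zeros((M, N))
        for row, idx in enumerate(combinations(range(N), n_a)):
            assign[row, list(idx)] = 1.0
        perm = _rst_from_assignment(X, assign, n_a, method)
        p = float(np.mean(perm >= observed - _TIE_EPS))
        return observed, p

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    order = np.argsort(rng.random((n_permutations, N)), axis=1)[:, :n_a]
    assign = np.zeros((n_permutations, N))
    np.put_along_axis(assign, order, 1.0, axis=1)
    perm = _rst_from_assignment(X, assign, n_a, method)
    n_ge = int(np.sum(perm >= observed - _TIE_EPS))
    p = (1 + n_ge) / (1 + n_permutations)
    return observed, p


def n_pairwise_comparisons(k: int) -> int:
    """Number of unordered population pairs, k(k−1)/2."""
    if k < 1:
        raise ValueError("need at least one population")
    return k * (k - 1) // 2


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Per-test threshold α/m, with its 4-decimal display rounding.

    Returns ``(exact, display)``; e.g. α = 0.05 with m = 136 pairwise
    comparisons gives exact 0.05/136 ≈ 0.000368 which prints as 0.0004.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    exact = alpha / m
    return exact, round(exact, 4)


class RstPermutation(BaseEstimator):
    """Pairwise population Rst matrix with permutation p-values.

    scikit-learn-style estimator: ``fit(X, y)`` takes an (n_samples,
    n_loci) repeat-count matrix and per-sample population labels (or a
    normalized :class:`HaplotypeTable`, in which case ``y`` defaults to
    its population column).

    Parameters
    ----------
    n_permutations : int
        Permutations per pair (10,000 replicates the conventional
        setting for this test).
    alpha : float
        Family-wise significance level for the Bonferroni flagging.
    method : {"ssd", "components"}
        Rst convention; see :func:`rst_pair`.
    random_state : int or None
        Seed; each pair draws from an independently spawned stream so
        results do not depend on pair evaluation order.

    Attributes
    ----------
    labels_ : list of str
        Population names in first-appearance order.
    distances_ : DataFrame
        Symmetric Rst matrix, zero diagonal.
    p_values_ : DataFrame
        Symmetric permutation p-values (diagonal 1).
    threshold_ : float
        Bonferroni per-test threshold α/m.
    significant_ : DataFrame
        Boolean matrix, p below the Bonferroni threshold.
    n_comparisons_ : int
        k(k−1)/2 for the k populations compared.
    """

    def __init__(
        self,
        n_permutations: int = 10_000,
        alpha: float = 0.05,
        method: str = "ssd",
        random_state: int | None = None,
    ):
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.method = method
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, HaplotypeTable):
            table = filter_complete(X)
            y = table.populations.to_numpy()
            X = table.matrix().astype(float)
        else:
            X = np.asarray(X, dtype=float)
            if y is None:
                raise ValueError("population labels y are required for array input")
            y = np.asarray(y)
        if X.shape[0] != len(y):
            raise ValueError("X and y have mismatched lengths")

        labels = list(dict.fromkeys(y))
        if len(labels) < 2:
            raise InsufficientSampleError("need >= 2 populations for Rst")
        groups = {lab: X[y == lab] for lab in labels}

        k = len(labels)
        dist = pd.DataFrame(0.0, index=labels, columns=labels)
        pval = pd.DataFrame(1.0, index=labels, columns=labels)
        streams = np.random.SeedSequence(self.random_state).spawn(k * (k - 1) // 2)
        pair_idx = 0
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                rng = np.random.default_rng(streams[pair_idx])
                pair_idx += 1
                rst, p = permutation_test(
                    groups[a],
                    groups[b],
                    n_permutations=self.n_permutations,
                    seed=rng,
                    method=self.method,
                )
                dist.loc[a, b] = dist.loc[b, a] = rst
                pval.loc[a, b] = pval.loc[b, a] = p

        self.labels_ = labels
        self.distances_ = dist
        self.p_values_ = pval
        self.n_comparisons_ = n_pairwise_comparisons(k)
        self.threshold_, self.threshold_display_ = bonferroni_threshold(
            self.alpha, self.n_comparisons_
        )
        self.significant_ = (pval < self.threshold_) & ~np.eye(k, dtype=bool)
        return self


__all__ = [
    "rst_pair",
    "permutation_test",
    "bonferroni_threshold",
    "n_pairwise_comparisons",
    "RstPermutation",
]
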