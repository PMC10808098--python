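"""Classical (Torgerson) multidimensional scaling of distance matrices.

Double-centers the squared distance matrix, eigendecomposes, and keeps
the top-k positive-eigenvalue axes. Fit quality is reported as Kruskal
stress-1 between input and embedded distances and as the squared
Pearson correlation between the two distance sets. An optional
stress-majorization (SMACOF) refinement is available for qualitative
comparison with iterative MDS programs.

Negative input entries (possible for variance-component Rst estimates)
are floored at 0 before embedding: a genetic distance below zero is a
sampling artifact, not a geometry.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.manifold import smacof


def _condensed(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(D, k=1)
    return D[iu]


def kruskal_stress(d_input: np.ndarray, d_embedded: np.ndarray) -> float:
    """Kruskal stress-1: sqrt(Σ(d̂ − d)² / Σ d²) over unordered pairs."""
    num = float(np.sum((d_embedded - d_input) ** 2))
    den = float(np.sum(d_input**2))
    if den == 0:
        return 0.0 if num == 0 else float("inf")
    return float(np.sqrt(num / den))


def distance_r_squared(d_input: np.ndarray, d_embedded: np.ndarray) -> float:
    """Squared Pearson correlation between input and embedded distances.

    Degenerate (zero-variance) inputs yield 1.0 when the embedding
    reproduces them exactly and 0.0 otherwise.
    """
    if np.std(d_input) == 0 or np.std(d_embedded) == 0:
        return 1.0 if np.allclose(d_input, d_embedded) else 0.0
    r = float(np.corrcoef(d_input, d_embedded)[0, 1])
    return r * r


class ClassicalMDS(BaseEstimator):
    """Torgerson classical scaling.

    Parameters
    ----------
    n_components : int
        Requested embedding dimension; if fewer positive eigenvalues
        exist, fewer axes are returned with a warning.
    refine : bool
        If True, polish the classical solution with SMACOF stress
        majorization (metric), initialized at the classical coordinates.
    clip_negative : bool
        Floor negative input distances at 0 before embedding (default).

    Attributes
    ----------
    embedding_ : ndarray of shape (n, k)
        Coordinates, centered at the origin.
    eigenvalues_ : ndarray
        All eigenvalues of the double-centered matrix, descending.
    stress_ : float
        Kruskal stress-1 of the returned embedding.
    r_squared_ : float
        Squared correlation between input and embedded distances.
    labels_ : list or None
        Row labels when the input was a DataFrame.
    """

    def __init__(
        self,
        n_components: int = 2,
        refine: bool = False,
        clip_negative: bool = True,
    ):
        self.n_components = n_components
        self.refine = refine
        self.clip_negative = clip_negative

    def fit(self, D, y=None):
        labels = None
        if isinstance(D, pd.DataFrame):
            labels = list(D.index)
            D = D.to_numpy(dtype=float)
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.clip_negative:
            D = np.maximum(D, 0.0)

        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        eigval, eigvec = np.linalg.eigh(B)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]

        tol = max(1e-10, 1e-10 * max(abs(eigval[0]), 1.0))
        n_pos = int(np.sum(eigval > tol))
        k = min(self.n_components, max(n_pos, 1))
        if n_pos < self.n_components:
            warnings.warn(
                f"only {n_pos} positive eigenvalues; returning {k} axes "
                f"instead of {self.n_components}",
                stacklevel=2,
            )
        if n_pos == 0:
            coords = np.zeros((n, k))
        else:
            coords = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))

        if self.refine and n_pos > 0:
            coords, _ = smacof(
                D,
                metric=True,
                n_components=k,
                init=coords,
                n_init=1,
                random_state=0,
                normalized_stress=False,
            )
        coords = coords - coords.mean(axis=0, keepdims=True)

        d_in = _condensed(D)
        d_emb = _condensed(
            np.sqrt(
                np.maximum(
                    np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1),
                    0.0,
                )
            )
        )
        self.embedding_ = coords
        self.eigenvalues_ = eigval
        self.n_positive_eigenvalues_ = n_pos
        self.stress_ = kruskal_stress(d_in, d_emb)
        self.r_squared_ = distance_r_squared(d_in, d_emb)
        self.labels_ = labels
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).embedding_

    def coordinates_frame(self) -> pd.DataFrame:
        """Embedding as a DataFrame with Dim1..Dimk columns."""
        k = self.embedding_.shape[1]
        idx = self.labels_ if self.labels_ is not None else range(len(self.embedding_))
        return pd.DataFrame(
            self.embedding_, index=idx, columns=[f"Dim{i + 1}" for i in range(k)]
        )


def classical_mds(D, n_components: int = 2, refine: bool = False) -> ClassicalMDS:
    """Fit :class:`ClassicalMDS` and return the fitted estimator."""
    return ClassicalMDS(n_components=n_components, refine=refine).fit(D)


__all__ = ["ClassicalMDS", "classical_mds", "kruskal_stress", "distance_r_squared"]
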