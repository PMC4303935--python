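"""The four distance metrics on expression space.

A sample's whole-transcriptome profile is a point in the space whose axes
are genes.  Four distances between two profiles X and Y are provided:

* Euclidean            d² = Σ_i (x_i − y_i)²
* scaled               d² = Σ_i (x_i − y_i)² / M_i²,  M_i² = ⟨x_i²⟩ over
                       the dataset (per-gene root-mean-square scale)
* Pearson (cosine)     d  = 1 − X·Y / (|X||Y|) = 1 − cos ∠(X, Y)
* Mahalanobis          d² = (X−Y)ᵀ S⁻¹ (X−Y),  S the dataset covariance

The "Pearson" distance here is the uncentered cosine dissimilarity, not
the mean-centered correlation: for non-negative expression values it lies
in [0, 1] and is invariant under arbitrary positive rescaling of either
profile, which is what makes it robust to per-sample normalization.  A
mean-centered variant is available behind ``centered=True``.

With far more genes than samples the covariance matrix is singular; the
Mahalanobis form then uses the Moore-Penrose pseudo-inverse (singular
values below 1e-10 of the largest truncated) or, on request, a ridge
inverse (S + λI)⁻¹.  All computations are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, ConfigurationError, DegenerateDataError

logger = logging.getLogger(__name__)

#: relative singular-value cutoff for the pseudo-inverse
PINV_RCOND = 1e-10

METRICS = ("euclidean", "scaled", "pearson", "mahalanobis")


@dataclass(frozen=True)
class ExpressionVector:
    """One sample's expression profile with aligned gene identifiers."""

    values: np.ndarray
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 1:
            raise AlignmentError("expression vector must be 1-D and non-empty")
        if len(self.gene_ids) != self.values.size:
            raise AlignmentError(
                f"{self.values.size} values vs {len(self.gene_ids)} gene ids"
            )


def _as_aligned_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Coerce two inputs to aligned float arrays.

    Accepts plain sequences/arrays (assumed aligned) or ExpressionVector
    pairs, whose gene ids are checked for identical order.
    """
    if isinstance(x, ExpressionVector) and isinstance(y, ExpressionVector):
        if x.gene_ids != y.gene_ids:
            bad = [a for a, b in zip(x.gene_ids, y.gene_ids) if a != b]
            extra = set(x.gene_ids) ^ set(y.gene_ids)
            raise AlignmentError(
                f"gene identifiers differ between vectors: "
                f"{sorted(extra)[:10] or bad[:10]}"
            )
        return x.values, y.values
    xa = np.asarray(getattr(x, "values", x), dtype=float)
    ya = np.asarray(getattr(y, "values", y), dtype=float)
    if xa.shape != ya.shape:
        raise AlignmentError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if xa.ndim != 1 or xa.size < 1:
        raise AlignmentError("expression vectors must be 1-D and non-empty")
    return xa, ya


# ---------------------------------------------------------------------------
# dataset-level quantities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneScale:
    """Per-gene mean squared expression ⟨x_i²⟩ over a dataset.

    Used to normalize the Euclidean sum gene-by-gene so that highly
    expressed genes do not dominate.  A zero entry means the gene is zero
    in every sample and must be removed before scaled distances.
    """

    m_squared: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "m_squared",
                           np.asarray(self.m_squared, dtype=float))
        if (self.m_squared < 0).any():
            raise DegenerateDataError("negative mean-square gene scale")

    @property
    def zero_genes(self) -> np.ndarray:
        return np.flatnonzero(self.m_squared == 0.0)


def gene_scale(dataset: np.ndarray | Sequence) -> GeneScale:
    """Per-gene mean of squared expression over all samples.

    ``dataset`` is a genes x samples array, or a sequence of aligned
    expression vectors (one per sample).
    """
    X = _dataset_to_array(dataset)
    return GeneScale(np.mean(X ** 2, axis=1))


def _dataset_to_array(dataset) -> np.ndarray:
    """Genes x samples float array from array or sequence-of-vectors input."""
    if isinstance(dataset, np.ndarray):
        X = np.asarray(dataset, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    else:
        vecs = [np.asarray(getattr(v, "values", v), dtype=float) for v in dataset]
        if not vecs:
            raise DegenerateDataError("empty dataset")
        if len({v.size for v in vecs}) != 1:
            raise AlignmentError("dataset vectors have differing lengths")
        X = np.column_stack(vecs)
    if X.size == 0:
        raise DegenerateDataError("empty dataset")
    return X


@dataclass
class CovarianceMatrix:
    """Gene-gene covariance of a dataset, with its inversion policy.

    ``centered`` records whether gene means were subtracted (the standard
    sample covariance, divisor n) or the literal second-moment matrix
    ⟨x_i x_j⟩ was kept.  ``inverse_mode`` is ``"pseudo"`` (Moore-Penrose,
    small singular values truncated) or ``"ridge"`` ((S + λI)⁻¹ with
    ``ridge_lambda``); ``inverse_used`` records what was actually applied
    once an inverse is computed.
    """

    s: np.ndarray
    centered: bool = True
    inverse_mode: str = "pseudo"
    ridge_lambda: Optional[float] = None
    inverse_used: Optional[str] = None
    _inv: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.ndim != 2 or self.s.shape[0] != self.s.shape[1]:
            raise AlignmentError("covariance matrix must be square")
        if not np.allclose(self.s, self.s.T, atol=1e-8 * max(1.0, np.abs(self.s).max())):
            raise DegenerateDataError("covariance matrix is not symmetric")
        if self.inverse_mode not in ("exact", "pseudo", "ridge"):
            raise ConfigurationError(f"unknown inverse_mode {self.inverse_mode!r}")
        if self.inverse_mode == "ridge" and not (self.ridge_lambda and self.ridge_lambda > 0):
            raise ConfigurationError("ridge inverse requires a positive ridge_lambda")

    @property
    def n_genes(self) -> int:
        return self.s.shape[0]

    def inverse(self) -> np.ndarray:
        """The (pseudo/ridge/exact) inverse, computed once and cached."""
        if self._inv is None:
            if self.inverse_mode == "ridge":
                self._inv = np.linalg.inv(
                    self.s + self.ridge_lambda * np.eye(self.n_genes)
                )
                self.inverse_used = f"ridge(lambda={self.ridge_lambda:g})"
            elif self.inverse_mode == "exact":
                self._inv = np.linalg.inv(self.s)
                self.inverse_used = "exact"
            else:
                self._inv = np.linalg.pinv(self.s, rcond=PINV_RCOND, hermitian=True)
                rank = np.linalg.matrix_rank(self.s, hermitian=True)
                self.inverse_used = "pseudo-inverse"
                if rank < self.n_genes:
                    logger.info(
                        "singular covariance (rank %d < %d genes); "
                        "Moore-Penrose pseudo-inverse used", rank, self.n_genes,
                    )
        return self._inv


def covariance_matrix(
    dataset, centered: bool = True,
    inverse_mode: str = "pseudo", ridge_lambda: Optional[float] = None,
) -> CovarianceMatrix:
    """Gene-gene covariance averaged over all samples in the dataset.

    ``centered=True`` (default) subtracts per-gene means (sample
    covariance with divisor n); ``centered=False`` keeps the raw
    second-moment matrix ⟨x_i x_j⟩.
    """
    X = _dataset_to_array(dataset)
    n = X.shape[1]
    if centered:
        if n < 2:
            raise DegenerateDataError(
                "centered covariance needs at least 2 samples"
            )
        Xc = X - X.mean(axis=1, keepdims=True)
    else:
        Xc = X
    s = (Xc @ Xc.T) / n
    return CovarianceMatrix(s, centered=centered, inverse_mode=inverse_mode,
                            ridge_lambda=ridge_lambda)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def euclidean_distance(x, y) -> float:
    """Plain Euclidean distance sqrt(Σ (x_i − y_i)²)."""
    xa, ya = _as_aligned_arrays(x, y)
    return float(np.linalg.norm(xa - ya))


def scaled_distance(x, y, scale: GeneScale) -> float:
    """Euclidean distance with each gene normalized by its RMS scale M_i.

    Requires every M_i² > 0: genes that are zero across the whole dataset
    carry no information and must be removed first.
    """
    xa, ya = _as_aligned_arrays(x, y)
    m2 = scale.m_squared
    if m2.size != xa.size:
        raise AlignmentError(
            f"scale has {m2.size} genes, vectors have {xa.size}"
        )
    if (m2 == 0).any():
        raise DegenerateDataError(
            f"zero per-gene scale at indices {list(scale.zero_genes[:10])}; "
            "remove genes that are zero in every sample before using the "
            "scaled distance"
        )
    # same reduction as the Euclidean path so unit scales reduce exactly
    return float(np.linalg.norm((xa - ya) / np.sqrt(m2)))


def pearson_distance(x, y, centered: bool = False) -> float:
    """Correlation (cosine) distance 1 − cos ∠(X, Y).

    The default is the uncentered form: invariant to positive rescaling
    of either vector, and guaranteed to lie in [0, 1] when all components
    are non-negative.  ``centered=True`` subtracts each vector's mean
    first (classical Pearson correlation distance); the [0, 1] range then
    no longer holds.
    """
    xa, ya = _as_aligned_arrays(x, y)
    if centered:
        xa = xa - xa.mean()
        ya = ya - ya.mean()
    nx = np.linalg.norm(xa)
    ny = np.linalg.norm(ya)
    if nx == 0.0 or ny == 0.0:
        raise DegenerateDataError(
            "cosine distance undefined for a zero-norm vector"
        )
    cos = float(np.dot(xa, ya) / (nx * ny))
    # clamp tiny floating overshoot so identical vectors give exactly 0
    cos = min(1.0, max(-1.0, cos))
    return 1.0 - cos


def mahalanobis_distance(x, y, cov: CovarianceMatrix) -> float:
    """Covariance-weighted distance sqrt((X−Y)ᵀ S⁻¹ (X−Y)).

    Accounts for gene-gene correlations in the dataset.  When S is
    singular (genes outnumber samples) the inverse follows
    ``cov.inverse_mode``; the mode actually used is recorded on ``cov``.
    """
    xa, ya = _as_aligned_arrays(x, y)
    if cov.n_genes != xa.size:
        raise AlignmentError(
            f"covariance over {cov.n_genes} genes, vectors have {xa.size}"
        )
    d = xa - ya
    q = float(d @ cov.inverse() @ d)
    if q < -1e-8 * max(1.0, float(d @ d)):
        raise DegenerateDataError(
            f"negative Mahalanobis quadratic form ({q:.3e}); "
            "covariance is not positive semi-definite"
        )
    return float(np.sqrt(max(q, 0.0)))
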