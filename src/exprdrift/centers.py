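"""Subset centroids, per-sample distance profiles and nearest-center calls.

Each labeled subset of samples (normal tissue, tumor, metastasis, ...)
gets a center: the arithmetic mean of its members' expression vectors.
Every sample is then summarized by its distance profile (r_1, ..., r_k) —
the distance to each center under one metric — and may be classified to
the nearest center.

The centroid of the "normal" subset plays a special role: the distance
from it measures how far a sample has drifted from the homeostatic state,
and is the quantity related to tumor grade and survival downstream.

Centroids are computed on whatever scale the matrix is in; no internal
re-normalization is applied (scale differences between cohorts are
absorbed by the cosine distance's scale invariance).

By default a sample contributes to its own group's centroid ("naive"
mode).  This slightly biases within-group distances downward, so for any
accuracy claim the leave-one-out profiles — each sample scored against
centroids recomputed without it — are recommended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .distances import (
    METRICS,
    CovarianceMatrix,
    GeneScale,
    covariance_matrix,
    gene_scale,
)
from .errors import AlignmentError, ConfigurationError, DegenerateDataError
from .io import FLOAT_FORMAT, ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class CenterSet:
    """One centroid per group, plus the metric they will be scored under.

    ``centroids`` is a genes x labels DataFrame whose index fixes the gene
    order all profiles must share.  ``scale`` (per-gene RMS) is fitted for
    the scaled metric and ``cov`` for the Mahalanobis metric, both over
    the full training matrix.
    """

    labels: list[str]
    centroids: pd.DataFrame
    metric: str = "pearson"
    cov: Optional[CovarianceMatrix] = None
    scale: Optional[GeneScale] = None
    group_sizes: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ConfigurationError(
                f"unknown metric {self.metric!r}; expected one of {METRICS}"
            )
        if list(self.centroids.columns) != self.labels:
            raise AlignmentError("centroid columns must match labels")
        if self.metric == "mahalanobis" and self.cov is None:
            raise ConfigurationError("mahalanobis metric requires a covariance")
        if self.metric == "scaled" and self.scale is None:
            raise ConfigurationError("scaled metric requires a gene scale")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.centroids.index)

    def centroid(self, label: str) -> np.ndarray:
        return self.centroids[label].to_numpy(dtype=float)


def compute_centers(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    metric: str = "pearson",
    centered_cov: bool = True,
    inverse_mode: str = "pseudo",
    ridge_lambda: Optional[float] = None,
) -> CenterSet:
    """Arithmetic-mean centroid of each group, plus metric auxiliaries.

    Group labels come from the metadata; labels are ordered
    lexicographically for determinism.  Every labeled sample must be
    present in the matrix.  A single-sample group is allowed (its centroid
    is that sample) but logged, since it cannot express within-group
    spread.
    """
    missing = [s for s in metadata.sample_ids if s not in matrix.values.columns]
    if missing:
        raise AlignmentError(
            f"metadata samples absent from the expression matrix: {missing[:10]}"
        )
    labels = metadata.labels
    if not labels:
        raise DegenerateDataError("no groups in metadata")

    work = matrix
    scale = None
    if metric == "scaled":
        scale_full = gene_scale(matrix.values[metadata.sample_ids].to_numpy())
        zero = scale_full.zero_genes
        if zero.size:
            keep = [g for i, g in enumerate(matrix.gene_ids) if i not in set(zero)]
            logger.warning(
                "dropping %d gene(s) with zero scale before scaled distances",
                zero.size,
            )
            if not keep:
                raise DegenerateDataError("all genes have zero scale")
            work = matrix.subset_genes(keep)
        scale = gene_scale(work.values[metadata.sample_ids].to_numpy())

    cov = None
    if metric == "mahalanobis":
        cov = covariance_matrix(
            work.values[metadata.sample_ids].to_numpy(),
            centered=centered_cov,
            inverse_mode=inverse_mode,
            ridge_lambda=ridge_lambda,
        )

    cent = {}
    sizes = {}
    for g in labels:
        members = metadata.members(g)
        if not members:
            raise DegenerateDataError(f"group {g!r} has no samples")
        if len(members) == 1:
            logger.warning("group %r has a single sample; centroid equals it", g)
        cent[g] = work.values[members].mean(axis=1)
        sizes[g] = len(members)
    centroids = pd.DataFrame(cent, columns=labels)
    return CenterSet(labels=labels, centroids=centroids, metric=metric,
                     cov=cov, scale=scale, group_sizes=sizes)


# ---------------------------------------------------------------------------
# distance profiles
# ---------------------------------------------------------------------------

def _profile_block(X: np.ndarray, C: np.ndarray, centers: CenterSet) -> np.ndarray:
    """Distances from each column of X (samples) to each column of C (centers)."""
    if centers.metric == "euclidean":
        return cdist(X.T, C.T, metric="euclidean")
    if centers.metric == "pearson":
        norms = np.linalg.norm(X, axis=0)
        cnorms = np.linalg.norm(C, axis=0)
        if (norms == 0).any() or (cnorms == 0).any():
            raise DegenerateDataError(
                "cosine distance undefined for zero-norm sample or centroid"
            )
        d = cdist(X.T, C.T, metric="cosine")
        return np.clip(d, 0.0, 2.0)
    if centers.metric == "scaled":
        w = 1.0 / np.sqrt(centers.scale.m_squared)
        return cdist((X * w[:, None]).T, (C * w[:, None]).T, metric="euclidean")
    if centers.metric == "mahalanobis":
        VI = centers.cov.inverse()
        D = X.T[:, None, :] - C.T[None, :, :]
        q = np.einsum("abi,ij,abj->ab", D, VI, D)
        return np.sqrt(np.maximum(q, 0.0))
    raise ConfigurationError(f"unknown metric {centers.metric!r}")


def distance_profiles(matrix: ExpressionMatrix, centers: CenterSet) -> pd.DataFrame:
    """Distance from every sample to every center.

    Returns a DataFrame indexed by sample id with one column per center
    label, ordered as ``centers.labels``.
    """
    if list(matrix.gene_ids) != centers.gene_ids:
        common = set(matrix.gene_ids) & set(centers.gene_ids)
        if len(common) == len(centers.gene_ids) and len(common) == matrix.n_genes:
            matrix = matrix.subset_genes(centers.gene_ids)  # reorder only
        elif set(centers.gene_ids) <= set(matrix.gene_ids):
            matrix = matrix.subset_genes(centers.gene_ids)
        else:
            raise AlignmentError(
                "matrix gene set does not cover the centers' gene set; "
                f"missing {sorted(set(centers.gene_ids) - set(matrix.gene_ids))[:10]}"
            )
    R = _profile_block(matrix.X, centers.centroids.to_numpy(dtype=float), centers)
    return pd.DataFrame(R, index=pd.Index(matrix.sample_ids, name="sample_id"),
                        columns=centers.labels)


def leave_one_out_profiles(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    metric: str = "pearson",
    **center_kwargs,
) -> pd.DataFrame:
    """Distance profiles with each sample excluded from its own centroid.

    The distance to a sample's own group uses the group mean recomputed
    without it (mean-update identity); distances to other groups use the
    full centroids.  Every group needs at least 2 samples.  Dataset-level
    auxiliaries (gene scale, covariance) stay fitted on the full matrix.
    """
    small = [g for g in metadata.labels if len(metadata.members(g)) < 2]
    if small:
        raise DegenerateDataError(
            f"leave-one-out needs >= 2 samples per group; too small: {small}"
        )
    centers = compute_centers(matrix, metadata, metric=metric, **center_kwargs)
    profiles = distance_profiles(matrix, centers)

    work = matrix if list(matrix.gene_ids) == centers.gene_ids \
        else matrix.subset_genes(centers.gene_ids)
    for g in centers.labels:
        members = metadata.members(g)
        n_g = len(members)
        c_full = centers.centroid(g)
        Xg = work.values[members].to_numpy(dtype=float)
        # mean-update: centroid of the group without sample j
        C_loo = (n_g * c_full[:, None] - Xg) / (n_g - 1)
        for j, sid in enumerate(members):
            block = _profile_block(Xg[:, [j]], C_loo[:, [j]], centers)
            profiles.loc[sid, g] = block[0, 0]
    return profiles


# ---------------------------------------------------------------------------
# nearest-center classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Assignment:
    """Nearest-center call for one sample."""

    label: str
    margin: float
    tie: bool


def nearest_center(r, labels: Optional[list[str]] = None) -> Assignment:
    """Label of the smallest distance plus the margin to the runner-up.

    Exact ties are broken by lexicographic label order and flagged.
    """
    if isinstance(r, pd.Series):
        labels = list(r.index) if labels is None else labels
        r = r.to_numpy(dtype=float)
    r = np.asarray(r, dtype=float)
    if labels is None or len(labels) != r.size or r.size == 0:
        raise ConfigurationError("nearest_center needs one label per distance")
    order = sorted(range(r.size), key=lambda i: (r[i], labels[i]))
    best = order[0]
    if r.size == 1:
        return Assignment(labels[best], np.inf, False)
    second = order[1]
    tie = bool(r[best] == r[second])
    return Assignment(labels[best], float(r[second] - r[best]), tie)


def classify(profiles: pd.DataFrame) -> pd.DataFrame:
    """Nearest-center assignment for every row of a profile table."""
    rows = [nearest_center(profiles.loc[s]) for s in profiles.index]
    return pd.DataFrame(
        {
            "assigned_label": [a.label for a in rows],
            "margin": [a.margin for a in rows],
            "tie": [a.tie for a in rows],
        },
        index=profiles.index,
    )


def classification_accuracy(profiles: pd.DataFrame, metadata: SampleMetadata) -> float:
    """Fraction of samples whose nearest center matches their true group."""
    calls = classify(profiles)
    truth = metadata.groups.reindex(profiles.index)
    return float((calls["assigned_label"] == truth).mean())


def write_profiles(
    profiles: pd.DataFrame,
    metadata: SampleMetadata,
    path: str | Path,
) -> None:
    """Tab-separated profile table: sample, group, r_<label>..., call, margin."""
    calls = classify(profiles)
    out = pd.DataFrame(index=profiles.index)
    out["group"] = metadata.groups.reindex(profiles.index)
    for lab in profiles.columns:
        out[f"r_{lab}"] = profiles[lab]
    out["assigned_label"] = calls["assigned_label"]
    out["margin"] = calls["margin"]
    out["tie"] = calls["tie"].astype(int)
    out.to_csv(Path(path), sep="\t", index_label="sample_id",
               float_format=FLOAT_FORMAT)
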