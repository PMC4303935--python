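"""Unit and property tests for the four distance metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exprdrift.distances import (
    CovarianceMatrix,
    ExpressionVector,
    GeneScale,
    covariance_matrix,
    euclidean_distance,
    gene_scale,
    mahalanobis_distance,
    pearson_distance,
    scaled_distance,
)
from exprdrift.errors import AlignmentError, DegenerateDataError


# --------------------------------------------------------------------------
# independent naive-loop oracles
# --------------------------------------------------------------------------

def naive_euclidean(x, y):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))


def naive_scaled(x, y, m2):
    return math.sqrt(sum((a - b) ** 2 / m for a, b, m in zip(x, y, m2)))


def naive_pearson(x, y):
    dot = sum(a * b for a, b in zip(x, y))
    nx = math.sqrt(sum(a * a for a in x))
    ny = math.sqrt(sum(b * b for b in y))
    return 1.0 - dot / (nx * ny)


def naive_mahalanobis(x, y, s_inv):
    d = [a - b for a, b in zip(x, y)]
    q = 0.0
    for i in range(len(d)):
        for j in range(len(d)):
            q += d[i] * s_inv[i][j] * d[j]
    return math.sqrt(q)


# --------------------------------------------------------------------------
# worked examples
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((0, 0), (3, 4), 5.0),                  # 3-4-5 triangle
        ((2.5, 7, 0.1), (2.5, 7, 0.1), 0.0),
        ((1, 2, 3), (4, 6, 3), 5.0),            # sqrt(9+16+0)
    ],
)
def test_euclidean_examples(x, y, expected):
    assert euclidean_distance(x, y) == pytest.approx(expected, abs=1e-12)


def test_gene_scale_examples():
    np.testing.assert_allclose(
        gene_scale([(1, 0), (3, 4)]).m_squared, [5.0, 8.0])
    c = 3.7
    np.testing.assert_allclose(
        gene_scale([(c, c, c)]).m_squared, [c**2] * 3)
    zeros = gene_scale([(0.0, 0.0), (0.0, 0.0)])
    np.testing.assert_array_equal(zeros.m_squared, [0.0, 0.0])
    np.testing.assert_array_equal(zeros.zero_genes, [0, 1])


def test_gene_scale_empty_dataset_errors():
    with pytest.raises(DegenerateDataError):
        gene_scale([])


def test_scaled_distance_examples():
    scale = GeneScale([5.0, 8.0])
    assert scaled_distance((1, 0), (3, 4), scale) == pytest.approx(
        math.sqrt(4 / 5 + 16 / 8), abs=1e-12)
    assert scaled_distance((1, 0), (1, 0), scale) == 0.0
    # unit scales: reduces exactly to Euclidean
    unit = GeneScale([1.0, 1.0])
    assert scaled_distance((1, 2), (0, 0), unit) == euclidean_distance((1, 2), (0, 0))


def test_scaled_distance_rejects_zero_scale():
    with pytest.raises(DegenerateDataError, match="zero"):
        scaled_distance((1, 2), (3, 4), GeneScale([1.0, 0.0]))


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((5, 5, 5), (1, 1, 1), 0.0),            # collinear
        ((1, 0), (0, 1), 1.0),                  # orthogonal
        ((1, 1), (1, 0), 1 - 1 / math.sqrt(2)),  # 45 degrees
    ],
)
def test_pearson_examples(x, y, expected):
    assert pearson_distance(x, y) == pytest.approx(expected, abs=1e-12)


def test_pearson_zero_vector_errors():
    with pytest.raises(DegenerateDataError):
        pearson_distance((0, 0), (1, 1))


def test_pearson_centered_variant_differs():
    # mean-centered correlation distance of collinear-but-offset vectors
    x, y = (1.0, 2.0, 3.0), (10.0, 20.0, 30.0)
    assert pearson_distance(x, y) == pytest.approx(0.0, abs=1e-12)
    # centered form equals 1 - corr; here corr = 1 as well
    assert pearson_distance(x, y, centered=True) == pytest.approx(0.0, abs=1e-12)
    # anti-correlated after centering but similar in direction
    a, b = (10.0, 11.0, 12.0), (12.0, 11.0, 10.0)
    assert pearson_distance(a, b) < 0.02
    assert pearson_distance(a, b, centered=True) == pytest.approx(2.0, abs=1e-9)


def test_covariance_examples():
    dataset = [(1.0, 0.0), (-1.0, 0.0)]
    for centered in (True, False):  # means are zero, both modes agree
        cov = covariance_matrix(dataset, centered=centered)
        np.testing.assert_allclose(cov.s, [[1.0, 0.0], [0.0, 0.0]], atol=1e-15)
        assert cov.centered is centered
    same = covariance_matrix([(2.0, 3.0)] * 4, centered=True)
    np.testing.assert_allclose(same.s, np.zeros((2, 2)), atol=1e-15)


def test_covariance_centered_needs_two_samples():
    with pytest.raises(DegenerateDataError):
        covariance_matrix([(1.0, 2.0)], centered=True)
    # uncentered second-moment matrix is fine with one sample
    cov = covariance_matrix([(1.0, 2.0)], centered=False)
    np.testing.assert_allclose(cov.s, [[1.0, 2.0], [2.0, 4.0]])


def test_mahalanobis_examples():
    ident = CovarianceMatrix(np.eye(2))
    assert mahalanobis_distance((0, 0), (3, 4), ident) == pytest.approx(5.0, abs=1e-9)
    diag = CovarianceMatrix(np.diag([4.0, 1.0]))
    assert mahalanobis_distance((2, 0), (0, 0), diag) == pytest.approx(1.0, abs=1e-12)
    assert mahalanobis_distance((1, 2), (1, 2), diag) == 0.0


def test_mahalanobis_singular_uses_pseudo_inverse():
    # rank-1 covariance: distance only measured along the informative axis
    cov = CovarianceMatrix(np.array([[1.0, 0.0], [0.0, 0.0]]))
    d = mahalanobis_distance((1.0, 5.0), (0.0, 0.0), cov)
    assert d == pytest.approx(1.0, abs=1e-9)
    assert cov.inverse_used == "pseudo-inverse"


def test_mahalanobis_ridge_mode():
    cov = CovarianceMatrix(np.zeros((2, 2)), inverse_mode="ridge", ridge_lambda=4.0)
    d = mahalanobis_distance((2.0, 0.0), (0.0, 0.0), cov)
    assert d == pytest.approx(1.0, abs=1e-12)
    assert cov.inverse_used == "ridge(lambda=4)"


def test_mahalanobis_misaligned_covariance_errors():
    with pytest.raises(AlignmentError):
        mahalanobis_distance((1, 2, 3), (0, 0, 0), CovarianceMatrix(np.eye(2)))


def test_expression_vector_alignment_error_names_genes():
    x = ExpressionVector([1.0, 2.0], ("gA", "gB"))
    y = ExpressionVector([1.0, 2.0], ("gA", "gC"))
    with pytest.raises(AlignmentError, match="gB|gC"):
        euclidean_distance(x, y)
    with pytest.raises(AlignmentError):
        euclidean_distance((1, 2), (1, 2, 3))


# --------------------------------------------------------------------------
# metric properties
# --------------------------------------------------------------------------

vec = st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=5, max_size=5)


@settings(max_examples=100, derandomize=True)
@given(vec, vec)
def test_symmetry_and_identity(xs, ys):
    x, y = np.array(xs), np.array(ys)
    scale = GeneScale(np.ones(5) * 2.0)
    cov = CovarianceMatrix(np.diag([1.0, 2.0, 3.0, 4.0, 5.0]))
    for d in (
        euclidean_distance,
        lambda a, b: scaled_distance(a, b, scale),
        pearson_distance,
        lambda a, b: mahalanobis_distance(a, b, cov),
    ):
        assert d(x, x) == pytest.approx(0.0, abs=1e-12)
        assert d(x, y) == pytest.approx(d(y, x), rel=1e-12, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(vec, vec, vec)
def test_triangle_inequality(xs, ys, zs):
    x, y, z = (np.array(v) for v in (xs, ys, zs))
    scale = GeneScale(np.full(5, 3.0))
    cov = CovarianceMatrix(np.diag([0.5, 1.0, 2.0, 4.0, 8.0]))
    for d in (
        euclidean_distance,
        lambda a, b: scaled_distance(a, b, scale),
        lambda a, b: mahalanobis_distance(a, b, cov),
    ):
        assert d(x, z) <= d(x, y) + d(y, z) + 1e-9 * (1 + d(x, y) + d(y, z))


@settings(max_examples=100, derandomize=True)
@given(vec, vec, st.floats(min_value=1e-3, max_value=1e3))
def test_pearson_range_and_scale_invariance(xs, ys, c):
    x, y = np.array(xs), np.array(ys)
    d = pearson_distance(x, y)
    assert 0.0 <= d <= 1.0
    assert pearson_distance(c * x, y) == pytest.approx(d, abs=1e-12)
    assert pearson_distance(x, c * y) == pytest.approx(d, abs=1e-12)


def test_oracle_equivalence_on_random_vectors(rng):
    """All four metrics agree with naive-loop reimplementations to 1e-12."""
    for _ in range(100):
        x = rng.uniform(0.1, 10.0, size=5)
        y = rng.uniform(0.1, 10.0, size=5)
        data = rng.uniform(0.1, 10.0, size=(5, 8))
        scale = gene_scale(data)
        cov = covariance_matrix(data, centered=True)
        s_inv = cov.inverse()
        assert euclidean_distance(x, y) == pytest.approx(
            naive_euclidean(x, y), abs=1e-12)
        assert scaled_distance(x, y, scale) == pytest.approx(
            naive_scaled(x, y, scale.m_squared), abs=1e-12)
        assert pearson_distance(x, y) == pytest.approx(
            naive_pearson(x, y), abs=1e-12)
        assert mahalanobis_distance(x, y, cov) == pytest.approx(
            naive_mahalanobis(x, y, s_inv.tolist()), rel=1e-12, abs=1e-12)


def test_mahalanobis_identity_covariance_matches_euclidean(rng):
    cov = CovarianceMatrix(np.eye(7))
    for _ in range(20):
        x, y = rng.normal(size=7), rng.normal(size=7)
        assert mahalanobis_distance(x, y, cov) == pytest.approx(
            euclidean_distance(x, y), abs=1e-9)
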