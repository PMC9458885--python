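"""The ten pairwise distance measures used to compare varieties.

All measures operate on nonnegative 0-1-coded feature vectors (dosages or
trait-level indicators) and are oriented as distances: similarity-type
measures (jaccard, dice, cosine, harmonic_mean, pearson) are returned as
1 - similarity so that 0 always means "identical" and larger means
"further apart".

Degenerate inputs follow a continuity convention: for the similarity-type
measures two all-zero vectors are at distance 0 and an all-zero vector is
at distance 1 from any nonzero one; for the correlation measure a pair
with a constant member is at distance 1 unless both are identical
constants (distance 0).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import DistanceMatrix

#: The ten measures of the metric screen, lowercase registry names.
TEN_METRICS = (
    "euclidean",
    "manhattan",
    "gower",
    "canberra",
    "harmonic_mean",
    "jaccard",
    "squared_euclidean",
    "pearson",
    "cosine",
    "dice",
)

#: Divergence offered as an alternative reading of the "pearson" measure
#: (chi-square divergence); symmetrized when used in matrix form.
ALT_METRICS = ("pearson_chi2",)


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape or x.size < 1:
        raise ValueError("inputs must be equal-length 1-d vectors (length >= 1)")
    return x, y


def pair_distance(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    """Distance between two feature vectors under the named measure.

    This is the scalar reference implementation of every formula; the
    matrix builder is vectorized separately and tested against it.
    """
    x, y = _check_pair(x, y)
    d = x.size
    if metric == "euclidean":
        return float(np.sqrt(np.sum((x - y) ** 2)))
    if metric == "squared_euclidean":
        return float(np.sum((x - y) ** 2))
    if metric == "manhattan":
        return float(np.sum(np.abs(x - y)))
    if metric == "gower":
        # range term omitted: features are already on the 0-1 scale
        return float(np.sum(np.abs(x - y)) / d)
    if metric == "canberra":
        num = np.abs(x - y)
        den = x + y
        terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        return float(terms.sum())
    if metric == "jaccard":
        xy = float(x @ y)
        den = float(x @ x + y @ y) - xy
        if den == 0.0:  # both all-zero
            return 0.0
        return 1.0 - xy / den
    if metric == "dice":
        den = float(x @ x + y @ y)
        if den == 0.0:
            return 0.0
        return float(np.sum((x - y) ** 2)) / den
    if metric == "cosine":
        nx = float(np.sqrt(x @ x))
        ny = float(np.sqrt(y @ y))
        if nx == 0.0 and ny == 0.0:
            return 0.0
        if nx == 0.0 or ny == 0.0:
            return 1.0
        return 1.0 - float(x @ y) / (nx * ny)
    if metric == "harmonic_mean":
        sx = float(x.sum())
        sy = float(y.sum())
        if sx == 0.0 and sy == 0.0:
            return 0.0
        if sx == 0.0 or sy == 0.0:
            return 1.0
        num = x * y
        den = x + y
        hm = np.divide(num, den, out=np.zeros_like(num), where=den > 0).sum()
        return 1.0 - 2.0 * float(hm) / np.sqrt(sx * sy)
    if metric == "pearson":
        cx = x - x.mean()
        cy = y - y.mean()
        nx = float(np.sqrt(cx @ cx))
        ny = float(np.sqrt(cy @ cy))
        if nx == 0.0 or ny == 0.0:
            return 0.0 if np.array_equal(x, y) else 1.0
        return 1.0 - float(cx @ cy) / (nx * ny)
    if metric == "pearson_chi2":
        num = (x - y) ** 2
        terms = np.divide(num, y, out=np.zeros_like(num), where=y > 0)
        return float(terms.sum())
    raise KeyError(f"unknown metric {metric!r}")


def _pairwise_harmonic_sum(m: np.ndarray, chunk: int = 16) -> np.ndarray:
    """S[i, j] = sum_k m[i,k] m[j,k] / (m[i,k] + m[j,k]), 0/0 terms -> 0."""
    n = m.shape[0]
    out = np.zeros((n, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        a = m[start:stop, None, :]  # (c, 1, d)
        b = m[None, :, :]  # (1, n, d)
        num = a * b
        den = a + b
        terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        out[start:stop] = terms.sum(axis=2)
    return out


def distance_matrix(
    m: np.ndarray,
    metric: str,
    variety_ids: list[str] | None = None,
    source: str = "",
) -> DistanceMatrix:
    """All-pairs distance matrix of a varieties x features grid.

    The input must be imputed (no NaN).  Results equal applying
    :func:`pair_distance` to every row pair; the heavy metrics are
    vectorized for panels with thousands of features.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("feature matrix must be 2-dimensional")
    if np.isnan(m).any():
        raise ValueError("feature matrix contains missing values; impute first")
    n, d = m.shape
    if variety_ids is None:
        variety_ids = [f"V{i + 1}" for i in range(n)]

    if n == 1:
        values = np.zeros((1, 1))
        return DistanceMatrix(values, list(variety_ids), metric, source)

    if metric == "euclidean":
        values = squareform(pdist(m, "euclidean"))
    elif metric == "squared_euclidean":
        values = squareform(pdist(m, "sqeuclidean"))
    elif metric == "manhattan":
        values = squareform(pdist(m, "cityblock"))
    elif metric == "gower":
        values = squareform(pdist(m, "cityblock")) / d
    elif metric == "canberra":
        values = squareform(pdist(m, "canberra"))
    elif metric in ("jaccard", "dice", "cosine", "pearson"):
        values = _gram_based(m, metric)
    elif metric == "harmonic_mean":
        s = m.sum(axis=1)
        hm = _pairwise_harmonic_sum(m)
        root = np.sqrt(np.outer(s, s))
        with np.errstate(invalid="ignore", divide="ignore"):
            values = 1.0 - 2.0 * hm / root
        zero = s == 0
        values[zero[:, None] ^ zero[None, :]] = 1.0
        values[zero[:, None] & zero[None, :]] = 0.0
    elif metric == "pearson_chi2":
        # asymmetric divergence: use the symmetrized average
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dij = pair_distance(m[i], m[j], "pearson_chi2")
                dji = pair_distance(m[j], m[i], "pearson_chi2")
                values[i, j] = values[j, i] = (dij + dji) / 2.0
    else:
        raise KeyError(f"unknown metric {metric!r}")

    values = np.maximum(values, 0.0)  # clip float noise
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return DistanceMatrix(values, list(variety_ids), metric, source)


def _gram_based(m: np.ndarray, metric: str) -> np.ndarray:
    n = m.shape[0]
    if metric == "pearson":
        c = m - m.mean(axis=1, keepdims=True)
    else:
        c = m
    gram = c @ c.T
    sq = np.diag(gram).copy()
    if metric == "jaccard":
        den = sq[:, None] + sq[None, :] - gram
        with np.errstate(invalid="ignore", divide="ignore"):
            values = 1.0 - gram / den
        values[den == 0] = 0.0  # both all-zero
        return values
    if metric == "dice":
        den = sq[:, None] + sq[None, :]
        num = sq[:, None] + sq[None, :] - 2.0 * gram  # squared euclidean
        with np.errstate(invalid="ignore", divide="ignore"):
            values = num / den
        values[den == 0] = 0.0
        return values
    # cosine and pearson: 1 - gram / (|x||y|), with degenerate-norm rules
    norms = np.sqrt(sq)
    den = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = 1.0 - gram / den
    zero = norms == 0
    if zero.any():
        one_zero = zero[:, None] ^ zero[None, :]
        both_zero = zero[:, None] & zero[None, :]
        values[one_zero] = 1.0
        if metric == "pearson":
            # identical constants -> 0, different constants -> 1
            eq = np.ones((n, n), dtype=bool)
            zi = np.flatnonzero(zero)
            for a in zi:
                for b in zi:
                    eq[a, b] = np.array_equal(m[a], m[b])
            values[both_zero] = np.where(eq[both_zero], 0.0, 1.0)
        else:
            values[both_zero] = 0.0
    return values


def molecular_distance(
    g_values: np.ndarray,
    variety_ids: list[str],
    metric: str = "jaccard",
) -> DistanceMatrix:
    """Distance matrix on the imputed SNP dosage matrix."""
    return distance_matrix(g_values, metric, variety_ids, source="molecular")


def phenotypic_distance(
    indicator_values: np.ndarray,
    variety_ids: list[str],
    metric: str = "jaccard",
) -> DistanceMatrix:
    """Distance matrix on the binary trait-level indicator matrix."""
    return distance_matrix(
        indicator_values, metric, variety_ids, source="phenotypic"
    )
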