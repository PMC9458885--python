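"""Correlation between molecular and phenotypic distance matrices.

The central statistic is the product-moment correlation of the two
lower-triangle vectors (a Mantel-type correlation).  Because the
N(N-1)/2 pairwise distances are not independent observations, the
significance of r is assessed by a Mantel permutation test: one matrix's
varieties are relabelled jointly in rows and columns and r recomputed.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    DistanceCorrelationResult,
    DistanceMatrix,
    GenotypeMatrix,
    PhenotypeIndicatorMatrix,
    SubsampleCurve,
    TraitTable,
)
from .distances import TEN_METRICS, distance_matrix


def lower_triangle(dm: DistanceMatrix) -> np.ndarray:
    """Row-major lower-triangle vector of a distance matrix (length N(N-1)/2)."""
    if dm.n < 2:
        raise ValueError("need at least 2 varieties")
    i, j = np.tril_indices(dm.n, k=-1)
    return dm.values[i, j]


def _pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    if den == 0:
        return np.nan
    return float((a @ b) / den)


def distance_correlation(
    dm_mol: DistanceMatrix,
    dm_phe: DistanceMatrix,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> DistanceCorrelationResult:
    """Mantel-style correlation between two distance matrices.

    ``p`` is the one-sided permutation p-value
    ``(1 + #{r_perm >= r_obs}) / (1 + n_perm)``; pass ``n_perm=0`` to skip
    the test (p reported as 1).
    """
    if dm_mol.variety_ids != dm_phe.variety_ids:
        raise ValueError("distance matrices are over different variety sets")
    a = lower_triangle(dm_mol)
    b = lower_triangle(dm_phe)
    r_obs = _pearson_r(a, b)
    n_pairs = a.size
    if n_perm <= 0:
        return DistanceCorrelationResult(
            metric=dm_mol.metric, r=r_obs, p=1.0, n_pairs=n_pairs
        )
    rng = np.random.default_rng(rng)
    n = dm_mol.n
    i, j = np.tril_indices(n, k=-1)
    count = 0
    values = dm_phe.values
    for _ in range(n_perm):
        perm = rng.permutation(n)
        b_perm = values[np.ix_(perm, perm)][i, j]
        if _pearson_r(a, b_perm) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return DistanceCorrelationResult(
        metric=dm_mol.metric, r=r_obs, p=p, n_pairs=n_pairs
    )


def metric_screen(
    geno_values: np.ndarray,
    pheno: PhenotypeIndicatorMatrix,
    variety_ids: list[str],
    metrics: tuple[str, ...] = TEN_METRICS,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> list[DistanceCorrelationResult]:
    """Apply each measure to both sides and rank by the correlation.

    Returns one result per metric, sorted by descending r (ties broken
    by metric name).  The same measure is always used on the molecular
    and the phenotypic side.
    """
    rng = np.random.default_rng(rng)
    results = []
    for metric in metrics:
        dm_mol = distance_matrix(
            geno_values, metric, variety_ids, source="molecular"
        )
        dm_phe = distance_matrix(
            pheno.values, metric, variety_ids, source="phenotypic"
        )
        results.append(distance_correlation(dm_mol, dm_phe, n_perm, rng))
    return sorted(results, key=lambda res: (-res.r, res.metric))


def subsample_curve(
    geno_values: np.ndarray,
    pheno: PhenotypeIndicatorMatrix,
    variety_ids: list[str],
    axis: str,
    sizes: list[int],
    reps: int,
    metric: str,
    seed: int,
) -> SubsampleCurve:
    """Correlation as SNP- or trait-subset size grows (ceiling-effect curve).

    For each size, ``reps`` subsets are drawn without replacement and the
    subset-side distance matrix is correlated against the full other-side
    matrix.  On the trait axis whole traits are kept or dropped: a
    trait's indicator block is never split.
    """
    if axis not in ("snps", "traits"):
        raise ValueError("axis must be 'snps' or 'traits'")
    if sorted(sizes) != list(sizes) or len(set(sizes)) != len(sizes):
        raise ValueError("sizes must be strictly increasing")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    traits = pheno.trait_names
    total = geno_values.shape[1] if axis == "snps" else len(traits)
    if sizes[-1] > total:
        raise ValueError(f"largest size {sizes[-1]} exceeds {total} available")

    if axis == "snps":
        fixed = distance_matrix(
            pheno.values, metric, variety_ids, source="phenotypic"
        )
    else:
        fixed = distance_matrix(
            geno_values, metric, variety_ids, source="molecular"
        )

    rng = np.random.default_rng(seed)
    r_values = np.empty((len(sizes), reps))
    for si, size in enumerate(sizes):
        for rep in range(reps):
            pick = rng.choice(total, size=size, replace=False)
            if axis == "snps":
                sub = distance_matrix(
                    geno_values[:, pick], metric, variety_ids, "molecular"
                )
            else:
                chosen = [traits[k] for k in sorted(pick)]
                block = pheno.subset_traits(chosen)
                sub = distance_matrix(
                    block.values, metric, variety_ids, "phenotypic"
                )
            r_values[si, rep] = distance_correlation(sub, fixed, n_perm=0).r
    return SubsampleCurve(axis=axis, sizes=list(sizes), r_values=r_values, seed=seed)


def trait_correlation_matrix(
    t: TraitTable,
    display_cut: float = 0.35,
    method: str = "pearson",
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise correlations of grade-code columns, with a display mask.

    Grade codes are treated as numeric scores; correlations are computed
    pairwise-complete over missing values.  Returns ``(corr, mask)``
    where ``mask[i, j]`` is True when |r| >= display_cut (the value worth
    displaying).  An undefined correlation (constant column on the
    common support) is recorded as nan and masked out.
    """
    if t.n_traits < 2:
        raise ValueError("need at least 2 traits")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    codes = t.codes
    k = t.n_traits
    corr = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            both = ~np.isnan(codes[:, a]) & ~np.isnan(codes[:, b])
            x, y = codes[both, a], codes[both, b]
            if x.size < 2:
                r = np.nan
            else:
                if method == "spearman":
                    from scipy.stats import rankdata

                    x, y = rankdata(x), rankdata(y)
                r = _pearson_r(x, y)
            corr[a, b] = corr[b, a] = r
    with np.errstate(invalid="ignore"):
        mask = np.abs(corr) >= display_cut
    mask &= ~np.isnan(corr)
    return corr, mask


def genotype_feature_matrix(g: GenotypeMatrix) -> np.ndarray:
    """The molecular feature grid (imputed dosages) for distance work."""
    if g.has_missing():
        raise ValueError("genotypes contain missing calls; impute first")
    return g.values
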