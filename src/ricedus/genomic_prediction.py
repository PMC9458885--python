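"""Ridge-regression BLUP of grade-coded traits from genome-wide SNPs.

Model: y = mu + X alpha + e with alpha ~ N(0, sigma_u^2 I) and
e ~ N(0, sigma_e^2 I), so y ~ N(mu 1, sigma_u^2 K + sigma_e^2 I) with
K = Xc Xc' (Xc column-centered).  The variance components are estimated
by REML, profiled down to a one-dimensional search over the shrinkage
ratio lambda = sigma_e^2 / sigma_u^2 using the spectral decomposition of
the centered marker cross-product matrix — the standard ridge-BLUP
computation for n << p marker panels.

Ordinal grade codes are treated as numeric responses, and prediction
accuracy is the correlation between predicted and observed codes in a
held-out test set, averaged over repeated random train/test splits.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .containers import (
    DistanceCorrelationResult,
    GenotypeMatrix,
    MixedModelFit,
    PhenotypeIndicatorMatrix,
    PredictionResult,
    TraitTable,
)
from .distances import distance_matrix
from .matrix_correlation import distance_correlation

#: Search interval for log(lambda) in the REML optimization.
LOG_LAMBDA_BOUNDS = (-10.0, 10.0)


def mixed_solve(y: np.ndarray, X: np.ndarray) -> MixedModelFit:
    """REML fit of the ridge-regression BLUP model y = mu + X alpha + e.

    X columns are mean-centered internally so that mu is the population
    mean; predictions for new varieties apply the same centering.  A
    zero-variance response yields a degenerate fit (alpha = 0,
    mu = mean(y)) rather than an error.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("rows of X must match length of y")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in y or X; impute/drop first")
    col_means = X.mean(axis=0)
    Xc = X - col_means

    if np.allclose(y, y[0]):
        return MixedModelFit(
            mu=float(y.mean()),
            alpha=np.zeros(X.shape[1]),
            var_u=0.0,
            var_e=0.0,
            degenerate=True,
            column_means=col_means,
        )

    K = Xc @ Xc.T
    # Project out the intercept: eigen-decompose S (K + offset I) S where
    # S = I - J/n.  The offset keeps the retained spectrum strictly
    # positive so the single S-nullspace eigenvalue (exactly 0) can be
    # dropped reliably.
    offset = np.sqrt(n)
    ones = np.ones(n)
    A = K + offset * np.eye(n)
    A = A - np.outer(ones, ones @ A) / n
    A = A - np.outer(A @ ones, ones) / n
    theta_all, U_all = np.linalg.eigh(A)
    order = np.argsort(theta_all)[::-1]
    theta = theta_all[order][: n - 1] - offset
    theta = np.maximum(theta, 0.0)  # clip eigen noise
    U = U_all[:, order][:, : n - 1]
    eta = U.T @ y
    eta2 = eta**2

    def neg_restricted_loglik(log_lam: float) -> float:
        lam = np.exp(log_lam)
        denom = theta + lam
        return float(
            (n - 1) * np.log(eta2 @ (1.0 / denom)) + np.log(denom).sum()
        )

    res = minimize_scalar(
        neg_restricted_loglik,
        bounds=LOG_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    var_u = float(eta2 @ (1.0 / (theta + lam)) / (n - 1))
    var_e = lam * var_u

    # GLS intercept and BLUP of marker effects at the REML lambda
    Vlam = K + lam * np.eye(n)
    Vinv_y = np.linalg.solve(Vlam, y)
    Vinv_1 = np.linalg.solve(Vlam, ones)
    mu = float((ones @ Vinv_y) / (ones @ Vinv_1))
    alpha = Xc.T @ np.linalg.solve(Vlam, y - mu)
    return MixedModelFit(
        mu=mu,
        alpha=alpha,
        var_u=var_u,
        var_e=var_e,
        degenerate=False,
        column_means=col_means,
    )


def ridge_alpha(
    y: np.ndarray, X: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Marker effects at a fixed shrinkage ratio (no REML).

    Returns ``(mu, alpha)`` with alpha the ridge solution
    ``(Xc'Xc + lam I)^-1 Xc' (y - mu)`` at the GLS intercept.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n = y.size
    Xc = X - X.mean(axis=0)
    K = Xc @ Xc.T
    Vlam = K + lam * np.eye(n)
    ones = np.ones(n)
    mu = float(
        (ones @ np.linalg.solve(Vlam, y)) / (ones @ np.linalg.solve(Vlam, ones))
    )
    alpha = np.linalg.solve(
        Xc.T @ Xc + lam * np.eye(X.shape[1]), Xc.T @ (y - mu)
    )
    return mu, alpha


def cv_accuracy(
    geno: GenotypeMatrix | np.ndarray,
    t: TraitTable,
    trait: str,
    n_train: int = 90,
    reps: int = 100,
    seed: int = 0,
) -> PredictionResult:
    """Repeated random-split cross-validated prediction accuracy.

    Varieties with a missing code for the trait are excluded; ``n_train``
    of the remainder form the training set each replicate and accuracy
    is the correlation of predicted vs observed codes on the held-out
    set.  A replicate whose test-set truth is constant has no defined
    correlation: it is recorded as nan and excluded from the mean.
    """
    X_full = geno.values if isinstance(geno, GenotypeMatrix) else np.asarray(geno)
    if np.isnan(X_full).any():
        raise ValueError("genotypes contain missing calls; impute first")
    j = t.trait_names.index(trait)
    y_full = t.codes[:, j]
    observed = ~np.isnan(y_full)
    X = X_full[observed]
    y = y_full[observed]
    n = y.size
    if np.unique(y).size < 2:
        raise ValueError(f"trait {trait!r} has fewer than 2 observed codes")
    if not 1 <= n_train < n:
        raise ValueError(f"n_train must be in [1, {n - 1}], got {n_train}")

    rng = np.random.default_rng(seed)
    accs = np.empty(reps)
    dropped = 0
    for rep in range(reps):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        fit = mixed_solve(y[train], X[train])
        pred = fit.predict(X[test])
        truth = y[test]
        if np.allclose(truth, truth[0]) or np.allclose(pred, pred[0]):
            accs[rep] = np.nan
            dropped += 1
            continue
        accs[rep] = np.corrcoef(pred, truth)[0, 1]
    return PredictionResult(trait=trait, accuracies=accs, n_dropped=dropped)


def proportional_n_train(n_varieties: int, ratio: float = 90 / 122) -> int:
    """Scale the default 90-of-122 training fraction to another panel size."""
    return max(1, min(n_varieties - 1, round(ratio * n_varieties)))


def stratify_traits(
    results: list[PredictionResult],
    threshold: float = 0.443,
) -> tuple[list[PredictionResult], list[PredictionResult], dict]:
    """Split traits into low-accuracy (A) and high-accuracy (B) groups.

    Mean accuracy < threshold goes to group A; >= threshold to group B.
    Returns ``(group_a, group_b, summary)`` where the summary carries
    group sizes, per-group mean accuracies and the overall mean/extremes.
    """
    group_a, group_b = [], []
    for res in results:
        if res.mean_accuracy < threshold:
            res.group = "A"
            group_a.append(res)
        else:
            res.group = "B"
            group_b.append(res)
    all_means = np.array([r.mean_accuracy for r in results])
    summary = {
        "n_a": len(group_a),
        "n_b": len(group_b),
        "mean_a": (
            float(np.mean([r.mean_accuracy for r in group_a]))
            if group_a
            else float("nan")
        ),
        "mean_b": (
            float(np.mean([r.mean_accuracy for r in group_b]))
            if group_b
            else float("nan")
        ),
        "mean_overall": float(all_means.mean()) if results else float("nan"),
        "max": float(all_means.max()) if results else float("nan"),
        "min": float(all_means.min()) if results else float("nan"),
    }
    return group_a, group_b, summary


def group_distance_correlation(
    geno_values: np.ndarray,
    pheno: PhenotypeIndicatorMatrix,
    group_traits: list[str],
    variety_ids: list[str],
    metric: str = "jaccard",
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> DistanceCorrelationResult:
    """Molecular vs phenotypic correlation using one trait group only.

    Phenotypic distances are recomputed on the group's indicator blocks;
    the molecular matrix always uses the full SNP panel.
    """
    if not group_traits:
        raise ValueError("trait group is empty")
    block = pheno.subset_traits(group_traits)
    dm_mol = distance_matrix(geno_values, metric, variety_ids, "molecular")
    dm_phe = distance_matrix(block.values, metric, variety_ids, "phenotypic")
    return distance_correlation(dm_mol, dm_phe, n_perm, rng)
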