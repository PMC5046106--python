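"""Per-phenotype association tests of a single variant.

The univariate test is the two-sided t-test on the slope of the simple
linear regression of each phenotype on the additive genotype score — the
test reported by standard GWAS software for a quantitative trait.  It is
computed through the algebraically identical Pearson-correlation form

    t = r * sqrt((n - 2) / (1 - r^2)),   df = n - 2,

which vectorizes over many genotype vectors (variants or permutations) at
once.  Signed standardized score statistics, r * sqrt(n - 1), are exposed
for the SUMSCORE comparator; under the permutation null they have mean 0
and variance 1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "P_FLOOR",
    "univariate_pvalues",
    "correlation_pvalues",
    "batch_correlations",
    "score_statistics",
    "adjust_covariates",
]

# lower clamp keeps log p finite for the partial-sum statistics
P_FLOOR = 1e-300


class MonomorphicVariantError(ValueError):
    """Raised when the genotype vector is constant (no association testable)."""


def _check_xy(Y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Y = np.asarray(Y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.ndim != 2 or x.ndim != 1:
        raise ValueError("Y must be (n, K) and x must be (n,)")
    if Y.shape[0] != x.shape[0]:
        raise ValueError(f"n mismatch: Y has {Y.shape[0]} rows, x has {x.shape[0]}")
    if Y.shape[0] < 3:
        raise ValueError("need n >= 3 for a t-test with df = n - 2")
    if np.ptp(x) == 0:
        raise MonomorphicVariantError("genotype vector is constant")
    if not np.all(np.isfinite(Y)):
        raise ValueError("phenotype matrix contains non-finite values")
    return Y, x


def batch_correlations(Yc: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    """Pearson correlations between centered phenotypes and genotype columns.

    Parameters
    ----------
    Yc : (n, K) column-centered phenotype matrix
    Xc : (n, M) column-centered genotype matrix (variants or permutations)

    Returns
    -------
    (M, K) correlation matrix, clipped into (-1, 1).
    """
    ynorm = np.linalg.norm(Yc, axis=0)
    xnorm = np.linalg.norm(Xc, axis=0)
    r = (Xc.T @ Yc) / np.outer(xnorm, ynorm)
    return np.clip(r, -1.0 + 1e-16, 1.0 - 1e-16)


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values of the correlation t-test with df = n - 2."""
    r = np.asarray(r, dtype=np.float64)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.clip(p, P_FLOOR, 1.0)


def univariate_pvalues(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Two-sided slope p-values of each phenotype regressed on the genotype.

    Entries are clamped to [1e-300, 1] so that downstream log transforms are
    finite even under exact collinearity.
    """
    Y, x = _check_xy(Y, x)
    n = x.shape[0]
    Yc = Y - Y.mean(axis=0)
    xc = (x - x.mean())[:, None]
    r = batch_correlations(Yc, xc)[0]
    return correlation_pvalues(r, n)


def score_statistics(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Signed standardized score statistics of each phenotype vs the genotype.

    The centered cross-product sum_i (y_ik - ybar_k)(x_i - xbar) divided by
    its exact permutation-null standard deviation sqrt(SS_y * SS_x / (n-1)),
    i.e. r * sqrt(n - 1); asymptotically standard normal under the null.
    """
    Y, x = _check_xy(Y, x)
    n = x.shape[0]
    Yc = Y - Y.mean(axis=0)
    xc = (x - x.mean())[:, None]
    r = batch_correlations(Yc, xc)[0]
    return r * np.sqrt(n - 1)


def adjust_covariates(Y: np.ndarray, C: "np.ndarray | None") -> np.ndarray:
    """Residualize each phenotype on an intercept plus covariates by OLS.

    With ``C`` empty or None this reduces to column-centering.  Raises on a
    rank-deficient design (collinear covariates).
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if C is None or np.size(C) == 0:
        return Y - Y.mean(axis=0)
    C = np.asarray(C, dtype=np.float64)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate matrix row count does not match phenotypes")
    design = np.column_stack([np.ones(n), C])
    q = design.shape[1]
    rank = np.linalg.matrix_rank(design)
    if rank < q:
        raise np.linalg.LinAlgError(
            f"covariate design is rank deficient (rank {rank} < {q})")
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ beta
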