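"""Comparison tests for multi-phenotype association.

Six established tests against which the adaptive combination is benchmarked:

* TATES — Simes-type combination of the ordered univariate p-values,
  rescaled by effective numbers of independent tests;
* Tippett — min-p statistic, permutation p-value;
* Fisher's combination (FC) — -2 sum(ln p), permutation p-value;
* MANOVA — Wilks' Lambda likelihood-ratio test of the multivariate
  regression of phenotypes on genotype;
* MultiPhen — reversed proportional-odds (ordinal logistic) regression of
  the genotype on all phenotypes, likelihood-ratio chi-square;
* SUMSCORE — sum of the signed standardized univariate score statistics,
  two-sided permutation p-value.

The permutation-based tests (Tippett, FC, SUMSCORE) consume the same
:class:`~afcomb.core.PermutationDraws` object as the AFC test, so all four
are evaluated on identical genotype shuffles.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, special, stats

from .core import PermutationDraws, permutation_draws
from .univariate import MonomorphicVariantError, _check_xy

__all__ = [
    "effective_number",
    "effective_number_profile",
    "tates",
    "tippett_statistic",
    "tippett_test",
    "tippett_pvalues",
    "fisher_statistic",
    "fc_test",
    "fc_pvalues",
    "wilks_lambda",
    "manova_wilks",
    "multiphen",
    "sumscore_statistic",
    "sumscore_test",
    "sumscore_pvalues",
]


# ---------------------------------------------------------------------------
# TATES


def effective_number(R: np.ndarray) -> float:
    """Effective number of independent tests from a correlation matrix.

    Eigenvalue rule of Li & Ji: m_e = sum_i [ I(lambda_i >= 1) +
    (lambda_i - floor(lambda_i)) ].  Equals K for the identity matrix and 1
    when all correlations are 1.
    """
    R = np.asarray(R, dtype=np.float64)
    lam = np.clip(np.linalg.eigvalsh(R), 0.0, None)
    # snap near-integer eigenvalues so the floor() in the rule is stable
    near = np.abs(lam - np.round(lam)) < 1e-9
    lam = np.where(near, np.round(lam), lam)
    return float(np.sum((lam >= 1.0) + (lam - np.floor(lam))))


def _check_correlation(R: np.ndarray, K: int) -> np.ndarray:
    R = np.asarray(R, dtype=np.float64)
    if R.shape != (K, K):
        raise ValueError(f"correlation matrix must be {K}x{K}")
    if not np.allclose(R, R.T, atol=1e-8) or not np.allclose(np.diag(R), 1.0,
                                                             atol=1e-8):
        raise ValueError("R must be symmetric with unit diagonal")
    if np.linalg.eigvalsh(R).min() < -1e-8:
        raise ValueError("R is not positive semi-definite")
    return R


def effective_number_profile(R: np.ndarray, order: np.ndarray) -> np.ndarray:
    """m_e among the top-j phenotypes, j = 1..K, for a given p-value order."""
    K = len(order)
    out = np.empty(K)
    for j in range(1, K + 1):
        idx = order[:j]
        out[j - 1] = effective_number(R[np.ix_(idx, idx)])
    return out


def tates(p: np.ndarray, R: np.ndarray,
          corr_transform=None) -> float:
    """TATES combined p-value from univariate p-values and the phenotype
    correlation matrix.

    p_TATES = min_j (m_e / m_e(j)) * p_(j), where m_e(j) is the effective
    number of independent tests among the j phenotypes with the smallest
    p-values.  ``corr_transform`` optionally maps phenotype correlations to
    p-value correlations elementwise (off-diagonal) before the eigenvalue
    rule; the default uses the phenotype correlations directly.
    """
    p = np.asarray(p, dtype=np.float64)
    K = p.shape[0]
    R = _check_correlation(R, K)
    if corr_transform is not None:
        Rt = corr_transform(R)
        np.fill_diagonal(Rt, 1.0)
        R = _check_correlation(Rt, K)
    order = np.argsort(p, kind="stable")
    me_top = effective_number_profile(R, order)
    m_e = me_top[-1]
    return float(min(1.0, np.min(m_e * p[order] / me_top)))


# ---------------------------------------------------------------------------
# permutation comparators (shared shuffles with AFC)


def _smoothed_rank(count: np.ndarray, B: int, smooth: bool) -> np.ndarray:
    if smooth:
        return (1.0 + count) / (B + 1.0)
    return np.maximum(count, 1) / B


def tippett_statistic(p: np.ndarray) -> float:
    """Tippett's statistic: the minimum univariate p-value."""
    return float(np.min(np.asarray(p, dtype=np.float64)))


def tippett_pvalues(P: np.ndarray, null_P: np.ndarray,
                    smooth: bool = True) -> np.ndarray:
    """Permutation p-values of the min-p statistic for rows of P."""
    obs = np.atleast_2d(P).min(axis=1)
    null = np.sort(null_P.min(axis=1))
    cnt = np.searchsorted(null, obs, side="right")
    return _smoothed_rank(cnt, null_P.shape[0], smooth)


def tippett_test(Y=None, x=None, B: int = 1000, rng=None,
                 draws: "PermutationDraws | None" = None,
                 smooth: bool = True) -> float:
    """Tippett permutation test; accepts a shared permutation stream."""
    if draws is None:
        draws = permutation_draws(Y, x, B, rng=rng)
    return float(tippett_pvalues(draws.p_obs[None, :], draws.null_P,
                                 smooth=smooth)[0])


def fisher_statistic(p: np.ndarray) -> float:
    """Fisher's combination statistic -2 sum(ln p)."""
    p = np.asarray(p, dtype=np.float64)
    return float(-2.0 * np.sum(np.log(p)))


def fc_pvalues(P: np.ndarray, null_P: np.ndarray,
               smooth: bool = True) -> np.ndarray:
    """Permutation p-values of Fisher's combination for rows of P."""
    obs = -2.0 * np.sum(np.log(np.atleast_2d(P)), axis=1)
    null = np.sort(-2.0 * np.sum(np.log(null_P), axis=1))
    # count permutations with statistic >= observed
    cnt = null.shape[0] - np.searchsorted(null, obs, side="left")
    return _smoothed_rank(cnt, null_P.shape[0], smooth)


def fc_test(Y=None, x=None, B: int = 1000, rng=None,
            draws: "PermutationDraws | None" = None,
            smooth: bool = True) -> float:
    """Fisher-combination permutation test on shared shuffles."""
    if draws is None:
        draws = permutation_draws(Y, x, B, rng=rng)
    return float(fc_pvalues(draws.p_obs[None, :], draws.null_P,
                            smooth=smooth)[0])


def sumscore_statistic(scores: np.ndarray) -> float:
    """SUMSCORE statistic: the sum of signed standardized score statistics."""
    return float(np.sum(np.asarray(scores, dtype=np.float64)))


def sumscore_pvalues(S: np.ndarray, null_S: np.ndarray,
                     smooth: bool = True) -> np.ndarray:
    """Two-sided permutation p-values of the score sum for rows of S."""
    obs = np.abs(np.atleast_2d(S).sum(axis=1))
    null = np.sort(np.abs(null_S.sum(axis=1)))
    cnt = null.shape[0] - np.searchsorted(null, obs, side="left")
    return _smoothed_rank(cnt, null_S.shape[0], smooth)


def sumscore_test(Y=None, x=None, B: int = 1000, rng=None,
                  draws: "PermutationDraws | None" = None,
                  smooth: bool = True) -> float:
    """SUMSCORE two-sided permutation test on shared shuffles."""
    if draws is None:
        draws = permutation_draws(Y, x, B, rng=rng)
    return float(sumscore_pvalues(draws.scores_obs[None, :],
                                  draws.null_scores, smooth=smooth)[0])


# ---------------------------------------------------------------------------
# MANOVA (Wilks' Lambda)


def wilks_lambda(Y: np.ndarray, x: np.ndarray) -> float:
    """Wilks' Lambda |E| / |E + H| for the regression of Y on one genotype."""
    Y, x = _check_xy(Y, x)
    n, K = Y.shape
    if n <= K + 1:
        raise np.linalg.LinAlgError("need n > K + 1 for a nonsingular fit")
    Yc = Y - Y.mean(axis=0)
    xc = x - x.mean()
    E0 = Yc.T @ Yc                       # total (intercept-only) SSCP
    b = (Yc.T @ xc) / (xc @ xc)
    E = E0 - np.outer(b, b) * (xc @ xc)  # residual SSCP; E + H = E0
    sign, logdet_E = np.linalg.slogdet(E)
    sign0, logdet_E0 = np.linalg.slogdet(E0)
    if sign <= 0 or sign0 <= 0:
        raise np.linalg.LinAlgError("singular residual covariance")
    lam = np.exp(logdet_E - logdet_E0)
    if not np.isfinite(lam) or lam <= 0:
        raise np.linalg.LinAlgError("singular residual covariance")
    return float(lam)


def manova_wilks(Y: np.ndarray, x: np.ndarray, stat: str = "bartlett") -> float:
    """MANOVA p-value for association of all phenotypes with one variant.

    ``stat`` selects the reference distribution for Lambda:
    'bartlett' (default): -(n - 1 - (K+2)/2) ln(Lambda) ~ chi2(K);
    'plain': -n ln(Lambda) ~ chi2(K);
    'rao': ((1 - Lambda)/Lambda) (n - K - 1)/K ~ F(K, n - K - 1), exact for
    a single predictor.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64).T).T
    n, K = Y.shape
    lam = wilks_lambda(Y, x)
    if stat == "bartlett":
        chi2 = -(n - 1 - (K + 2) / 2.0) * np.log(lam)
        return float(stats.chi2.sf(chi2, K))
    if stat == "plain":
        return float(stats.chi2.sf(-n * np.log(lam), K))
    if stat == "rao":
        f = (1.0 - lam) / lam * (n - K - 1) / K
        return float(stats.f.sf(f, K, n - K - 1))
    raise ValueError(f"unknown stat {stat!r}")


# ---------------------------------------------------------------------------
# MultiPhen (reversed proportional-odds regression)


class ConvergenceError(RuntimeError):
    """Ordinal regression failed to converge."""


def _prop_odds_negll_grad(params, Yx, codes, C):
    """Negative log-likelihood and gradient of the proportional-odds model.

    Cutpoints are parameterized as theta_0 = a_0, theta_j = theta_{j-1} +
    exp(a_j) to keep them ordered.  ``codes`` are category indices 0..C-1.
    """
    n, K = Yx.shape
    beta = params[:K]
    alpha = params[K:]
    theta = np.concatenate([[alpha[0]], alpha[0] + np.cumsum(np.exp(alpha[1:]))])
    eta = Yx @ beta
    # a = theta_c - eta (upper cut), b = theta_{c-1} - eta (lower cut)
    upper = np.where(codes < C - 1, theta[np.minimum(codes, C - 2)] - eta, np.inf)
    lower = np.where(codes > 0, theta[np.maximum(codes - 1, 0)] - eta, -np.inf)
    Fa, Fb = special.expit(upper), special.expit(lower)
    L = np.clip(Fa - Fb, 1e-300, None)
    nll = -np.sum(np.log(L))

    fa = np.where(np.isfinite(upper), Fa * (1.0 - Fa), 0.0)
    fb = np.where(np.isfinite(lower), Fb * (1.0 - Fb), 0.0)
    w = (fa - fb) / L
    grad_beta = Yx.T @ w                     # d(nll)/d(beta)
    grad_theta = np.zeros(C - 1)
    np.add.at(grad_theta, np.minimum(codes, C - 2), np.where(codes < C - 1,
                                                             -fa / L, 0.0))
    np.add.at(grad_theta, np.maximum(codes - 1, 0), np.where(codes > 0,
                                                             fb / L, 0.0))
    grad_alpha = np.empty(C - 1)
    grad_alpha[0] = grad_theta.sum()
    if C > 2:
        # theta_j depends on alpha_l (l>=1) for j >= l
        rev = np.cumsum(grad_theta[::-1])[::-1]
        grad_alpha[1:] = rev[1:] * np.exp(alpha[1:])
    return nll, np.concatenate([grad_beta, grad_alpha])


def _fit_prop_odds(Yx, codes, C, ridge: float = 0.0):
    n, K = Yx.shape
    counts = np.bincount(codes, minlength=C)
    cum = np.cumsum(counts)[:-1] / n
    theta0 = special.logit(cum)
    alpha0 = np.concatenate([[theta0[0]], np.log(np.maximum(
        np.diff(theta0), 1e-3))]) if C > 2 else theta0
    x0 = np.concatenate([np.zeros(K), alpha0])

    def fun(params):
        nll, grad = _prop_odds_negll_grad(params, Yx, codes, C)
        if ridge:
            nll += 0.5 * ridge * params[:K] @ params[:K]
            grad = grad.copy()
            grad[:K] += ridge * params[:K]
        return nll, grad

    res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12,
                                     "gtol": 1e-8})
    return res


def multiphen(Y: np.ndarray, x: np.ndarray) -> float:
    """MultiPhen-style p-value: ordinal regression of genotype on phenotypes.

    Fits a proportional-odds logistic model with the 0/1/2 genotype as the
    ordinal response and all K phenotypes as predictors, and compares it to
    the intercept-only model by a likelihood-ratio chi-square with K degrees
    of freedom.  With only two genotype classes in the sample this reduces
    to binary logistic regression (warned).  Quasi-separated fits are
    retried with a small ridge penalty (warned).
    """
    Y, x = _check_xy(Y, x)
    n, K = Y.shape
    levels, codes = np.unique(x, return_inverse=True)
    C = len(levels)
    if C < 2:
        raise MonomorphicVariantError("genotype vector is constant")
    if C == 2:
        warnings.warn("only two genotype classes present; using binary "
                      "logistic regression", RuntimeWarning, stacklevel=2)
    Yx = Y - Y.mean(axis=0)
    res = _fit_prop_odds(Yx, codes, C)
    if not res.success or not np.isfinite(res.fun):
        warnings.warn("ordinal fit did not converge; retrying with a ridge-"
                      "stabilized refit", RuntimeWarning, stacklevel=2)
        res = _fit_prop_odds(Yx, codes, C, ridge=1e-4 * n)
        if not np.isfinite(res.fun):
            raise ConvergenceError(
                f"proportional-odds fit failed: {res.message}")
    counts = np.bincount(codes, minlength=C)
    ll0 = float(np.sum(counts * np.log(counts / n)))
    lrt = 2.0 * (-res.fun - ll0)
    return float(stats.chi2.sf(max(lrt, 0.0), K))
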