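"""The Adaptive Fisher's Combination (AFC) statistic and permutation machinery.

Given K univariate p-values for one variant, the method forms the partial
sums of ordered log p-values

    T_k = sum_{i<=k} ln p_(i),    k = 1..K,

where p_(i) is the i-th smallest p-value.  T_1 is Tippett's min-p statistic
(on the log scale) and T_K is Fisher's combination; the family in between
combines exactly the k most significant phenotypes.  Each T_k is transferred
to an empirical p-value by its rank within a permutation null sample, the
smallest transferred p-value across k is the adaptive statistic T_all, and
its own permutation rank gives the final p-value.  The number of combined
p-values is thus chosen by the data.

Because the joint null distribution of the K univariate p-values does not
depend on which variant is tested, the permutation null sample
(:class:`NullReference`) is built once — from any one variant — and reused
for every variant in a GWAS.

Conventions (documented, rank-based and therefore invariant to any strictly
increasing transform of the T_k):

* natural log for T_k;
* observed statistics are transferred as (1 + #{null <= observed})/(B + 1),
  i.e. the observed profile counts itself in the pooled set, so transferred
  p-values lie in [1/(B+1), 1];
* null profiles are transferred against the null sample including
  themselves, rank/B;
* ties count as exceedances (inclusive <=, the conservative convention);
* the final p-value is (1 + #{b : T_all^(b) <= T_all^(obs)})/(B + 1) with
  add-one smoothing on by default (``smooth=False`` gives #{...}/B);
* ties in k_star break toward smaller k (fewer combined phenotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .univariate import P_FLOOR, batch_correlations, correlation_pvalues

__all__ = [
    "PermutationDraws",
    "NullReference",
    "AfcResult",
    "partial_log_sums",
    "rank_transfer",
    "afc_statistic",
    "permutation_draws",
    "build_null_reference",
    "null_reference_from_pvalues",
    "afc_from_reference",
    "afc_pvalues_batch",
    "afc_test",
    "meta_afc",
    "save_reference",
    "load_reference",
]


# ---------------------------------------------------------------------------
# statistics


def partial_log_sums(p: np.ndarray) -> np.ndarray:
    """Partial sums T_k of ordered log p-values for one p-value vector.

    Accepts a (K,) vector or an (M, K) matrix (row-wise profiles).  All
    entries must lie in (0, 1]; clamping away from zero happens upstream.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return np.cumsum(np.log(np.sort(p, axis=-1)), axis=-1)


def afc_statistic(per_k_p: np.ndarray) -> tuple[float, int]:
    """Minimum transferred p-value and the (1-based) k attaining it.

    Ties break toward the smallest k, the most parsimonious phenotype subset.
    """
    per_k_p = np.asarray(per_k_p, dtype=np.float64)
    if per_k_p.size == 0:
        raise ValueError("empty per-k p-value vector")
    k = int(np.argmin(per_k_p))
    return float(per_k_p[k]), k + 1


# ---------------------------------------------------------------------------
# permutation draws (shared across AFC and the permutation comparators)


@dataclass(frozen=True)
class PermutationDraws:
    """Observed and genotype-permuted univariate correlations for one variant.

    One set of B genotype shuffles drives AFC, Tippett, Fisher-combination
    and SUMSCORE simultaneously, so their special-case relationships hold on
    identical shuffles.
    """

    n: int
    r_obs: np.ndarray       # (K,) observed phenotype-genotype correlations
    null_r: np.ndarray      # (B, K) correlations under genotype shuffles
    seed: "int | None" = None

    @property
    def B(self) -> int:
        return self.null_r.shape[0]

    @property
    def K(self) -> int:
        return self.null_r.shape[1]

    @property
    def p_obs(self) -> np.ndarray:
        return correlation_pvalues(self.r_obs, self.n)

    @property
    def null_P(self) -> np.ndarray:
        return correlation_pvalues(self.null_r, self.n)

    @property
    def scores_obs(self) -> np.ndarray:
        return self.r_obs * np.sqrt(self.n - 1)

    @property
    def null_scores(self) -> np.ndarray:
        return self.null_r * np.sqrt(self.n - 1)


def permutation_draws(
    Y: np.ndarray,
    x: np.ndarray,
    B: int,
    rng: "int | np.random.Generator | None" = None,
    chunk: int = 2048,
) -> PermutationDraws:
    """Compute observed and B genotype-shuffled univariate correlations.

    Shuffles are Fisher-Yates permutations of the genotype index; phenotypes
    stay fixed.  Work is chunked so memory stays O(chunk * n).
    """
    from .scenarios import as_rng
    from .univariate import _check_xy

    if B < 1:
        raise ValueError("need B >= 1 permutations")
    Y, x = _check_xy(Y, x)
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = as_rng(rng)
    n = x.shape[0]
    Yc = Y - Y.mean(axis=0)
    xc = x - x.mean()
    r_obs = batch_correlations(Yc, xc[:, None])[0]
    null_r = np.empty((B, Y.shape[1]))
    for start in range(0, B, chunk):
        m = min(chunk, B - start)
        Xp = rng.permuted(np.broadcast_to(xc, (m, n)), axis=1)
        null_r[start:start + m] = batch_correlations(Yc, Xp.T)
    return PermutationDraws(n=n, r_obs=r_obs, null_r=null_r, seed=seed)


# ---------------------------------------------------------------------------
# null reference


@dataclass
class NullReference:
    """B permutation replicates of the partial-sum profile, built once.

    ``null_T`` holds one row per permutation.  Derived arrays — per-column
    sorted profiles and the null distribution of the min-p statistic — are
    computed lazily and cached.
    """

    null_T: np.ndarray                 # (B, K)
    seed: "int | None" = None
    source: str = ""
    _sorted_T: "np.ndarray | None" = field(default=None, repr=False)
    _sorted_Tall: "np.ndarray | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.null_T = np.asarray(self.null_T, dtype=np.float64)
        if self.null_T.ndim != 2 or self.null_T.shape[0] < 1:
            raise ValueError("null_T must be a (B >= 1, K) matrix")

    @property
    def B(self) -> int:
        return self.null_T.shape[0]

    @property
    def K(self) -> int:
        return self.null_T.shape[1]

    @property
    def sorted_T(self) -> np.ndarray:
        if self._sorted_T is None:
            self._sorted_T = np.sort(self.null_T, axis=0)
        return self._sorted_T

    @property
    def null_Tall(self) -> np.ndarray:
        """Null sample of the min-p statistic: each permutation profile
        rank-transferred against the full null sample (self-inclusive),
        then minimized over k."""
        if self._sorted_Tall is None:
            B, K = self.null_T.shape
            perk = np.empty_like(self.null_T)
            for k in range(K):
                perk[:, k] = np.searchsorted(
                    self.sorted_T[:, k], self.null_T[:, k], side="right")
            self._sorted_Tall = np.sort(perk.min(axis=1) / B)
        return self._sorted_Tall


def null_reference_from_pvalues(null_P: np.ndarray,
                                seed: "int | None" = None,
                                source: str = "") -> NullReference:
    """Build a NullReference from a (B, K) matrix of permutation p-values."""
    return NullReference(partial_log_sums(null_P), seed=seed, source=source)


def build_null_reference(
    Y: np.ndarray,
    x_ref: np.ndarray,
    B: int,
    rng: "int | np.random.Generator | None" = None,
) -> NullReference:
    """Build the reusable permutation null from one (any) variant.

    Shuffling the genotypes B times against the fixed phenotype matrix gives
    B partial-sum profiles whose joint law does not depend on the variant
    chosen, so the reference serves every variant tested against the same
    phenotypes.
    """
    draws = permutation_draws(Y, x_ref, B, rng=rng)
    return null_reference_from_pvalues(
        draws.null_P, seed=draws.seed,
        source=f"permutation null, n={draws.n}, B={B}")


def save_reference(path, ref: NullReference) -> None:
    """Serialize a NullReference (lossless) to an .npz file."""
    np.savez_compressed(
        path, null_T=ref.null_T,
        seed=np.array(-1 if ref.seed is None else ref.seed, dtype=np.int64),
        source=np.array(ref.source))


def load_reference(path) -> NullReference:
    with np.load(path, allow_pickle=False) as z:
        seed = int(z["seed"])
        return NullReference(z["null_T"],
                             seed=None if seed < 0 else seed,
                             source=str(z["source"]))


# ---------------------------------------------------------------------------
# transfer and the AFC test


def rank_transfer(T_obs: np.ndarray, ref: NullReference) -> np.ndarray:
    """Empirical p-values of observed partial sums within the null sample.

    For each k, p_k = (1 + #{b : T_k^(b) <= T_k^(obs)}) / (B + 1): the
    observed profile counts itself in the pooled set of B + 1 profiles.
    Accepts (K,) or (M, K); smaller T_k means more significant.
    """
    T_obs = np.asarray(T_obs, dtype=np.float64)
    squeeze = T_obs.ndim == 1
    T = np.atleast_2d(T_obs)
    if T.shape[1] != ref.K:
        raise ValueError(f"K mismatch: observed {T.shape[1]}, reference {ref.K}")
    out = np.empty_like(T)
    for k in range(ref.K):
        cnt = np.searchsorted(ref.sorted_T[:, k], T[:, k], side="right")
        out[:, k] = (1.0 + cnt) / (ref.B + 1.0)
    return out[0] if squeeze else out


@dataclass(frozen=True)
class AfcResult:
    """Outcome of one AFC test."""

    p_value: float
    T_all: float               # min over k of the transferred p-values
    per_k_p: np.ndarray        # (K,) transferred p-values
    k_star: int                # 1-based number of combined p-values
    B: int                     # permutations behind the null reference


def _final_pvalues(T_all_obs: np.ndarray, ref: NullReference,
                   smooth: bool = True) -> np.ndarray:
    cnt = np.searchsorted(ref.null_Tall, T_all_obs, side="right")
    if smooth:
        return (1.0 + cnt) / (ref.B + 1.0)
    return np.maximum(cnt, 1) / ref.B


def afc_pvalues_batch(P: np.ndarray, ref: NullReference,
                      smooth: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized AFC over an (M, K) matrix of univariate p-value vectors.

    Returns (final p-values (M,), k_star (M,)).  This is the per-variant
    fast path of a GWAS: one prebuilt reference, M variants.
    """
    perk = rank_transfer(partial_log_sums(P), ref)
    perk = np.atleast_2d(perk)
    kstar = np.argmin(perk, axis=1) + 1
    T_all = perk.min(axis=1)
    return _final_pvalues(T_all, ref, smooth=smooth), kstar


def afc_from_reference(p: np.ndarray, ref: NullReference,
                       smooth: bool = True) -> AfcResult:
    """AFC test of one variant's univariate p-values against a prebuilt null."""
    p = np.asarray(p, dtype=np.float64)
    perk = rank_transfer(partial_log_sums(p), ref)
    T_all, k_star = afc_statistic(perk)
    p_final = float(_final_pvalues(np.array([T_all]), ref, smooth=smooth)[0])
    return AfcResult(p_value=p_final, T_all=T_all, per_k_p=perk,
                     k_star=k_star, B=ref.B)


def afc_test(
    Y: np.ndarray,
    x: np.ndarray,
    B: int = 1000,
    rng: "int | np.random.Generator | None" = None,
    smooth: bool = True,
    draws: "PermutationDraws | None" = None,
) -> AfcResult:
    """Full AFC permutation test of K phenotypes against one variant.

    Computes the observed univariate p-values, shuffles the genotypes B
    times to build the null reference, and rank-transfers.  Passing
    precomputed ``draws`` reuses a shared permutation stream.
    """
    if draws is None:
        draws = permutation_draws(Y, x, B, rng=rng)
    ref = null_reference_from_pvalues(draws.null_P, seed=draws.seed,
                                      source="afc_test")
    return afc_from_reference(draws.p_obs, ref, smooth=smooth)


# ---------------------------------------------------------------------------
# meta-analysis variant


def _psd_factor(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=np.float64)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    w, V = np.linalg.eigh(sigma)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("covariance is not positive semi-definite")
    return V * np.sqrt(np.clip(w, 0.0, None))


def meta_afc(
    z_list: "list[np.ndarray]",
    sigma_list: "list[np.ndarray]",
    B_mc: int = 1000,
    rng: "int | np.random.Generator | None" = None,
    smooth: bool = True,
) -> AfcResult:
    """AFC for meta-analysis of L studies' summary z-statistics.

    Stacks the per-study z-vectors into one vector with block-diagonal null
    covariance, converts to two-sided normal p-values, and replaces genotype
    permutation with Monte-Carlo draws from the multivariate-normal null to
    build the reference.
    """
    from .scenarios import as_rng

    if len(z_list) != len(sigma_list) or not z_list:
        raise ValueError("need matching, non-empty z and covariance lists")
    factors = [_psd_factor(s) for s in sigma_list]
    z = np.concatenate([np.asarray(v, dtype=np.float64).ravel() for v in z_list])
    for v, s in zip(z_list, sigma_list):
        if np.size(v) != np.shape(s)[0]:
            raise ValueError("z vector and covariance dimension mismatch")
    rng = as_rng(rng)
    draws = np.concatenate(
        [rng.standard_normal((B_mc, f.shape[0])) @ f.T for f in factors], axis=1)
    p_obs = np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)
    null_P = np.clip(2.0 * stats.norm.sf(np.abs(draws)), P_FLOOR, 1.0)
    ref = null_reference_from_pvalues(null_P, source="meta-analysis MC null")
    return afc_from_reference(p_obs, ref, smooth=smooth)
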