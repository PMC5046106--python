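"""Simulation experiments: type-I-error calibration and power comparisons.

Two calibration designs and one power design, all built on the scenario
generators:

* plain calibration — many independent null replicates (beta = 0) of one
  scenario; the rejection fraction at each nominal alpha is compared with
  its binomial confidence interval;
* GWAS-mimicking calibration — one null phenotype set, very many variants
  (MAF drawn uniformly) treated as replicates, one shared permutation null
  built from the first variant;
* power — rejection fraction at a fixed alpha across a grid of effect sizes
  or of correlation values.

By default all permutation tests within one experiment share a single null
reference, built once per configuration (the "done only once for a GWAS"
fast path); ``shared_null=False`` re-permutes per replicate for fidelity
checks at small scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import comparators as cmp
from .core import (NullReference, afc_pvalues_batch, afc_test,
                   null_reference_from_pvalues, permutation_draws)
from .scenarios import ScenarioConfig, as_rng, generate_scenario_batch
from .univariate import batch_correlations, correlation_pvalues

__all__ = [
    "ALL_METHODS",
    "binomial_ci",
    "SharedNull",
    "replicate_pvalues",
    "estimate_type1_error",
    "estimate_type1_gwas_mimic",
    "estimate_power",
    "attach_rejection_ci",
]

ALL_METHODS = ("afc", "tates", "tippett", "fc", "manova", "multiphen",
               "sumscore")


def binomial_ci(p: float, n: int, level: float = 0.95,
                method: str = "normal") -> tuple[float, float]:
    """Confidence interval for a rejection rate estimated from n replicates.

    ``method='normal'`` gives the Wald interval p +/- z * sqrt(p(1-p)/n)
    (the form behind the printed intervals in calibration tables);
    ``method='exact'`` gives Clopper-Pearson.
    """
    if not 0.0 <= p <= 1.0 or n < 1:
        raise ValueError("need p in [0,1] and n >= 1")
    if method == "normal":
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(p * (1.0 - p) / n)
        return (p - half, p + half)
    if method == "exact":
        k = int(round(p * n))
        lo = 0.0 if k == 0 else stats.beta.ppf((1 - level) / 2, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(1 - (1 - level) / 2, k + 1, n - k)
        return (float(lo), float(hi))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# shared permutation null for a whole experiment


@dataclass
class SharedNull:
    """One permutation null sample serving AFC, Tippett, FC and SUMSCORE."""

    ref: NullReference
    null_min_sorted: np.ndarray    # sorted min-p statistics
    null_fc_sorted: np.ndarray     # sorted -2 sum(ln p)
    null_ss_sorted: np.ndarray     # sorted |sum of scores|

    @classmethod
    def from_draws(cls, draws) -> "SharedNull":
        null_P = draws.null_P
        return cls(
            ref=null_reference_from_pvalues(null_P, seed=draws.seed),
            null_min_sorted=np.sort(null_P.min(axis=1)),
            null_fc_sorted=np.sort(-2.0 * np.log(null_P).sum(axis=1)),
            null_ss_sorted=np.sort(np.abs(draws.null_scores.sum(axis=1))),
        )

    @property
    def B(self) -> int:
        return self.ref.B

    def afc(self, P: np.ndarray) -> np.ndarray:
        return afc_pvalues_batch(P, self.ref)[0]

    def tippett(self, P: np.ndarray) -> np.ndarray:
        cnt = np.searchsorted(self.null_min_sorted, P.min(axis=1), side="right")
        return (1.0 + cnt) / (self.B + 1.0)

    def fc(self, P: np.ndarray) -> np.ndarray:
        obs = -2.0 * np.log(P).sum(axis=1)
        cnt = self.B - np.searchsorted(self.null_fc_sorted, obs, side="left")
        return (1.0 + cnt) / (self.B + 1.0)

    def sumscore(self, S: np.ndarray) -> np.ndarray:
        obs = np.abs(S.sum(axis=1))
        cnt = self.B - np.searchsorted(self.null_ss_sorted, obs, side="left")
        return (1.0 + cnt) / (self.B + 1.0)


def _replicate_correlations(Y: np.ndarray, X: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate phenotype-genotype correlations for stacked data.

    Y is (R, n, K), X is (R, n); returns (r (R, K), Yc centered copy).
    """
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=1, keepdims=True)
    num = np.einsum("rnk,rn->rk", Yc, Xc)
    den = np.sqrt(np.einsum("rnk,rnk->rk", Yc, Yc)
                  * np.einsum("rn,rn->r", Xc, Xc)[:, None])
    r = np.clip(num / den, -1.0 + 1e-16, 1.0 - 1e-16)
    return r, Yc


def replicate_pvalues(
    config: ScenarioConfig,
    n_replicates: int,
    B: int,
    rng: "int | np.random.Generator | None" = None,
    methods: tuple = ("afc",),
    shared_null: bool = True,
    chunk: int = 500,
) -> pd.DataFrame:
    """One p-value per replicate and method for a scenario configuration.

    With ``shared_null`` (default) the permutation null is built once from
    the first replicate and reused; otherwise every replicate gets its own B
    genotype shuffles.
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    # independent substreams so replicate data do not depend on the null mode
    gen_rng, ref_rng, perm_rng = as_rng(
        config.seed if rng is None else rng).spawn(3)
    rng = gen_rng
    n = config.n
    perm_methods = {"afc", "tippett", "fc", "sumscore"} & set(methods)

    shared = None
    if shared_null and perm_methods:
        Y0, x0 = generate_scenario_batch(config, 1, rng=ref_rng)
        draws = permutation_draws(Y0[0], x0[0], B, rng=ref_rng)
        shared = SharedNull.from_draws(draws)

    out: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    done = 0
    while done < n_replicates:
        m_rep = min(chunk, n_replicates - done)
        Y, X = generate_scenario_batch(config, m_rep, rng=rng)
        r, _ = _replicate_correlations(Y, X.astype(np.float64))
        P = correlation_pvalues(r, n)
        S = r * np.sqrt(n - 1)
        for method in methods:
            if method in perm_methods and shared is not None:
                if method == "sumscore":
                    out[method].append(getattr(shared, method)(S))
                else:
                    out[method].append(getattr(shared, method)(P))
            elif method in perm_methods:
                vals = np.empty(m_rep)
                for i in range(m_rep):
                    d = permutation_draws(Y[i], X[i], B, rng=perm_rng)
                    if method == "afc":
                        vals[i] = afc_test(Y[i], X[i], draws=d).p_value
                    elif method == "tippett":
                        vals[i] = cmp.tippett_test(draws=d)
                    elif method == "fc":
                        vals[i] = cmp.fc_test(draws=d)
                    else:
                        vals[i] = cmp.sumscore_test(draws=d)
                out[method].append(vals)
            elif method == "tates":
                vals = np.empty(m_rep)
                for i in range(m_rep):
                    R = np.corrcoef(Y[i], rowvar=False)
                    vals[i] = cmp.tates(P[i], R)
                out[method].append(vals)
            elif method == "manova":
                out[method].append(np.array(
                    [cmp.manova_wilks(Y[i], X[i]) for i in range(m_rep)]))
            elif method == "multiphen":
                out[method].append(np.array(
                    [cmp.multiphen(Y[i], X[i]) for i in range(m_rep)]))
        done += m_rep
    return pd.DataFrame({m: np.concatenate(v) for m, v in out.items()})


def attach_rejection_ci(rate: float, n: int) -> tuple[float, float]:
    lo, hi = binomial_ci(rate, n)
    return max(lo, 0.0), min(hi, 1.0)


def estimate_type1_error(
    configs: "list[ScenarioConfig]",
    alphas: tuple = (0.01, 0.001),
    n_replicates: int = 2000,
    B: int = 2000,
    rng: "int | np.random.Generator | None" = None,
    methods: tuple = ("afc",),
    shared_null: bool = True,
) -> pd.DataFrame:
    """Estimated rejection rates under the null for each configuration.

    Each config is forced to ``beta = 0``.  Returns one row per
    (scenario, n, method, alpha) with the rate and its 95% binomial CI.
    Nominal levels below the permutation resolution 1/B are reported as NaN.
    """
    rng = as_rng(rng)
    rows = []
    for config in configs:
        config = dataclasses.replace(config, beta=0.0)
        pvals = replicate_pvalues(config, n_replicates, B, rng=rng,
                                  methods=methods, shared_null=shared_null)
        for method in methods:
            for alpha in alphas:
                if alpha < 1.0 / B:
                    import warnings
                    warnings.warn(f"alpha={alpha} below permutation "
                                  f"resolution 1/B={1 / B}", RuntimeWarning)
                    rate = np.nan
                    lo = hi = np.nan
                else:
                    rate = float((pvals[method] <= alpha).mean())
                    lo, hi = attach_rejection_ci(rate, n_replicates)
                rows.append({"scenario": config.scenario, "n": config.n,
                             "K": config.K, "method": method, "alpha": alpha,
                             "rate": rate, "ci_low": lo, "ci_high": hi,
                             "n_replicates": n_replicates, "B": B})
    return pd.DataFrame(rows)


def estimate_type1_gwas_mimic(
    scenario: int,
    n: int = 6000,
    K: int = 8,
    n_variants: int = 100_000,
    B: int = 100_000,
    alphas: tuple = (1e-3, 1e-4, 1e-5),
    rng: "int | np.random.Generator | None" = None,
    maf_range: tuple = (0.05, 0.5),
    rho_fa: float = 0.1,
    rho_phe: float = 0.1,
    chunk: int = 5000,
    return_pvalues: bool = False,
):
    """GWAS-mimicking null calibration: many variants as replicates.

    One null phenotype set is generated for the scenario; variants are drawn
    with MAF uniform on ``maf_range``; the permutation null reference is
    built once from the genotypes at the first variant and every variant's
    AFC p-value is computed against it.
    """
    rng = as_rng(rng)
    config = ScenarioConfig(scenario=scenario, n=n, K=K, beta=0.0,
                            maf=0.3, rho_fa=rho_fa, rho_phe=rho_phe)
    Yb, _ = generate_scenario_batch(config, 1, rng=rng)
    Y = Yb[0]
    Yc = Y - Y.mean(axis=0)

    def draw_genotypes(m: int) -> np.ndarray:
        maf = rng.uniform(*maf_range, size=m)
        X = rng.binomial(2, maf[:, None], size=(m, n))
        bad = np.ptp(X, axis=1) == 0
        while bad.any():                      # monomorphic redraw (rare)
            X[bad] = rng.binomial(2, maf[bad, None], size=(bad.sum(), n))
            bad = np.ptp(X, axis=1) == 0
        return X

    x_first = draw_genotypes(1)[0]
    draws = permutation_draws(Y, x_first.astype(np.float64), B, rng=rng,
                              chunk=chunk)
    ref = null_reference_from_pvalues(draws.null_P)
    ref.null_Tall  # force the cached null min-p sample

    pvals = np.empty(n_variants)
    done = 0
    while done < n_variants:
        m = min(chunk, n_variants - done)
        X = draw_genotypes(m).astype(np.float64)
        Xc = (X - X.mean(axis=1, keepdims=True)).T
        r = batch_correlations(Yc, Xc)
        P = correlation_pvalues(r, n)
        pvals[done:done + m] = afc_pvalues_batch(P, ref)[0]
        done += m

    rows = []
    for alpha in alphas:
        rate = float((pvals <= alpha).mean())
        lo, hi = attach_rejection_ci(rate, n_variants)
        rows.append({"scenario": scenario, "n": n, "K": K, "alpha": alpha,
                     "rate": rate, "ci_low": lo, "ci_high": hi,
                     "n_variants": n_variants, "B": B})
    table = pd.DataFrame(rows)
    return (table, pvals) if return_pvalues else table


def estimate_power(
    config: ScenarioConfig,
    betas: "tuple | None" = None,
    rhos: "tuple | None" = None,
    rho_param: str = "rho_fa",
    alpha: float = 0.001,
    n_replicates: int = 1000,
    B: int = 10_000,
    rng: "int | np.random.Generator | None" = None,
    methods: tuple = ALL_METHODS,
    shared_null: bool = True,
) -> pd.DataFrame:
    """Rejection rates at one alpha across an effect-size or correlation grid.

    Exactly one of ``betas`` (power vs effect size) or ``rhos`` (power vs
    between-factor / phenotype correlation, chosen by ``rho_param``) must be
    given.  Returns tidy rows (grid value, method, power, CI).
    """
    if (betas is None) == (rhos is None):
        raise ValueError("give exactly one of betas or rhos")
    rng = as_rng(rng)
    grid = [("beta", b) for b in betas] if betas is not None else \
           [(rho_param, r) for r in rhos]
    rows = []
    for param, value in grid:
        cfg = dataclasses.replace(config, **{param: value})
        pvals = replicate_pvalues(cfg, n_replicates, B, rng=rng,
                                  methods=methods, shared_null=shared_null)
        for method in methods:
            power = float((pvals[method] <= alpha).mean())
            lo, hi = attach_rejection_ci(power, n_replicates)
            rows.append({"scenario": cfg.scenario, "param": param,
                         "value": value, "beta": cfg.beta, "method": method,
                         "alpha": alpha, "power": power, "ci_low": lo,
                         "ci_high": hi, "n_replicates": n_replicates, "B": B})
    return pd.DataFrame(rows)


def plot_power_curves(table: pd.DataFrame, path) -> None:
    """Basic power-curve plot (one line per method) from estimate_power output."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for method, sub in table.groupby("method"):
        sub = sub.sort_values("value")
        ax.plot(sub["value"], sub["power"], marker="o", label=method)
    ax.set_xlabel(table["param"].iloc[0])
    ax.set_ylabel("power")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
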