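"""Synthetic genotype and multi-phenotype data generation.

Genotypes at a single biallelic variant are drawn under Hardy-Weinberg
equilibrium from a minor-allele frequency.  Phenotypes follow one of six
factor-model scenarios that differ in how many latent factors there are,
how the factors are correlated, and whether the genetic effect enters a
factor (and hence a block of phenotypes) or a single phenotype:

1. one factor f = beta * X carrying only the genetic effect; all K
   phenotypes associated, and independent under the null.
2. four correlated factors, effect on the fourth; K/4 phenotypes associated.
3. two correlated factors, effect on the second; K/2 phenotypes associated.
4. four correlated factors, effect added to the K-th phenotype only.
5. one factor, effect added to the K-th phenotype only.
6. exchangeably correlated phenotypes ("network" structure, no common
   factor), effect added to every phenotype.

Phenotypes built from a factor f with loading ``a`` are
``Y_j = a * f + sqrt(1 - a^2) * eps_j`` with i.i.d. standard-normal
residuals, so the within-factor phenotype correlation is exactly ``a**2``
and the between-factor correlation is ``a**2 * rho_fa``.  Setting
``beta = 0`` makes every scenario a null model (phenotypes independent of
genotype).
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScenarioConfig",
    "simulate_genotypes",
    "generate_scenario",
    "generate_scenario_batch",
    "write_phenotypes_tsv",
    "write_genotypes_vcf",
    "write_genotypes_raw",
    "write_config",
    "read_config",
]


def as_rng(seed: "int | np.random.Generator | None") -> np.random.Generator:
    """Return a Generator; integers become fresh PCG64 streams."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one simulation scenario.

    Parameters
    ----------
    scenario : int in 1..6
    n : number of individuals
    K : number of phenotypes (multiple of 4 for scenarios 2/4, of 2 for 3)
    maf : minor-allele frequency in (0, 0.5]
    beta : genetic effect size (0 gives the null model)
    loading : factor loading ``a`` in [0, 1); within-factor correlation a**2
    rho_fa : between-factor correlation (scenarios 2-4)
    rho_phe : common phenotype correlation (scenario 6)
    seed : default RNG seed used when no generator is passed explicitly
    """

    scenario: int
    n: int = 1000
    K: int = 20
    maf: float = 0.3
    beta: float = 0.0
    loading: float = 0.75
    rho_fa: float = 0.1
    rho_phe: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in range(1, 7):
            raise ValueError(f"scenario must be in 1..6, got {self.scenario}")
        if self.n < 2 or self.K < 1:
            raise ValueError("need n >= 2 and K >= 1")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.loading < 1.0:
            raise ValueError("loading must be in [0, 1)")
        for name in ("rho_fa", "rho_phe"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.scenario in (2, 4) and self.K % 4:
            raise ValueError(f"scenario {self.scenario} requires K divisible by 4")
        if self.scenario == 3 and self.K % 2:
            raise ValueError("scenario 3 requires K divisible by 2")

    @property
    def n_factors(self) -> int:
        return {1: 1, 2: 4, 3: 2, 4: 4, 5: 1, 6: 0}[self.scenario]


def simulate_genotypes(
    n: int, maf: float, rng: "int | np.random.Generator | None" = None
) -> np.ndarray:
    """Draw n additive genotype scores under Hardy-Weinberg equilibrium.

    Each entry is Binomial(2, maf): P(2) = maf^2, P(1) = 2 maf (1-maf),
    P(0) = (1-maf)^2.  Returns an int8 vector with entries in {0, 1, 2}.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(rng)
    return rng.binomial(2, maf, size=n).astype(np.int8)


def _exchangeable_cholesky(m: int, rho: float) -> np.ndarray:
    """Cholesky factor of the compound-symmetry matrix (1-rho) I + rho A."""
    sigma = np.full((m, m), rho)
    np.fill_diagonal(sigma, 1.0)
    return np.linalg.cholesky(sigma)


def _phenotypes_from_factors(F: np.ndarray, K: int, loading: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Map factor draws F (R, n, m) to phenotypes Y (R, n, K) in m blocks."""
    R, n, m = F.shape
    block = K // m
    resid = np.sqrt(1.0 - loading**2)
    Y = np.repeat(loading * F, block, axis=2)
    Y += resid * rng.standard_normal((R, n, K))
    return Y


def generate_scenario_batch(
    config: ScenarioConfig,
    n_replicates: int,
    rng: "int | np.random.Generator | None" = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate many independent replicates of one scenario.

    Returns ``(Y, X)`` with ``Y`` of shape (R, n, K) and genotypes ``X`` of
    shape (R, n).  Scenarios 2 and 4 consume the RNG identically apart from
    where the effect is added, so with ``beta = 0`` and the same seed they
    produce identical data.
    """
    rng = as_rng(config.seed if rng is None else rng)
    R, n, K = n_replicates, config.n, config.K
    a, beta = config.loading, config.beta

    X = rng.binomial(2, config.maf, size=(R, n)).astype(np.int8)
    Xf = X.astype(np.float64)

    s = config.scenario
    if s == 1:
        # the factor is purely genetic: f = beta * X, no latent residual,
        # so the K phenotypes are mutually independent under the null
        f = beta * Xf
        Y = _phenotypes_from_factors(f[:, :, None], K, a, rng)
    elif s == 5:
        f = rng.standard_normal((R, n))
        Y = _phenotypes_from_factors(f[:, :, None], K, a, rng)
        Y[:, :, K - 1] += beta * Xf
    elif s in (2, 3, 4):
        m = 4 if s in (2, 4) else 2
        L = _exchangeable_cholesky(m, config.rho_fa)
        F = rng.standard_normal((R, n, m)) @ L.T
        if s in (2, 3):
            F[:, :, m - 1] += beta * Xf
        Y = _phenotypes_from_factors(F, K, a, rng)
        if s == 4:
            Y[:, :, K - 1] += beta * Xf
    else:  # scenario 6
        L = _exchangeable_cholesky(K, config.rho_phe)
        Y = rng.standard_normal((R, n, K)) @ L.T
        Y += beta * Xf[:, :, None]
        Y += rng.standard_normal((R, n, K))
    return Y, X


def generate_scenario(
    config: ScenarioConfig, rng: "int | np.random.Generator | None" = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one dataset: phenotype matrix (n, K) and genotype vector (n,)."""
    Y, X = generate_scenario_batch(config, 1, rng=rng)
    return Y[0], X[0]


# ---------------------------------------------------------------------------
# writers


def phenotype_names(K: int) -> list[str]:
    return [f"pheno_{k + 1}" for k in range(K)]


def sample_ids(n: int) -> list[str]:
    return [f"S{i + 1}" for i in range(n)]


def write_phenotypes_tsv(path: "str | os.PathLike", Y: np.ndarray,
                         names: "list[str] | None" = None,
                         ids: "list[str] | None" = None) -> None:
    """Write an n x K phenotype matrix as TSV with sample_id + named columns."""
    import pandas as pd

    Y = np.asarray(Y, dtype=float)
    names = names or phenotype_names(Y.shape[1])
    ids = ids or sample_ids(Y.shape[0])
    df = pd.DataFrame(Y, columns=names)
    df.insert(0, "sample_id", ids)
    df.to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(path: "str | os.PathLike", X: np.ndarray,
                        variant_ids: "list[str] | None" = None,
                        ids: "list[str] | None" = None) -> None:
    """Write additive genotypes as a minimal biallelic VCF (GT field only).

    ``X`` is (n,) for a single variant or (n, M) for M variants; the count of
    ALT alleles equals the additive score (0 -> 0/0, 1 -> 0/1, 2 -> 1/1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=int).T).T
    if X.ndim != 2:
        raise ValueError("X must be (n,) or (n, M)")
    n, M = X.shape
    ids = ids or sample_ids(n)
    variant_ids = variant_ids or [f"var_{j + 1}" for j in range(M)]
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##contig=<ID=1>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(ids) + "\n")
    for j in range(M):
        calls = "\t".join(gt[int(v)] for v in X[:, j])
        buf.write(f"1\t{j + 1}\t{variant_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_genotypes_raw(path: "str | os.PathLike", X: np.ndarray,
                        variant_ids: "list[str] | None" = None,
                        ids: "list[str] | None" = None) -> None:
    """Write genotypes in the PLINK --recode A (.raw) dialect."""
    X = np.atleast_2d(np.asarray(X, dtype=int).T).T
    n, M = X.shape
    ids = ids or sample_ids(n)
    variant_ids = variant_ids or [f"var_{j + 1}" for j in range(M)]
    with open(path, "w") as fh:
        fh.write("FID IID PAT MAT SEX PHENOTYPE "
                 + " ".join(f"{v}_G" for v in variant_ids) + "\n")
        for i in range(n):
            row = " ".join(str(int(v)) for v in X[i])
            fh.write(f"{ids[i]} {ids[i]} 0 0 0 -9 {row}\n")


def write_config(path: "str | os.PathLike", config: ScenarioConfig) -> None:
    """Write a ScenarioConfig as a flat key:value text file."""
    with open(path, "w") as fh:
        for field in dataclasses.fields(config):
            fh.write(f"{field.name}: {getattr(config, field.name)}\n")


def read_config(path: "str | os.PathLike") -> ScenarioConfig:
    kw: dict = {}
    casts = {f.name: f.type for f in dataclasses.fields(ScenarioConfig)}
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        key, val = key.strip(), val.strip()
        if key not in casts:
            raise ValueError(f"unknown config key {key!r}")
        if val == "None":
            kw[key] = None
        elif key in ("scenario", "n", "K", "seed"):
            kw[key] = int(val)
        else:
            kw[key] = float(val)
    return ScenarioConfig(**kw)
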