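# Methods

This note records the exact statistical procedures, conventions and defaults
implemented in `afcomb`, in enough detail to re-derive every number the
package produces.

## 1. Setting

One biallelic variant with additive genotype score x ∈ {0, 1, 2} is tested
for association with K quantitative phenotypes Y₁ … Y_K measured on n
individuals. The univariate building block (module `univariate`) is the
correlation-form t-test: with r_k the sample correlation of Y_k and x,

    t_k = r_k √((n − 2) / (1 − r_k²)),   p_k = 2 · P(T_{n−2} ≥ |t_k|),

equivalent to the Wald test of the slope in the linear regression of Y_k on
x. The signed standardized score statistic is S_k = r_k √(n − 1).
Covariates are removed by least-squares residualization of the phenotypes
(and implicitly of the genotype, since correlations with residualized Y are
unchanged by the genotype's covariate component under permutation
calibration). p-values are clamped to [1e−300, 1] to keep logs finite;
correlations are clipped to ±(1 − 1e−16).

## 2. The AFC test (module `core`)

Order the univariate p-values p₍₁₎ ≤ … ≤ p₍K₎ and form the partial sums of
ordered natural-log p-values

    T_k = Σ_{i ≤ k} ln p_(i),    k = 1 … K.

T₁ is a monotone function of the minimum p-value (Tippett) and T_K of
Fisher's combination; intermediate k interpolate between "best single
trait" and "pool everything".

**Permutation null.** The genotype vector is shuffled B times
(Fisher–Yates); each shuffle b yields a profile T⁽ᵇ⁾ = (T₁⁽ᵇ⁾ … T_K⁽ᵇ⁾).
Because the phenotypes are held fixed and the genotype enters each profile
only through the vector of correlations with an exchangeable shuffle, the
joint null law of the profile is the same whichever variant is shuffled.
The B×K matrix is therefore stored once (`NullReference`, `.npz`
serializable) and reused for every variant of a scan.

**Rank transfer.** The observed profile is converted to per-k empirical
p-values counting itself into the pooled sample:

    p̃_k = (1 + #{b : T_k⁽ᵇ⁾ ≤ T_k^obs}) / (B + 1),

with ties counted inclusively (≤). Null profiles are transferred
*self-inclusively* against their own sample, p̃_k⁽ᵇ⁾ = rank_b / B, which
makes the two transfer maps order-isomorphic and gives the exact
special-case reductions below.

**Final statistic and p-value.**

    T_all = min_k p̃_k,      k* = smallest k attaining the minimum,
    p_AFC = (1 + #{b : T_all⁽ᵇ⁾ ≤ T_all^obs}) / (B + 1).

The add-one smoothing (default `smooth=True`) keeps p ≥ 1/(B+1) and makes
the null distribution stochastically dominate uniform; `smooth=False` gives
max(count, 1)/B. Exact consequences proven in the test suite:

* **K = 1**: p_AFC equals the smoothed univariate permutation p-value.
* On shared shuffles, p̃₁ is exactly Tippett's permutation p-value and p̃_K
  exactly Fisher-combination's (`PermutationDraws` feeds all three).
* Any strictly increasing transform applied to all T_k (observed and null)
  leaves every transferred p-value bit-identical — the test depends on the
  profile only through ranks.

**Meta-analysis variant** (`meta_afc`): given per-study z-vectors and their
null covariances, z-values are stacked, converted to two-sided normal
p-values, and the permutation sample is replaced by B Monte-Carlo draws
from the block-diagonal null normal law (PSD factor via eigendecomposition).

## 3. Simulation scenarios (module `scenarios`)

Genotypes: X ~ Binomial(2, MAF) (Hardy–Weinberg). Phenotypes derive from
latent factors with loading a: a block of phenotypes tied to factor f is
Y_j = a·f + √(1 − a²)·ε_j, ε_j i.i.d. N(0,1), so within-factor correlation
is a² and between-factor correlation a²·ρ_fa.

| scenario | factors | correlation | effect enters | affected traits |
|---|---|---|---|---|
| 1 | 1, purely genetic: f = βX | none under null | every phenotype via f | all K |
| 2 | 4, exchangeable ρ_fa | a², a²ρ_fa | 4th factor | last K/4 |
| 3 | 2, exchangeable ρ_fa | a², a²ρ_fa | 2nd factor | last K/2 |
| 4 | 4, exchangeable ρ_fa | a², a²ρ_fa | added to Y_K only | 1 |
| 5 | 1, N(0,1) | a² | added to Y_K only | 1 |
| 6 | none ("network") | pairwise ρ_phe/2 | added to every phenotype | all K |

Scenario 6 draws Ỹ ~ N(0, (1−ρ_phe)I + ρ_phe·11ᵀ), then Y = Ỹ + βX + ε with
a second independent N(0,1) noise, giving pairwise correlation ρ_phe/2.
Scenario 1's factor carries *only* the genetic effect (no latent residual),
so its null phenotypes are mutually independent; this is what makes
single-trait-oriented tests (min-p, TATES) weakest there while
whole-covariance tests (MANOVA) stay strong — the qualitative pattern the
power experiments check. Scenarios 2 and 4 consume the random stream
identically, so at β = 0 with a shared seed they generate identical data.

Defaults: n = 1000, K = 20, MAF = 0.3, a = 0.75, ρ_fa = ρ_phe = 0.1.

**Operating points for power experiments** (package choices, fixed a priori
at n = 1000, K = 20, α = 0.001): β = 0.05 (scenario 1; the effect loads on
all 20 phenotypes, chosen to roughly match scenario 6's per-phenotype
standardized effect), 0.2 (scenarios 2–3), 0.3 (scenarios 4–5; one
phenotype carries everything), 0.1 (scenario 6).

## 4. Comparators (module `comparators`)

* **TATES**: p = min_j (m_e / m_e(j)) · p₍ⱼ₎ with m_e(j) the effective
  number of independent tests among the j best phenotypes, computed by the
  eigenvalue rule m_e = Σ [1(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)] on the phenotype
  correlation matrix (eigenvalues within 1e−9 of an integer are snapped to
  it to stabilize the floor). An optional elementwise map from phenotype to
  p-value correlations can be supplied.
* **Tippett / FC / SUMSCORE**: permutation tests of min p, −2Σ ln p, and
  |Σ_k S_k| (two-sided) on the same genotype shuffles as AFC.
* **MANOVA**: Wilks Λ = |E|/|E₀| via a rank-one update; by default the
  Bartlett form −(n − 1 − (K+2)/2) ln Λ ~ χ²_K; `plain` (−n ln Λ) and the
  exact single-predictor `rao` F-form are options.
* **MultiPhen-style**: proportional-odds logistic regression of the ordinal
  genotype on all phenotypes, likelihood-ratio χ²_K against the
  intercept-only model. The solver is a hand-written negative
  log-likelihood + analytic gradient optimized with L-BFGS-B (cutpoints
  kept ordered via θ_j = θ_{j−1} + exp(α_j)); two genotype classes in-sample
  fall back to binary logistic regression (warned); quasi-separation is
  retried with ridge 1e−4·n (warned). statsmodels' OrderedModel is used as
  a correctness oracle in the tests but not at runtime (it is ~100× slower,
  which would put the power experiments far over budget).

## 5. Experiments (module `experiments`)

* Calibration (`estimate_type1_error`): β = 0 replicates, rejection rates
  with 95% binomial CIs. Default reduced scale 2,000 replicates / B = 2,000;
  a shared null reference built from the first replicate is the default
  fast path (per-replicate permutation available; the two agree on ≥ 99% of
  rejection decisions in the tests). α below 1/B yields NaN with a warning.
* GWAS-mimic calibration (`estimate_type1_gwas_mimic`): one phenotype draw,
  many variants with MAF ~ U(0.05, 0.5) (monomorphic draws are redrawn),
  one shared reference from the first variant; defaults n = 6000, K = 8,
  1e5 variants, B = 1e5 (≈ 1 min).
* Power (`estimate_power`): rejection rate at one α across a β grid or a
  correlation grid (ρ_fa or ρ_phe).
* `binomial_ci`: normal-approximation Wald interval p ± z√(p(1−p)/n)
  (the convention behind printed calibration intervals), Clopper–Pearson
  exact as an option.
* Reproducibility: replicate generation, reference building and permutation
  streams are split into independent `Generator.spawn` substreams, so
  shared-null and per-replicate runs see identical replicate data and every
  table is bit-reproducible given a seed.

## 6. Numerical and design choices

* All permutation work is chunked (`rng.permuted` on 2048–5000-row blocks)
  and reduced to BLAS matrix products; a full GWAS-mimic run (1e5 variants ×
  1e5 permutations, n = 6000, K = 8) takes ~1 minute on one CPU.
* Ties in k\* break toward the smallest k (most parsimonious subset).
* Natural logarithms throughout; partial sums work on (K,) or (M,K) arrays.
* Repository shape: a library (`src/afcomb`) with narrative `examples/` and
  a thin `click` CLI (`afc`) that only wraps library calls; experiments are
  functions returning tidy DataFrames so they compose with the tests.
* Statistical acceptance checks use exact central 99.9% binomial regions
  per Monte-Carlo rate (joint false-alarm control across ~26 checks) plus a
  "most cells within the 95% CI" layer; paired power orderings use exact
  one-sided McNemar tests on shared replicates.

## 7. Limitations

* Quantitative phenotypes only; no binary/survival traits, no
  relatedness/population-structure correction (covariate residualization is
  linear and homoscedastic).
* The shared null reference assumes exchangeable individuals and one cohort
  per scan; covariate-adjusted genotypes reuse the same reference only
  approximately.
* TATES here uses the eigenvalue effective-number rule directly on
  phenotype correlations; the original phenotype-to-p-value-correlation
  polynomial is not bundled (its fitted constants are not reproducible from
  public descriptions), only exposed as a user-supplied transform.
* The simulation scenarios are Gaussian factor models — convenient and
  standard, but narrower than real phenotype panels (no skew, no heavy
  tails, no missingness patterns).
* Meta-AFC assumes the supplied per-study covariances are correct; it does
  not estimate them.
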