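# afcomb — adaptive combination tests for multi-phenotype genetic association

Genome-wide association studies increasingly test one genetic variant
against **many phenotypes at once**: a variant may shift a whole block of
correlated traits (pleiotropy), or just one trait buried inside a panel of
twenty. Fixed combination rules each have a blind spot —

* **Tippett / min-p** (take the best single p-value) loses power when the
  effect is spread thinly over many phenotypes;
* **Fisher's combination** (pool all log p-values) loses power when only a
  few phenotypes carry signal and the rest add noise;
* **MANOVA / ordinal regression of genotype on phenotypes** lose power when
  the effect direction lines up with the dominant phenotype correlation.

`afcomb` implements an **adaptive Fisher-type combination (AFC)** test that
avoids committing in advance. From the K univariate p-values
p₍₁₎ ≤ … ≤ p₍K₎ it forms every *partial sum of ordered log p-values*

    T_k = Σ_{i≤k} ln p_(i),        k = 1 … K,

a family that contains min-p (k = 1) and Fisher's combination (k = K) as
endpoints. Each T_k is calibrated against a genotype-permutation null,
giving a transferred p-value per k; the statistic is the **minimum
transferred p-value over k**, itself calibrated by rank within the same
permutation sample. The test therefore adapts the number of combined
phenotypes, k\*, to the data, while permutation calibration keeps the type-I
error exact regardless of the phenotype correlation structure. A key
property makes it practical at GWAS scale: the permutation null of the
partial-sum profile does not depend on which variant is shuffled, so **one
stored null reference calibrates every variant in a scan**.

The package also ships the six factor-model simulation scenarios used to
study such tests, six comparator methods (TATES, Tippett, Fisher's
combination, MANOVA/Wilks, MultiPhen-style ordinal regression, SUMSCORE), a
summary-statistic meta-analysis variant, and an experiment harness for
type-I-error and power studies.

## Worked example

`examples/01_basic_test.py` — one common variant (MAF 0.3) influences a
latent factor shared by 5 of 20 phenotypes in 1,000 individuals:

```python
from afcomb import ScenarioConfig, afc_test, generate_scenario
from afcomb.univariate import univariate_pvalues

config = ScenarioConfig(scenario=2, n=1000, K=20, maf=0.3, beta=0.1)
Y, x = generate_scenario(config, rng=7)

p_uni = univariate_pvalues(Y, x)
result = afc_test(Y, x, B=10_000, rng=1)
```

Output of the script:

```
smallest univariate p-values: [0.00015 0.00016 0.00142 0.00293]
Bonferroni on the best one  : 0.00309
AFC p-value                 : 0.0015
combined the 2 smallest p-values (out of 20)
```

AFC notices that *two* phenotypes carry signal, combines exactly those, and
halves the Bonferroni p-value; had the signal sat in one phenotype or in
all twenty, k\* would have adapted accordingly.

More examples in `examples/`:

| script | shows |
|---|---|
| `01_basic_test.py` | simulate one dataset, run the AFC test |
| `02_gwas_shared_null.py` | one stored null reference calibrating 2,000 variants |
| `03_method_comparison.py` | all seven methods on signal and null data; exact T₁/T_K reductions |
| `04_calibration.py` | type-I-error table with binomial CIs |
| `05_power_curve.py` | power vs effect size for four methods |
| `06_meta_analysis.py` | AFC from per-study summary z-statistics |
| `07_cli_workflow.sh` | the `afc` command line end to end |

## Command line

```bash
afc simulate  --scenario 2 --n 1000 --k 20 --beta 0.2 --out-prefix demo
afc build-null --phenotypes demo.pheno.tsv --genotypes demo.vcf \
              --permutations 100000 --out null.npz
afc test      --phenotypes demo.pheno.tsv --genotypes demo.vcf \
              --null-reference null.npz --methods afc,tates,manova --out out.tsv
afc test-from-pvalues --pvalues gwas_pvalues.tsv --null-reference null.npz \
              --out afc.tsv          # from an existing univariate GWAS
afc calibrate --scenario 1 --scenario 6 --alpha 0.01 --out calib.tsv
afc power     --scenario 3 --beta 0.1 --beta 0.2 --out power.tsv
```

Phenotypes are TSV (`sample_id` + one column per trait); genotypes are VCF
or PLINK `--recode A` (.raw); covariates are residualized out before
testing.

## Package layout

- `afcomb.scenarios` — factor-model simulation scenarios, HWE genotypes, writers
- `afcomb.univariate` — univariate score/t tests, covariate adjustment
- `afcomb.core` — partial sums, rank transfer, null reference, AFC, meta-AFC
- `afcomb.comparators` — TATES, Tippett, FC, MANOVA, MultiPhen, SUMSCORE
- `afcomb.experiments` — calibration / power harness, binomial CIs
- `afcomb.io` — TSV / VCF / PLINK-raw readers, sample alignment
- `docs/methods.md` — model details, conventions, numerical choices, limitations
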