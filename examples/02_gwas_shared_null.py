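"""GWAS-style screening: one permutation null, many variants.

The permutation null of the AFC partial-sum profile does not depend on
which variant is shuffled, so a single reference (built once, here with
B = 20,000 shuffles of the first variant) calibrates every variant in the
scan.  That turns a permutation test into a cheap vectorized lookup.
"""

import numpy as np

from afcomb import (ScenarioConfig, afc_pvalues_batch, build_null_reference,
                    generate_scenario, load_reference, save_reference)
from afcomb.univariate import batch_correlations, correlation_pvalues

rng = np.random.default_rng(11)

# phenotypes for one cohort; 2,000 independent null variants
Y, _ = generate_scenario(ScenarioConfig(scenario=6, n=2000, K=8), rng=rng)
mafs = rng.uniform(0.05, 0.5, size=2000)
X = rng.binomial(2, mafs, size=(Y.shape[0], 2000)).astype(float)

# build the reference from the first variant and save it for later runs
ref = build_null_reference(Y, X[:, 0], B=20_000, rng=rng)
save_reference("null_reference.npz", ref)
ref = load_reference("null_reference.npz")

# univariate p-values for all variants at once, then batch AFC
Yc = Y - Y.mean(0)
Xc = X - X.mean(0)
r = batch_correlations(Yc, Xc)                    # (variants, phenotypes)
P = correlation_pvalues(r, n=Y.shape[0])
pvals, k_star = afc_pvalues_batch(P, ref)

print(f"tested {len(pvals)} variants against B={ref.B} shared permutations")
print("rejections at 0.01 (expect ~20 under the null):",
      int((pvals <= 0.01).sum()))
ks, counts = np.unique(k_star, return_counts=True)
print("k* distribution:", {int(k): int(c) for k, c in zip(ks, counts)})

import os

os.remove("null_reference.npz")
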