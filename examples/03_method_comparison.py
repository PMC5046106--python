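"""Run all seven tests on one dataset and on its null counterpart.

AFC, Tippett (min-p) and Fisher's combination share one set of genotype
shuffles, so their exact relationships hold on identical permutations:
the transferred T_1 is Tippett's p-value and the transferred T_K is FC's.
"""

import numpy as np

from afcomb import ScenarioConfig, afc_test, generate_scenario
from afcomb.comparators import (fc_test, manova_wilks, multiphen,
                                sumscore_test, tates, tippett_test)
from afcomb.core import permutation_draws
from afcomb.univariate import univariate_pvalues

for beta, label in ((0.25, "variant affects 5 of 20 phenotypes"),
                    (0.0, "null variant")):
    cfg = ScenarioConfig(scenario=2, n=1000, K=20, beta=beta)
    Y, x = generate_scenario(cfg, rng=3)
    draws = permutation_draws(Y, x, B=10_000, rng=4)   # shared shuffles
    p_uni = univariate_pvalues(Y, x)
    R = np.corrcoef(Y, rowvar=False)

    res = afc_test(Y, x, draws=draws)
    print(f"\n{label} (beta={beta}):")
    print(f"  afc       {res.p_value:.4g}   (k* = {res.k_star})")
    print(f"  tippett   {tippett_test(draws=draws):.4g}"
          f"   == transferred T_1 {res.per_k_p[0]:.4g}")
    print(f"  fc        {fc_test(draws=draws):.4g}"
          f"   == transferred T_K {res.per_k_p[-1]:.4g}")
    print(f"  tates     {tates(p_uni, R):.4g}")
    print(f"  manova    {manova_wilks(Y, x):.4g}")
    print(f"  multiphen {multiphen(Y, x):.4g}")
    print(f"  sumscore  {sumscore_test(draws=draws):.4g}")
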