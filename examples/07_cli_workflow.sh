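#!/usr/bin/env bash
# End-to-end command-line workflow in a scratch directory:
# simulate -> build a shared null -> test with several methods -> calibrate.
set -euo pipefail
work=$(mktemp -d)
trap 'rm -rf "$work"' EXIT

# one dataset: 8 phenotypes, the variant hits the last one (scenario 4)
afc simulate --scenario 4 --n 500 --k 8 --beta 0.5 --seed 3 \
    --out-prefix "$work/demo"

# reusable permutation null built from the simulated variant
afc build-null --phenotypes "$work/demo.pheno.tsv" \
    --genotypes "$work/demo.vcf" --permutations 5000 --seed 1 \
    --out "$work/null.npz"

# fast path: AFC / Tippett / FC / TATES / MANOVA against the stored null
afc test --phenotypes "$work/demo.pheno.tsv" --genotypes "$work/demo.vcf" \
    --null-reference "$work/null.npz" \
    --methods afc,tippett,fc,tates,manova --out "$work/results.tsv"
cat "$work/results.tsv"

# small null-calibration table (reduced scale, ~30 s)
afc calibrate --scenario 1 --n 300 --k 4 --alpha 0.05 \
    --replicates 500 --permutations 500 --seed 0 --out "$work/calib.tsv"
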