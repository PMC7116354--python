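"""Reweight a small synthetic GWAS with pathway annotations.

Builds a 2,000-SNP toy GWAS in which SNPs in the genes of two pathways are
enriched for association, runs the full pipeline (local-FDR posteriors ->
LASSO prior model with cross-validated penalty -> cubic p-value weights),
and prints the most significant SNPs before and after reweighting.  Truly
associated SNPs in enriched pathways should gain significance (weight > 1)
while unannotated SNPs are mildly down-weighted.
"""

import numpy as np

import gwasprio as gp

stats, coords, genesets, delta = gp.toy_dataset(seed=1)
res = gp.reweight(stats, coords, genesets, scheme="cpw", lam="cv",
                  n_lambda=30, seed=0)

d = res.diagnostics
print(f"SNPs: {d['n_snps']}  pathways: {d['n_annotations']}  "
      f"equivalence classes: {d['n_classes']}")
print(f"estimated null proportion pi0 = {d['pi0']:.3f}")
print(f"CV-selected penalty lambda* = {d['lambda_star']:.4g}")
print(f"alternative Z distribution: N({d['alt_mu']:.2f}, {1 + d['alt_tau2']:.2f})")

wr = res.results["cpw"]
order = np.argsort(wr.p_weighted)[:10]
print("\ntop 10 SNPs after reweighting "
      "(true = simulated as associated):")
print(f"{'SNP':>14} {'p':>10} {'weight':>8} {'p_weighted':>11}  true")
for j in order:
    print(f"{stats.snp_id[j]:>14} {stats.p[j]:10.2e} {wr.weight[j]:8.3f} "
          f"{wr.p_weighted[j]:11.2e}  {bool(delta[j])}")

gain = (wr.p_weighted[delta] < stats.p[delta]).mean()
print(f"\nfraction of truly associated SNPs whose p-value improved: {gain:.2f}")
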