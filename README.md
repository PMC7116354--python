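# gwasprio

Pathway-knowledge-guided prioritization of GWAS results.

Many truly associated variants sit just below the genome-wide significance
threshold.  When the genes of a disease cluster into a few biological
pathways, that clustering is information a standard GWAS ignores.
`gwasprio` takes ordinary summary statistics (SNP, chromosome, position,
p-value), a gene coordinate table (BED) and a list of gene sets (GMT),
learns **from the data** how enriched each gene set is for association
signal, and reweights the p-values so that SNPs in empirically enriched
pathways face a smaller multiple-testing penalty — while the family-wise
error rate is preserved, so the usual 5e-8 threshold still applies to the
weighted p-values.

## Method in brief

Z-scores `Z_j = Phi^{-1}(1 - P_j)` follow a two-group mixture
`Z_j ~ (1-delta_j) N(0,1) + delta_j N(mu, 1+tau^2)` with
`logit Pr(delta_j = 1) = kappa + beta' V_j`, where `V_j` is SNP j's binary
pathway-annotation row.  Instead of maximizing the mixture likelihood, a
two-step estimator is used:

1. local-FDR posteriors `psi_j = 1 - lfdr(z_j)` (theoretical N(0,1) null,
   Poisson-spline density estimate);
2. LASSO-penalized logistic regression of class-mean `psi` on the
   annotations, after merging SNPs with identical annotation rows into
   equivalence classes (class sizes as weights).  Fitted values are the
   per-class prior probabilities of association, with the penalty chosen by
   segment-preserving half-split cross-validation.

Priors become p-value weights `w_i` with `sum_i n_i w_i / M = 1` — either
proportional to the prior odds (**simple weighting, SPW**) or
`exp(cubic in the prior log-odds)` with coefficients maximizing the expected
number of true positives (**cubic weighting, CPW**).  Weighted p-values are
`min(1, p_j / w_i)`.

See [docs/methods.md](docs/methods.md) for the full model, estimation
details, the simulation design and known limitations.

## Worked example

```python
import gwasprio as gp

# 2,000-SNP synthetic GWAS in which two pathways are enriched for signal
stats, coords, genesets, truth = gp.toy_dataset(seed=1)
res = gp.reweight(stats, coords, genesets, scheme="cpw", lam="cv", seed=0)
print(res.diagnostics["pi0"], res.diagnostics["lambda_star"])
```

Running [examples/reweight_toy_gwas.py](examples/reweight_toy_gwas.py)
prints:

```
SNPs: 2000  pathways: 20  equivalence classes: 63
estimated null proportion pi0 = 0.901
CV-selected penalty lambda* = 2.071
alternative Z distribution: N(1.49, 4.05)

top 10 SNPs after reweighting (true = simulated as associated):
           SNP          p   weight  p_weighted  true
  rs71_9524000   3.38e-07    2.803    1.21e-07  True
   rs8_2008000   6.41e-07    3.498    1.83e-07  True
   ...
fraction of truly associated SNPs whose p-value improved: 1.00
```

`pi0` is the estimated fraction of null SNPs; `lambda*` the
cross-validated LASSO penalty; each SNP's `weight` multiplies its chance of
discovery (weights average 1 across the genome, so error control is
unchanged), and `p_weighted = p / weight` is what you compare against 5e-8.
The other example scripts show a whole-genome Type-1/power simulation
(`examples/simulation_study.py`) and the shrinkage path with
cross-validated penalty choice (`examples/penalty_path_and_cv.py`).

## Command line

```bash
gwasprio fixtures --out-dir demo/                  # write a toy dataset
gwasprio reweight --summary demo/summary.tsv --genes demo/genes.bed \
         --gene-sets demo/pathways.gmt --scheme cpw --lambda cv \
         --out results.tsv --diagnostics diag.json
gwasprio simulate --scenario scenario.yaml --out report.json
```

`reweight` writes a TSV with columns `SNP CHR BP P WEIGHT P_WEIGHTED
CLASS_ID` (header lines echo every effective parameter); `simulate` runs the
whole-genome case/control simulation described in the methods note and
reports Type-1 error and power per weighting scheme.

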