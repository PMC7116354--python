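"""Whole-genome simulation: Type-1 error and power of weighted analysis.

Simulates a scaled-down case/control GWAS (10 causal loci among 20,000 null
SNPs, 1,500 cases / 1,500 controls) with a synthetic pathway list in which
the causal genes cluster, then compares unweighted analysis with simple
(SPW) and cubic (CPW) p-value weighting.  Expected outcome: Type-1 error at
or below each level for all methods, and higher power for the weighted
analyses at stringent levels.
"""

import gwasprio as gp

scenario = gp.SimScenario(causal_specs=gp.example_causal_loci(10),
                          n_null_snps=20_000, n_replicates=10, seed=7)
pathway_config = gp.SyntheticPathwayConfig(n_true_pathways=20,
                                           true_genes_per_pathway=5)
study = gp.run_simulation_study(scenario, pathway_config, n_lambda=15,
                                levels=(1e-1, 1e-3, 1e-5))

print(f"replicates: {scenario.n_replicates}, null SNPs per replicate: "
      f"{study.reports['unweighted'].n_null}, causal SNPs: "
      f"{study.reports['unweighted'].n_causal}")
print(f"mean CV-selected penalty: {study.lambda_stars.mean():.3f}\n")
print(f"{'level':>8} | {'Type-1 unw':>10} {'spw':>8} {'cpw':>8} | "
      f"{'power unw':>9} {'spw':>7} {'cpw':>7}")
for i, level in enumerate(study.reports["unweighted"].levels):
    row = [study.reports[m].type1[i] for m in ("unweighted", "spw", "cpw")]
    pw = [study.reports[m].power[i] for m in ("unweighted", "spw", "cpw")]
    print(f"{level:8.0e} | {row[0]:10.2e} {row[1]:8.2e} {row[2]:8.2e} | "
          f"{pw[0]:9.3f} {pw[1]:7.3f} {pw[2]:7.3f}")

print("\nType-1 columns should sit at or below each level (up to Monte-Carlo "
      "noise at the most stringent levels, where only a handful of "
      "rejections are expected); weighted power should match or beat "
      "unweighted.")
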