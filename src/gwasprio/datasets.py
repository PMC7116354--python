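"""Small bundled synthetic datasets for examples, tests and smoke runs.

Everything here is generated programmatically and deterministically; nothing
is derived from real genotype or pathway databases.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import GeneCoordinates, GeneSetCollection, SummaryStats


def toy_dataset(n_snps: int = 2000, n_genes: int = 100, n_pathways: int = 20,
                genes_per_pathway: int = 8, n_enriched: int = 2,
                prior_in_enriched: float = 0.3, alt_mean: float = 3.0,
                seed: int = 0):
    """A small, fully synthetic GWAS with pathway-enriched signal.

    ``n_genes`` genes are tiled over four chromosomes, each hosting an equal
    share of the ``n_snps`` SNPs.  ``n_pathways`` pathways of
    ``genes_per_pathway`` genes are drawn at random; SNPs in genes of the
    first ``n_enriched`` pathways are associated (``z ~ N(alt_mean, 1)``)
    with probability ``prior_in_enriched``, all other SNPs are null N(0,1).

    Returns
    -------
    (SummaryStats, GeneCoordinates, GeneSetCollection, delta)
        ``delta`` is the per-SNP truth indicator.
    """
    rng = np.random.default_rng(seed)
    snps_per_gene = n_snps // n_genes
    rows, coord_rows = [], []
    gene_of_snp = []
    for g in range(n_genes):
        gene = f"G{g + 1:03d}"
        chrom = str(g % 4 + 1)
        base = 1_000_000 + (g // 4) * 500_000
        pos = base + np.arange(snps_per_gene) * 2_000
        coord_rows.append((gene, chrom, int(pos.min() - 1), int(pos.max())))
        for p in pos:
            rows.append((f"rs{g}_{p}", chrom, int(p)))
            gene_of_snp.append(gene)
    # remainder SNPs land in a gene desert on chromosome 5
    for j in range(n_snps - n_genes * snps_per_gene):
        rows.append((f"rs_desert_{j}", "5", 1_000_000 + j * 2_000))
        gene_of_snp.append(None)

    genes = [f"G{g + 1:03d}" for g in range(n_genes)]
    sets = []
    for k in range(n_pathways):
        members = rng.choice(genes, genes_per_pathway, replace=False)
        sets.append((f"P{k + 1:02d}", frozenset(members)))
    genesets = GeneSetCollection(sets)

    enriched_genes = set().union(*(genesets.sets[k][1] for k in range(n_enriched)))
    delta = np.array([g in enriched_genes and rng.random() < prior_in_enriched
                      for g in gene_of_snp])
    z = rng.standard_normal(n_snps)
    z[delta] += alt_mean
    p = np.clip(norm.sf(z), 1e-300, 1 - 1e-16)

    table = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    stats = SummaryStats(table["snp"].to_numpy(object),
                         table["chrom"].to_numpy(object),
                         table["pos"].to_numpy(np.int64), p)
    coords = GeneCoordinates(pd.DataFrame(
        coord_rows, columns=["gene", "chrom", "start", "end"]))
    return stats, coords, genesets, delta


def write_toy_files(out_dir, **kwargs) -> dict:
    """Write the toy dataset as summary.tsv / genes.bed / pathways.gmt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats, coords, genesets, _ = toy_dataset(**kwargs)
    paths = {"summary": out / "summary.tsv", "genes": out / "genes.bed",
             "gene_sets": out / "pathways.gmt"}
    stats.to_frame().to_csv(paths["summary"], sep="\t", index=False)
    coords.table[["chrom", "start", "end", "gene"]].to_csv(
        paths["genes"], sep="\t", index=False, header=False)
    with open(paths["gene_sets"], "w") as fh:
        for name, genes in genesets:
            fh.write("\t".join([name, "synthetic"] + sorted(genes)) + "\n")
    return paths
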