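"""Whole-genome retrospective case/control simulation for method evaluation.

The design: a set of independent causal loci with given control-population
minor allele frequencies and per-allele odds ratios is simulated
retrospectively for fixed case/control counts; each causal locus carries an
associated region of SNPs within +/- 1 Mb whose Z-scores decay in
correlation with distance; all remaining SNPs are null N(0,1).  Synthetic
pathway lists with tunable connectivity (number of enriched pathways and
causal genes per enriched pathway) provide the gene-level annotations, and
every simulated SNP maps positionally to exactly its host gene.

Type-1 error is measured on SNPs outside all +/- 1 Mb causal windows; power
is measured on the causal SNPs themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import GeneCoordinates, GeneSetCollection, SummaryStats

P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16


@dataclass
class CausalSpec:
    """One causal locus: position, control-population MAF, per-allele OR."""

    chrom: str
    pos: int
    maf: float
    odds_ratio: float
    gene: str

    def __post_init__(self):
        if not 0 < self.maf <= 0.5:
            raise ValueError("MAF must lie in (0, 0.5]")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be > 0")

    @property
    def case_maf(self) -> float:
        """Case-population allele frequency implied by the per-allele OR."""
        p0, r = self.maf, self.odds_ratio
        return r * p0 / (1 - p0 + r * p0)


def example_causal_loci(n_loci: int = 25) -> list:
    """A synthetic illustrative set of causal loci.

    MAFs span 0.1-0.4 and per-allele ORs span 1.2-1.6 — the range typical of
    suggestive GWAS loci for a common complex disease.  The values are
    invented for simulation studies, not taken from any catalog; the OR
    sequence is rotated against the MAF sequence so the two are not
    co-monotone.
    """
    mafs = np.round(np.linspace(0.1, 0.4, n_loci), 4)
    ors = np.round(np.roll(np.linspace(1.2, 1.6, n_loci), n_loci // 3), 4)
    return [CausalSpec(chrom=str(i % 22 + 1),
                       pos=2_000_000 + (i // 22) * 6_000_000,
                       maf=float(mafs[i]), odds_ratio=float(ors[i]),
                       gene=f"CGENE{i + 1:02d}")
            for i in range(n_loci)]


@dataclass
class SimScenario:
    """Configuration of one whole-genome simulation study."""

    causal_specs: list = field(default_factory=example_causal_loci)
    n_cases: int = 1500
    n_controls: int = 1500
    n_null_snps: int = 100_000
    snps_per_region: int = 20           # non-causal SNPs per associated region
    region_halfwidth_bp: int = 1_000_000
    ld_decay_bp: float = 50_000.0
    n_null_genes: int | None = None     # default: one null gene per 50 null SNPs
    null_snp_spacing_bp: int = 1_000
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.n_null_genes is None:
            self.n_null_genes = max(1, self.n_null_snps // 50)


@dataclass
class TruthLabels:
    """Per-SNP ground truth of a simulated study."""

    delta: np.ndarray       # causal indicator
    in_region: np.ndarray   # within +/- region_halfwidth of a causal SNP
    gene: np.ndarray        # host gene symbol

    @property
    def is_null(self) -> np.ndarray:
        return ~self.in_region


@dataclass
class SnpMap:
    """Static SNP layout of a scenario (identical across replicates)."""

    table: pd.DataFrame          # snp, chrom, pos, gene, is_causal, in_region,
                                 # locus (causal-locus index, -1 outside regions)
    coords: GeneCoordinates
    causal_genes: list
    null_genes: list

    def truth(self) -> TruthLabels:
        t = self.table
        return TruthLabels(t["is_causal"].to_numpy(bool),
                           t["in_region"].to_numpy(bool),
                           t["gene"].to_numpy(object))

    def base_stats(self) -> SummaryStats:
        t = self.table
        return SummaryStats(t["snp"].to_numpy(object), t["chrom"].to_numpy(object),
                            t["pos"].to_numpy(np.int64), np.full(len(t), 0.5))


def build_snp_map(scenario: SimScenario) -> SnpMap:
    """Lay out causal regions and null-gene blocks deterministically.

    Each causal locus gets ``snps_per_region`` SNPs evenly spaced across its
    +/- 1 Mb window plus the causal SNP itself, all hosted by the causal
    gene.  Null SNPs are tiled in contiguous blocks, one block per null gene,
    placed far (>= 10 Mb) from every causal window.  Gene intervals exactly
    cover their SNPs and are pairwise disjoint, so positional mapping at
    flank 0 assigns every SNP to exactly its host gene.
    """
    rows = []
    coord_rows = []
    causal_genes = []
    for li, spec in enumerate(scenario.causal_specs):
        offs = np.linspace(-scenario.region_halfwidth_bp,
                           scenario.region_halfwidth_bp,
                           scenario.snps_per_region + 2)[1:-1]
        offs = np.round(offs[offs != 0]).astype(np.int64)
        positions = np.sort(np.r_[spec.pos, spec.pos + offs])
        for pos in positions:
            is_c = pos == spec.pos
            rows.append((f"rs_l{li}_{pos}", spec.chrom, int(pos), spec.gene,
                         is_c, True, li))
        coord_rows.append((spec.gene, spec.chrom,
                           int(positions.min() - 1), int(positions.max())))
        causal_genes.append(spec.gene)

    null_genes = []
    per_gene = np.full(scenario.n_null_genes, scenario.n_null_snps // scenario.n_null_genes)
    per_gene[: scenario.n_null_snps % scenario.n_null_genes] += 1
    block_span = (per_gene.max() + 1) * scenario.null_snp_spacing_bp + 10_000
    for g in range(scenario.n_null_genes):
        if per_gene[g] == 0:
            continue
        gene = f"NGENE{g + 1:05d}"
        chrom = str(g % 22 + 1)
        base = 20_000_000 + (g // 22) * block_span
        pos = base + np.arange(per_gene[g], dtype=np.int64) * scenario.null_snp_spacing_bp
        for p in pos:
            rows.append((f"rs_n{g}_{p}", chrom, int(p), gene, False, False, -1))
        coord_rows.append((gene, chrom, int(pos.min() - 1), int(pos.max())))
        null_genes.append(gene)

    table = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "gene",
                                        "is_causal", "in_region", "locus"])
    coords = GeneCoordinates(pd.DataFrame(coord_rows,
                                          columns=["gene", "chrom", "start", "end"]))
    return SnpMap(table, coords, causal_genes, null_genes)


def simulate_causal_z(spec: CausalSpec, n_cases: int, n_controls: int,
                      rng: np.random.Generator) -> float:
    """Simulate the allelic-test Z-score of one causal locus.

    Case allele frequency follows from the per-allele odds ratio,
    ``p1 = OR p0 / (1 - p0 + OR p0)``; allele counts are drawn binomially
    (Hardy-Weinberg within each group) and the signed Z is the standard
    allelic test ``(phat1 - phat0) / SE`` with pooled-frequency SE.
    """
    import warnings

    p0, p1 = spec.maf, spec.case_maf
    a1 = rng.binomial(2 * n_cases, p1)
    a0 = rng.binomial(2 * n_controls, p0)
    exp_min = min(2 * n_cases * p1, 2 * n_cases * (1 - p1),
                  2 * n_controls * p0, 2 * n_controls * (1 - p0))
    if exp_min < 5:
        warnings.warn("expected allele count < 5: normal approximation unreliable",
                      stacklevel=2)
    ph1, ph0 = a1 / (2 * n_cases), a0 / (2 * n_controls)
    pbar = (a1 + a0) / (2 * n_cases + 2 * n_controls)
    se = np.sqrt(pbar * (1 - pbar) * (1 / (2 * n_cases) + 1 / (2 * n_controls)))
    return float((ph1 - ph0) / se) if se > 0 else 0.0


def analytic_mean_z(spec: CausalSpec, n_cases: int, n_controls: int) -> float:
    """Closed-form large-sample mean of the allelic-test Z (sqrt of the
    noncentrality parameter) — the oracle for the simulated causal Z."""
    p0, p1 = spec.maf, spec.case_maf
    pbar = (n_cases * p1 + n_controls * p0) / (n_cases + n_controls)
    se = np.sqrt(pbar * (1 - pbar) * (1 / (2 * n_cases) + 1 / (2 * n_controls)))
    return float((p1 - p0) / se)


def simulate_replicate(scenario: SimScenario, rng: np.random.Generator,
                       snp_map: SnpMap | None = None):
    """Simulate one replicate of genome-wide summary statistics.

    Causal Z-scores come from :func:`simulate_causal_z`; a region SNP at
    distance ``d`` from its causal SNP gets
    ``Z = r Z_c + sqrt(1 - r^2) eps`` with ``r = exp(-d / ld_decay_bp)``;
    all other SNPs are independent N(0,1).  One-sided p-values
    ``p = 1 - Phi(Z)``.
    """
    if snp_map is None:
        snp_map = build_snp_map(scenario)
    t = snp_map.table
    M = len(t)
    z = rng.standard_normal(M)

    locus = t["locus"].to_numpy()
    pos = t["pos"].to_numpy(np.int64)
    for li, spec in enumerate(scenario.causal_specs):
        zc = simulate_causal_z(spec, scenario.n_cases, scenario.n_controls, rng)
        in_locus = locus == li
        d = np.abs(pos[in_locus] - spec.pos).astype(float)
        r = np.exp(-d / scenario.ld_decay_bp)
        # at the causal SNP d=0 so r=1 and Z equals zc exactly
        z[in_locus] = r * zc + np.sqrt(1.0 - r ** 2) * z[in_locus]

    p = np.clip(norm.sf(z), P_FLOOR, P_CEIL)
    stats = SummaryStats(t["snp"].to_numpy(object), t["chrom"].to_numpy(object),
                         pos, p, z)
    return stats, snp_map.truth()


@dataclass
class SyntheticPathwayConfig:
    """Connectivity design of a synthetic pathway list.

    ``n_true_pathways`` (Tp) pathways are enriched: each holds
    ``true_genes_per_pathway`` (Tg) causal genes sampled with replacement
    across pathways (without replacement within a pathway), padded with null
    genes up to ``genes_per_pathway``.  The remaining pathways hold only null
    genes.  Larger Tg with smaller Tp means higher connectivity among causal
    genes.
    """

    n_true_pathways: int
    true_genes_per_pathway: int
    n_pathways_total: int = 100
    genes_per_pathway: int = 20

    def __post_init__(self):
        if self.n_true_pathways > self.n_pathways_total:
            raise ValueError("more true pathways than pathways in total")
        if self.true_genes_per_pathway > self.genes_per_pathway:
            raise ValueError("more causal genes than genes per pathway")


def make_synthetic_pathways(config: SyntheticPathwayConfig, causal_genes: list,
                            null_genes: list,
                            rng: np.random.Generator) -> GeneSetCollection:
    """Generate a pathway list with the requested causal-gene connectivity."""
    if config.true_genes_per_pathway > len(causal_genes):
        raise ValueError("true_genes_per_pathway exceeds the causal gene count")
    n_fill = config.genes_per_pathway - config.true_genes_per_pathway
    if config.genes_per_pathway > len(null_genes):
        raise ValueError("not enough null genes to fill pathways")
    sets = []
    for k in range(config.n_pathways_total):
        if k < config.n_true_pathways:
            genes = list(rng.choice(causal_genes, config.true_genes_per_pathway,
                                    replace=False))
            genes += list(rng.choice(null_genes, n_fill, replace=False))
        else:
            genes = list(rng.choice(null_genes, config.genes_per_pathway,
                                    replace=False))
        sets.append((f"PATHWAY{k + 1:03d}", frozenset(g.upper() for g in genes)))
    return GeneSetCollection(sets)


@dataclass
class EvalReport:
    """Type-1 error and power of one analysis across replicates."""

    levels: np.ndarray
    type1: np.ndarray            # per level: replicate-mean null rejection rate
    power: np.ndarray            # per level: pooled causal rejection rate
    per_snp_power: np.ndarray    # causal SNPs x levels
    n_null: int
    n_causal: int
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"level": self.levels, "type1_error": self.type1,
                             "power": self.power})

    def to_json_dict(self) -> dict:
        return {"levels": self.levels.tolist(), "type1": self.type1.tolist(),
                "power": self.power.tolist(), "n_null": self.n_null,
                "n_causal": self.n_causal, "n_replicates": self.n_replicates}


DEFAULT_LEVELS = (1e-1, 1e-2, 1e-3, 1e-5, 1e-7)


def evaluate(pvalue_replicates, truth: TruthLabels,
             levels=DEFAULT_LEVELS) -> EvalReport:
    """Empirical global Type-1 error and power across replicates.

    Type-1 error at level t: fraction of null SNPs (outside all causal
    windows) with p <= t, averaged over replicates.  Power at t: fraction of
    causal SNPs with p <= t, pooled over replicates (also reported per causal
    SNP).
    """
    levels = np.asarray(levels, dtype=float)
    null_mask, causal_mask = truth.is_null, truth.delta
    if not null_mask.any():
        raise ValueError("no null SNPs: Type-1 error undefined")
    P = np.asarray(pvalue_replicates, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    R = P.shape[0]
    type1 = np.array([np.mean(P[:, null_mask] <= t) for t in levels])
    if causal_mask.any():
        hits = np.stack([(P[:, causal_mask] <= t).mean(axis=0) for t in levels], axis=1)
        power = np.array([np.mean(P[:, causal_mask] <= t) for t in levels])
    else:
        hits = np.zeros((0, len(levels)))
        power = np.zeros(len(levels))
    return EvalReport(levels, type1, power, hits, int(null_mask.sum()),
                      int(causal_mask.sum()), R)
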