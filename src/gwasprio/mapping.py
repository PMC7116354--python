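"""SNP-to-pathway mapping and equivalence-class compression.

A SNP is annotated to a pathway when it falls inside (or within ``flank_bp``
of) any gene of that pathway.  SNPs sharing a bit-identical annotation row
are merged into an equivalence class; downstream model fitting operates on
the (much smaller) class-level data with class sizes as weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .io import GeneCoordinates, GeneSetCollection, SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMatrix:
    """Sparse binary SNP x annotation incidence matrix.

    Row order matches the :class:`~gwasprio.io.SummaryStats` the matrix was
    built from.  All-zero rows (unmapped SNPs) are retained; all-zero columns
    are dropped at construction.
    """

    V: sp.csr_matrix
    annotation_names: list
    snp_id: np.ndarray

    def __post_init__(self):
        self.V = sp.csr_matrix(self.V, dtype=np.int8)
        if self.V.shape[1] != len(self.annotation_names):
            raise ValueError("annotation name count does not match matrix width")
        if self.V.shape[0] != len(self.snp_id):
            raise ValueError("SNP id count does not match matrix height")
        if self.V.nnz and not np.all(self.V.data == 1):
            raise ValueError("annotation matrix entries must be 0/1")

    @property
    def n_snps(self) -> int:
        return self.V.shape[0]

    @property
    def n_annotations(self) -> int:
        return self.V.shape[1]


@dataclass
class EquivalenceClasses:
    """Partition of SNPs into classes with identical annotation rows.

    Attributes
    ----------
    class_of_snp : int array, length M
        Class index of each SNP (row order of the annotation matrix).
    V_classes : csr matrix, C x K
        Representative annotation row per class.
    sizes : int array, length C
        Class sizes ``n_i``; ``sizes.sum() == M``.
    psibar : float array or None
        Class-mean marginal posterior probability of association, filled by
        :func:`gwasprio.enrichment.class_mean_mppa`.
    """

    class_of_snp: np.ndarray
    V_classes: sp.csr_matrix
    sizes: np.ndarray
    annotation_names: list
    psibar: np.ndarray | None = None

    def __post_init__(self):
        self.class_of_snp = np.asarray(self.class_of_snp, dtype=np.int64)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.sum() != len(self.class_of_snp):
            raise ValueError("class sizes must sum to the number of SNPs")
        if self.V_classes.shape[0] != len(self.sizes):
            raise ValueError("one representative row per class required")

    @property
    def n_classes(self) -> int:
        return len(self.sizes)

    @property
    def n_snps(self) -> int:
        return len(self.class_of_snp)

    def with_psibar(self, psibar: np.ndarray) -> "EquivalenceClasses":
        return replace(self, psibar=np.asarray(psibar, dtype=float))

    def expand(self, class_values: np.ndarray) -> np.ndarray:
        """Broadcast per-class values back to SNPs, preserving SNP order."""
        return np.asarray(class_values)[self.class_of_snp]


def map_snps_to_pathways(stats: SummaryStats, coords: GeneCoordinates,
                         genesets: GeneSetCollection,
                         flank_bp: int = 0) -> AnnotationMatrix:
    """Build the binary SNP x pathway incidence matrix.

    A SNP at 1-based position ``pos`` maps to a gene interval
    ``[start, end)`` (0-based half-open) iff
    ``start - flank_bp <= pos - 1 < end + flank_bp``, and to a pathway iff it
    maps to at least one of the pathway's genes.  Pathway genes absent from
    the coordinate table are ignored (count logged); pathways with zero
    mapped SNPs are dropped (names logged).
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    pos0 = stats.pos - 1  # to 0-based

    # index SNPs per chromosome once
    snp_by_chrom: dict = {}
    for chrom in np.unique(stats.chrom):
        idx = np.flatnonzero(stats.chrom == chrom)
        order = np.argsort(pos0[idx], kind="stable")
        snp_by_chrom[chrom] = (idx[order], pos0[idx[order]])

    # per-gene SNP hits, computed once and shared across pathways
    gene_hits: dict = {}
    for gene, grp in coords.table.groupby("gene", sort=False):
        hits = []
        for chrom, s, e in grp[["chrom", "start", "end"]].itertuples(index=False):
            if chrom not in snp_by_chrom:
                continue
            idx, sorted_pos = snp_by_chrom[chrom]
            lo = np.searchsorted(sorted_pos, s - flank_bp, side="left")
            hi = np.searchsorted(sorted_pos, e + flank_bp, side="left")
            if hi > lo:
                hits.append(idx[lo:hi])
        gene_hits[gene] = (np.unique(np.concatenate(hits))
                           if hits else np.empty(0, dtype=np.int64))

    rows, cols, kept_names = [], [], []
    k = 0
    for name, genes in genesets:
        known = [g for g in genes if g in gene_hits]
        n_missing = len(genes) - len(known)
        if n_missing:
            logger.info("pathway %s: %d gene(s) absent from coordinates", name, n_missing)
        if not known:
            logger.info("pathway %s dropped: no genes with coordinates", name)
            continue
        snps = np.unique(np.concatenate([gene_hits[g] for g in known]))
        if snps.size == 0:
            logger.info("pathway %s dropped: zero mapped SNPs", name)
            continue
        rows.append(snps)
        cols.append(np.full(snps.size, k, dtype=np.int64))
        kept_names.append(name)
        k += 1

    M = stats.n_snps
    if k == 0:
        V = sp.csr_matrix((M, 0), dtype=np.int8)
    else:
        V = sp.coo_matrix(
            (np.ones(sum(r.size for r in rows), dtype=np.int8),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(M, k)).tocsr()
    return AnnotationMatrix(V, kept_names, stats.snp_id)


def collapse_equivalence_classes(annot: AnnotationMatrix) -> EquivalenceClasses:
    """Group SNPs with bit-identical annotation rows into equivalence classes.

    Classes are ordered by first occurrence in SNP order.
    """
    V = annot.V.tocsr()
    key_to_class: dict = {}
    class_of_snp = np.empty(V.shape[0], dtype=np.int64)
    rep_rows = []
    indptr, indices = V.indptr, V.indices
    for j in range(V.shape[0]):
        key = indices[indptr[j]:indptr[j + 1]].tobytes()
        cid = key_to_class.get(key)
        if cid is None:
            cid = len(rep_rows)
            key_to_class[key] = cid
            rep_rows.append(j)
        class_of_snp[j] = cid
    sizes = np.bincount(class_of_snp, minlength=len(rep_rows))
    V_classes = V[np.asarray(rep_rows)]
    return EquivalenceClasses(class_of_snp, V_classes, sizes, list(annot.annotation_names))
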