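"""Readers and writers for GWAS summary statistics, gene sets and gene coordinates.

Conventions
-----------
* Summary statistics are tab-delimited with a header; default column names
  are ``SNP``, ``CHR``, ``BP``, ``P``.  Base-pair positions are read 1-based.
* Gene coordinates are BED4 (``chrom  start  end  name``), 0-based
  half-open, and multiple records per gene symbol are unioned per chromosome.
* Gene sets are GMT: one pathway per line, tab-separated
  ``name  description  gene1  gene2 ...``.
* Chromosome labels are normalized so that ``chr1`` and ``1`` compare equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: p-values equal to 1 are pulled just inside (0, 1) so the probit transform
#: stays finite.
P_ONE_CLAMP = 1.0 - 1e-16

DEFAULT_COLUMNS = {"snp": "SNP", "chrom": "CHR", "pos": "BP", "p": "P"}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in its declared dialect."""


class EmptyInputError(ValueError):
    """Raised when a file parses but yields zero usable records."""


def normalize_chrom(chrom) -> str:
    """Normalize a chromosome label: strip a leading 'chr', uppercase X/Y/MT."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() if c.lower() in ("x", "y", "mt", "m") else c


@dataclass
class SummaryStats:
    """Per-SNP GWAS summary statistics.

    Attributes
    ----------
    snp_id, chrom, pos, p : arrays of equal length M
        SNP identifier, normalized chromosome, 1-based position and
        two-sided-reported p-value in (0, 1].
    z : array or None
        One-sided Z-score ``z = Phi^{-1}(1 - p)``; ``None`` until computed by
        :func:`gwasprio.enrichment.pvalues_to_zscores`.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    p: np.ndarray
    z: np.ndarray | None = None

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.p = np.asarray(self.p, dtype=float)
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
        m = len(self.snp_id)
        if not (len(self.chrom) == len(self.pos) == len(self.p) == m):
            raise ValueError("summary-stat fields have unequal lengths")
        if m == 0:
            raise EmptyInputError("no usable SNPs")
        if np.any(self.p <= 0) or np.any(self.p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        if np.any(self.pos < 0):
            raise ValueError("positions must be non-negative")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def with_z(self, z: np.ndarray) -> "SummaryStats":
        return replace(self, z=np.asarray(z, dtype=float))

    def subset(self, idx) -> "SummaryStats":
        return SummaryStats(
            self.snp_id[idx], self.chrom[idx], self.pos[idx], self.p[idx],
            None if self.z is None else self.z[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"SNP": self.snp_id, "CHR": self.chrom, "BP": self.pos, "P": self.p}
        if self.z is not None:
            d["Z"] = self.z
        return pd.DataFrame(d)


@dataclass
class GeneCoordinates:
    """Gene intervals, 0-based half-open, unioned per (gene, chromosome)."""

    table: pd.DataFrame  # columns: gene, chrom, start, end

    def __post_init__(self):
        t = self.table
        if np.any(t["start"].to_numpy() >= t["end"].to_numpy()):
            raise ValueError("gene intervals must satisfy start < end")

    @property
    def genes(self) -> set:
        return set(self.table["gene"])


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways); symbols upper-cased, unique per set."""

    sets: list = field(default_factory=list)  # list of (name, frozenset)

    def __post_init__(self):
        names = [n for n, _ in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("pathway names must be unique")
        if any(len(g) == 0 for _, g in self.sets):
            raise ValueError("empty gene sets are not allowed")

    @property
    def names(self) -> list:
        return [n for n, _ in self.sets]

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_summary_stats(path, column_map: dict | None = None) -> SummaryStats:
    """Read a tab-delimited summary-statistics table.

    Rows with missing, non-numeric or out-of-range p-values (p <= 0 or p > 1)
    are dropped with a logged count; p = 1 is clamped to ``1 - 1e-16``.
    Duplicate SNP ids keep the first occurrence.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path, sep="\t", dtype={cols["snp"]: str, cols["chrom"]: str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse summary statistics {path}: {exc}") from exc
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    df = df.rename(columns={v: k for k, v in cols.items()})
    n_in = len(df)
    df["p"] = pd.to_numeric(df["p"], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    keep = df["p"].notna() & (df["p"] > 0) & (df["p"] <= 1) & df["pos"].notna()
    n_drop = n_in - int(keep.sum())
    if n_drop:
        logger.warning("%s: dropped %d rows with missing/out-of-range p or position",
                       path, n_drop)
    df = df[keep]
    dup = df["snp"].duplicated()
    if dup.any():
        logger.warning("%s: dropped %d duplicate SNP ids", path, int(dup.sum()))
        df = df[~dup]
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no usable rows")
    p = df["p"].to_numpy(float)
    p = np.where(p >= 1.0, P_ONE_CLAMP, p)
    return SummaryStats(
        df["snp"].to_numpy(object),
        np.array([normalize_chrom(c) for c in df["chrom"]], dtype=object),
        df["pos"].to_numpy(np.int64),
        p,
    )


def write_summary_stats(stats: SummaryStats, path) -> None:
    stats.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file. Symbols are upper-cased and deduplicated per set."""
    sets, seen = [], set()
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name = fields[0]
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            seen.add(name)
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if genes:
                sets.append((name, genes))
    if not sets:
        raise EmptyInputError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def _union_intervals(iv: np.ndarray) -> np.ndarray:
    """Union of sorted [start, end) rows; input shape (n, 2)."""
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out)


def read_gene_coords(path) -> GeneCoordinates:
    """Read BED4 gene coordinates; transcripts of a symbol are unioned."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "gene"],
                         dtype={"chrom": str, "gene": str})
    except Exception as exc:
        raise FormatError(f"cannot parse BED file {path}: {exc}") from exc
    if df["gene"].isna().any():
        raise FormatError(f"{path}: BED4 requires a name column")
    bad = df["start"] >= df["end"]
    if bad.any():
        logger.warning("%s: rejected %d records with start >= end", path, int(bad.sum()))
        df = df[~bad]
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no usable gene records")
    df = df.assign(chrom=[normalize_chrom(c) for c in df["chrom"]],
                   gene=df["gene"].str.upper())
    rows = []
    for (gene, chrom), grp in df.groupby(["gene", "chrom"], sort=True):
        for s, e in _union_intervals(grp[["start", "end"]].to_numpy(np.int64)):
            rows.append((gene, chrom, int(s), int(e)))
    table = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    return GeneCoordinates(table)
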