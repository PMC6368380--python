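"""Pooled variant input/output and hard filtering.

A pooled-sequencing "sample" is a library made from equimolar DNA of many
individuals, so a variant record carries per-pool *read counts* for the two
alleles rather than genotypes.  The in-memory container, :class:`SiteTable`,
is column-oriented (NumPy arrays over sites x pools) so that the genome scan
stays vectorized; :class:`PooledSiteCounts` is the scalar per-site view used
by the formula-level API and by tests.

Supported dialects: VCF 4.2 with an ``AD`` (allelic depth) FORMAT field, and
popoolation2 ``sync`` text (``A:T:C:G:N:del`` count strings per pool).

The hard filters mirror a standard post-calling screen for pooled data:
per-pool depth bounds, a pooled minor-allele-frequency floor, a maximum
INDEL length, and GATK-style annotation thresholds (QD/FS/MQ/rank sums)
evaluated only when the annotations are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, ParseError, ZeroDepthError

__all__ = [
    "PooledSiteCounts",
    "SiteTable",
    "FilterConfig",
    "FilterReport",
    "read_pooled_vcf",
    "read_sync",
    "write_vcf",
    "write_sync",
    "filter_variants",
    "pool_allele_frequency",
]

MISSING = -1  # sentinel for absent per-pool counts

ANNOTATION_FIELDS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

_BASES = "ATCG"
_SYNC_ORDER = "ATCGN"  # + "del" as 6th column


@dataclass(frozen=True)
class PooledSiteCounts:
    """One biallelic site with per-pool ref/alt read counts (the analysis atom)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    counts: Mapping[str, tuple[int, int] | None]  # pool -> (ref_reads, alt_reads)
    is_indel: bool = False
    indel_len: int = 0
    is_biallelic: bool = True
    annotations: Mapping[str, float] | None = None

    def depth(self, pool: str) -> int:
        c = self.counts.get(pool)
        return 0 if c is None else c[0] + c[1]


def pool_allele_frequency(site: PooledSiteCounts, pool: str) -> float:
    """Read-based alternate allele frequency ``alt / (ref + alt)`` in one pool.

    Raises :class:`ZeroDepthError` when the pool has no (or absent) reads at
    the site, since 0/0 has no meaningful frequency.
    """
    c = site.counts.get(pool)
    if c is None or c[0] + c[1] == 0:
        raise ZeroDepthError(f"pool {pool!r} has zero depth at {site.chrom}:{site.pos}")
    return c[1] / (c[0] + c[1])


@dataclass
class SiteTable:
    """Column-oriented table of pooled sites, coordinate-sorted per chromosome.

    ``ref_reads``/``alt_reads`` are ``(n_sites, n_pools)`` integer arrays with
    ``MISSING`` (-1) marking absent counts.  ``annotations`` optionally holds
    caller metadata (QD, FS, MQ, MQRankSum, ReadPosRankSum) as float columns
    with NaN for absent values.  ``contigs`` records contig lengths so VCF
    round trips are byte-stable.
    """

    pools: tuple[str, ...]
    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    ref_reads: np.ndarray
    alt_reads: np.ndarray
    is_indel: np.ndarray
    indel_len: np.ndarray
    is_biallelic: np.ndarray
    annotations: pd.DataFrame | None = None
    contigs: dict[str, int] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "ref", "alt", "is_indel", "indel_len", "is_biallelic"):
            if len(getattr(self, name)) != n:
                raise DataError(f"column {name!r} length mismatch")
        if self.ref_reads.shape != (n, len(self.pools)):
            raise DataError("ref_reads shape does not match (n_sites, n_pools)")
        if self.alt_reads.shape != (n, len(self.pools)):
            raise DataError("alt_reads shape does not match (n_sites, n_pools)")

    @classmethod
    def from_records(cls, records: Sequence[PooledSiteCounts], pools: Sequence[str],
                     contigs: Mapping[str, int] | None = None) -> "SiteTable":
        pools = tuple(pools)
        n = len(records)
        ref_reads = np.full((n, len(pools)), MISSING, dtype=np.int64)
        alt_reads = np.full((n, len(pools)), MISSING, dtype=np.int64)
        ann_rows = []
        has_ann = False
        for i, rec in enumerate(records):
            for j, p in enumerate(pools):
                c = rec.counts.get(p)
                if c is not None:
                    ref_reads[i, j], alt_reads[i, j] = c
            row = {k: np.nan for k in ANNOTATION_FIELDS}
            if rec.annotations:
                has_ann = True
                for k in ANNOTATION_FIELDS:
                    if rec.annotations.get(k) is not None:
                        row[k] = float(rec.annotations[k])
            ann_rows.append(row)
        ann = pd.DataFrame(ann_rows, columns=list(ANNOTATION_FIELDS)) if has_ann else None
        return cls(
            pools=pools,
            chrom=np.array([r.chrom for r in records], dtype=object),
            pos=np.array([r.pos for r in records], dtype=np.int64),
            ref=np.array([r.ref for r in records], dtype=object),
            alt=np.array([r.alt for r in records], dtype=object),
            ref_reads=ref_reads,
            alt_reads=alt_reads,
            is_indel=np.array([r.is_indel for r in records], dtype=bool),
            indel_len=np.array([r.indel_len for r in records], dtype=np.int64),
            is_biallelic=np.array([r.is_biallelic for r in records], dtype=bool),
            annotations=ann,
            contigs=dict(contigs or {}),
        )

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def site(self, i: int) -> PooledSiteCounts:
        counts: dict[str, tuple[int, int] | None] = {}
        for j, p in enumerate(self.pools):
            r, a = int(self.ref_reads[i, j]), int(self.alt_reads[i, j])
            counts[p] = None if (r < 0 or a < 0) else (r, a)
        ann = None
        if self.annotations is not None:
            row = self.annotations.iloc[i]
            ann = {k: float(row[k]) for k in ANNOTATION_FIELDS if not math.isnan(row[k])}
            ann = ann or None
        return PooledSiteCounts(
            chrom=str(self.chrom[i]), pos=int(self.pos[i]),
            ref=str(self.ref[i]), alt=str(self.alt[i]), counts=counts,
            is_indel=bool(self.is_indel[i]), indel_len=int(self.indel_len[i]),
            is_biallelic=bool(self.is_biallelic[i]), annotations=ann,
        )

    def __iter__(self) -> Iterator[PooledSiteCounts]:
        return (self.site(i) for i in range(len(self)))

    def subset(self, mask: np.ndarray) -> "SiteTable":
        idx = np.asarray(mask)
        ann = None if self.annotations is None else self.annotations.loc[idx].reset_index(drop=True)
        return SiteTable(
            pools=self.pools,
            chrom=self.chrom[idx], pos=self.pos[idx],
            ref=self.ref[idx], alt=self.alt[idx],
            ref_reads=self.ref_reads[idx], alt_reads=self.alt_reads[idx],
            is_indel=self.is_indel[idx], indel_len=self.indel_len[idx],
            is_biallelic=self.is_biallelic[idx], annotations=ann,
            contigs=dict(self.contigs),
        )

    def equals(self, other: "SiteTable") -> bool:
        return (
            self.pools == other.pools
            and len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.pos == other.pos))
            and bool(np.all(self.ref == other.ref))
            and bool(np.all(self.alt == other.alt))
            and bool(np.all(self.ref_reads == other.ref_reads))
            and bool(np.all(self.alt_reads == other.alt_reads))
            and bool(np.all(self.is_indel == other.is_indel))
            and bool(np.all(self.indel_len == other.indel_len))
            and bool(np.all(self.is_biallelic == other.is_biallelic))
        )

    # -- vectorized count access ------------------------------------------

    def _pool_index(self, pools: Sequence[str]) -> list[int]:
        try:
            return [self.pools.index(p) for p in pools]
        except ValueError as exc:
            raise ConfigError(f"unknown pool in {tuple(pools)!r}; table has {self.pools}") from exc

    def pool_depths(self) -> np.ndarray:
        """(n_sites, n_pools) depths; absent counts count as depth 0."""
        r = np.where(self.ref_reads < 0, 0, self.ref_reads)
        a = np.where(self.alt_reads < 0, 0, self.alt_reads)
        return r + a

    def group_counts(self, pools: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Summed (ref, alt) read counts over a group of pools, per site."""
        idx = self._pool_index(pools)
        r = self.ref_reads[:, idx]
        a = self.alt_reads[:, idx]
        missing = (r < 0) | (a < 0)
        return (np.where(missing, 0, r).sum(axis=1),
                np.where(missing, 0, a).sum(axis=1))

    def group_freq(self, pools: Sequence[str]) -> np.ndarray:
        """Read-pooled alternate allele frequency of a pool group (NaN at depth 0)."""
        r, a = self.group_counts(pools)
        d = r + a
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, a / np.maximum(d, 1), np.nan)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt,
            "is_indel": self.is_indel, "indel_len": self.indel_len,
            "is_biallelic": self.is_biallelic,
        })
        for j, p in enumerate(self.pools):
            df[f"ref_{p}"] = self.ref_reads[:, j]
            df[f"alt_{p}"] = self.alt_reads[:, j]
        return df


# ---------------------------------------------------------------------------
# Filtering


@dataclass
class FilterConfig:
    """Post-calling hard filters for pooled variants.

    Depth bounds are applied per pool (any pool out of range removes the
    site); the allele-frequency floor is read as a pooled minor-allele
    frequency across all pools combined; INDELs of ``max_indel_len`` or
    longer are removed; the SNP/INDEL annotation thresholds are evaluated
    only for sites that carry the annotation.
    """

    min_depth: int = 10
    max_depth: int = 500
    min_af: float = 0.05
    max_indel_len: int = 5  # exclusive: INDELs shorter than this are kept
    biallelic_only: bool = True
    snp_qd: float = 2.0
    snp_fs: float = 60.0
    snp_mq: float = 40.0
    snp_mqranksum: float = -12.5
    snp_readposranksum: float = -8.0
    indel_qd: float = 2.0
    indel_fs: float = 200.0
    indel_readposranksum: float = -20.0

    def __post_init__(self) -> None:
        if not self.min_depth < self.max_depth:
            raise ConfigError("min_depth must be < max_depth")
        if not 0 <= self.min_af < 0.5:
            raise ConfigError("min_af must be in [0, 0.5)")


FILTER_RULES = ("non_biallelic", "depth", "allele_frequency", "indel_length", "hard_filter")


@dataclass
class FilterReport:
    """Per-rule removal tallies; removed + retained always equals the input."""

    total: int
    removed: dict[str, int]
    retained: int

    def __post_init__(self) -> None:
        if sum(self.removed.values()) + self.retained != self.total:
            raise DataError("filter report does not conserve site counts")

    def to_tsv(self, path: str | Path) -> None:
        rows = [("total", self.total)]
        rows += [(f"removed_{rule}", n) for rule, n in self.removed.items()]
        rows.append(("retained", self.retained))
        pd.DataFrame(rows, columns=["item", "count"]).to_csv(path, sep="\t", index=False)


def filter_variants(sites: SiteTable, cfg: FilterConfig | None = None) -> tuple[SiteTable, FilterReport]:
    """Apply the hard filters in a fixed rule order and tally removals.

    Rule order: non-biallelic, per-pool depth, pooled allele frequency,
    INDEL length, annotation hard filters.  Each removed site is charged to
    the first rule that rejects it, so the report is deterministic.
    """
    cfg = cfg or FilterConfig()
    n = len(sites)
    alive = np.ones(n, dtype=bool)
    removed: dict[str, int] = {}

    def apply(rule: str, bad: np.ndarray) -> None:
        bad = bad & alive
        removed[rule] = int(bad.sum())
        alive[bad] = False

    apply("non_biallelic", ~sites.is_biallelic if cfg.biallelic_only else np.zeros(n, bool))

    depths = sites.pool_depths()
    bad_depth = ((depths < cfg.min_depth) | (depths > cfg.max_depth)).any(axis=1)
    apply("depth", bad_depth)

    af = sites.group_freq(sites.pools)
    with np.errstate(invalid="ignore"):
        good_af = (af > cfg.min_af) & (af < 1.0 - cfg.min_af)
    apply("allele_frequency", ~np.where(np.isnan(af), False, good_af))

    apply("indel_length", sites.is_indel & (sites.indel_len >= cfg.max_indel_len))

    if sites.annotations is not None:
        ann = sites.annotations
        with np.errstate(invalid="ignore"):
            snp_bad = (
                (ann["QD"].to_numpy() < cfg.snp_qd)
                | (ann["FS"].to_numpy() > cfg.snp_fs)
                | (ann["MQ"].to_numpy() < cfg.snp_mq)
                | (ann["MQRankSum"].to_numpy() < cfg.snp_mqranksum)
                | (ann["ReadPosRankSum"].to_numpy() < cfg.snp_readposranksum)
            )
            indel_bad = (
                (ann["QD"].to_numpy() < cfg.indel_qd)
                | (ann["FS"].to_numpy() > cfg.indel_fs)
                | (ann["ReadPosRankSum"].to_numpy() < cfg.indel_readposranksum)
            )
        apply("hard_filter", np.where(sites.is_indel, indel_bad, snp_bad))
    else:
        removed["hard_filter"] = 0

    out = sites.subset(alive)
    return out, FilterReport(total=n, removed=removed, retained=len(out))


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER_FIELDS = (
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
)
_VCF_INFO_FIELDS = {
    "QD": '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
    "FS": '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">',
    "MQ": '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    "MQRankSum": '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
    "ReadPosRankSum": '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
}


def _fmt_float(x: float) -> str:
    s = f"{x:.6g}"
    return s


def write_vcf(table: SiteTable, path: str | Path) -> None:
    """Write the table as a minimal VCF 4.2 with per-pool AD/DP sample fields."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in table.contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    has_ann = table.annotations is not None
    if has_ann:
        lines.extend(_VCF_INFO_FIELDS.values())
    lines.extend(_VCF_HEADER_FIELDS)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.pools))
    ann = table.annotations
    for i in range(len(table)):
        if has_ann:
            row = ann.iloc[i]
            parts = [f"{k}={_fmt_float(row[k])}" for k in ANNOTATION_FIELDS if not math.isnan(row[k])]
            info = ";".join(parts) if parts else "."
        else:
            info = "."
        samples = []
        for j in range(table.n_pools):
            r, a = int(table.ref_reads[i, j]), int(table.alt_reads[i, j])
            samples.append(".:." if (r < 0 or a < 0) else f"{r},{a}:{r + a}")
        lines.append("\t".join([
            str(table.chrom[i]), str(int(table.pos[i])), ".",
            str(table.ref[i]), str(table.alt[i]), ".", ".", info, "AD:DP",
        ] + samples))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pooled_vcf(path: str | Path, pool_names: Sequence[str]) -> SiteTable:
    """Read a multi-sample VCF where every sample is a population pool.

    Per-pool ref/alt read counts come from the ``AD`` FORMAT field; records
    with more than one ALT allele are passed through flagged non-biallelic
    (only the first ALT's counts are kept); a missing AD entry marks that
    pool's counts absent.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such VCF: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions on bad input
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    for p in pool_names:
        if p not in samples:
            raise ConfigError(f"pool {p!r} is not a sample of {path} (samples: {samples})")
    order = [samples.index(p) for p in pool_names]

    contigs: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig="):
            body = line[len("##contig=<"):].rstrip(">")
            kv = dict(item.split("=", 1) for item in body.split(","))
            if "ID" in kv and "length" in kv:
                contigs[kv["ID"]] = int(kv["length"])

    chroms, poss, refs, alts = [], [], [], []
    is_indel, indel_len, is_biallelic = [], [], []
    ref_rows, alt_rows, ann_rows = [], [], []
    has_ann = False
    for lineno, v in enumerate(vcf):
        alt_alleles = v.ALT
        if not alt_alleles:
            raise ParseError("record without ALT allele", line=lineno + 1)
        ref, alt = v.REF, alt_alleles[0]
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(ref)
        alts.append(alt)
        is_biallelic.append(len(alt_alleles) == 1)
        indel = len(ref) != len(alt)
        is_indel.append(indel)
        indel_len.append(abs(len(ref) - len(alt)) if indel else 0)
        ad = v.format("AD")
        rrow = np.full(len(pool_names), MISSING, dtype=np.int64)
        arow = np.full(len(pool_names), MISSING, dtype=np.int64)
        if ad is not None:
            ad = np.asarray(ad)
            for k, j in enumerate(order):
                r, a = int(ad[j, 0]), int(ad[j, 1])
                if r >= 0 and a >= 0:
                    rrow[k], arow[k] = r, a
        ref_rows.append(rrow)
        alt_rows.append(arow)
        row = {}
        for key in ANNOTATION_FIELDS:
            val = v.INFO.get(key)
            row[key] = float(val) if val is not None else np.nan
        if any(not math.isnan(x) for x in row.values()):
            has_ann = True
        ann_rows.append(row)

    n = len(poss)
    return SiteTable(
        pools=tuple(pool_names),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        ref_reads=np.vstack(ref_rows) if n else np.empty((0, len(pool_names)), np.int64),
        alt_reads=np.vstack(alt_rows) if n else np.empty((0, len(pool_names)), np.int64),
        is_indel=np.array(is_indel, dtype=bool),
        indel_len=np.array(indel_len, dtype=np.int64),
        is_biallelic=np.array(is_biallelic, dtype=bool),
        annotations=pd.DataFrame(ann_rows, columns=list(ANNOTATION_FIELDS)) if has_ann else None,
        contigs=contigs,
    )


# ---------------------------------------------------------------------------
# popoolation2 sync dialect


def write_sync(table: SiteTable, path: str | Path) -> None:
    """Write SNP sites as popoolation2 sync text (INDELs cannot be expressed)."""
    lines = []
    for i in range(len(table)):
        if table.is_indel[i]:
            continue
        ref, alt = str(table.ref[i]), str(table.alt[i])
        cols = [str(table.chrom[i]), str(int(table.pos[i])), ref]
        for j in range(table.n_pools):
            counts = dict.fromkeys(_SYNC_ORDER, 0)
            r, a = int(table.ref_reads[i, j]), int(table.alt_reads[i, j])
            if r > 0:
                counts[ref] = r
            if a > 0 and alt in counts:
                counts[alt] = a
            cols.append(":".join(str(counts[b]) for b in _SYNC_ORDER) + ":0")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sync(path: str | Path, pool_names: Sequence[str]) -> SiteTable:
    """Read popoolation2 sync text into a :class:`SiteTable`.

    A site whose pooled counts segregate for exactly two of A/C/G/T, one of
    them the stated reference base, becomes a biallelic record; a site fixed
    for the reference stays biallelic with a placeholder alternate ``N`` and
    zero alt reads; anything else is flagged non-biallelic.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such sync file: {path}")
    records: list[PooledSiteCounts] = []
    n_cols = 3 + len(pool_names)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) != n_cols:
                raise ParseError(
                    f"expected {n_cols} columns for {len(pool_names)} pools, got {len(fields)}",
                    line=lineno,
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"bad position {pos_s!r}", line=lineno) from None
            per_pool = []
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise ParseError(f"bad count string {col!r}", line=lineno)
                per_pool.append([int(x) for x in parts])
            totals = np.asarray(per_pool).sum(axis=0)  # A,T,C,G,N,del over pools
            seg = [b for k, b in enumerate("ATCG") if totals[k] > 0]
            biallelic = False
            alt = "N"
            if len(seg) == 2 and ref in seg:
                biallelic = True
                alt = seg[0] if seg[1] == ref else seg[1]
            elif len(seg) == 1:
                # monomorphic: fixed for the reference, or for a single alternate
                biallelic = True
                alt = seg[0] if seg[0] != ref else "N"
            elif len(seg) == 0:
                biallelic = True  # no reads anywhere; zero-depth everywhere
            counts: dict[str, tuple[int, int] | None] = {}
            for p, vec in zip(pool_names, per_pool):
                r = vec["ATCG".index(ref)] if ref in "ATCG" else 0
                a = vec["ATCG".index(alt)] if alt in "ATCG" else 0
                counts[p] = (r, a)
            records.append(PooledSiteCounts(
                chrom=chrom, pos=pos, ref=ref, alt=alt, counts=counts,
                is_biallelic=biallelic,
            ))
    return SiteTable.from_records(records, pool_names)
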