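"""Per-SNP allele-frequency differentiation and candidate-variant filtering.

ΔAF — the absolute difference of a SNP's read-pooled allele frequency
between two groups — is binned at 2-decimal (half-up) resolution into ten
10% bins; "low" differentiation means rounded ΔAF <= 0.40, "high" means
>= 0.41, and >= 0.81 marks alleles fixed or nearly fixed in one group.  The
three complementary thresholds partition every scored SNP exactly once.

Candidate variants are the SNPs that pass all three prioritization
criteria: (1) inside a gene under selection, (2) coding consequence is
missense or nonsense, (3) the affected protein position is evolutionarily
conserved in a multiple protein alignment (consensus identity >= threshold,
default 0.8).  Pooled sequencing carries no phase, so two SNPs hitting the
same codon are evaluated independently (with a warning) unless explicitly
declared phased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .annotation import GeneModel
from .errors import AnnotationError, ConfigError, DataError
from .variant_io import PooledSiteCounts, SiteTable

__all__ = [
    "DeltaAFSummary",
    "CodingEffect",
    "ConservationCall",
    "CandidateVariant",
    "delta_af",
    "delta_af_table",
    "bin_delta_af",
    "classify_coding_effect",
    "column_conservation",
    "prioritize_variants",
]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# Delta AF


def delta_af(site: PooledSiteCounts, pools_a: Sequence[str], pools_b: Sequence[str]) -> float:
    """|p_A - p_B| on read-pooled group frequencies; symmetric in its groups."""
    def group_freq(pools: Sequence[str]) -> float:
        r = a = 0
        for p in pools:
            c = site.counts.get(p)
            if c is not None:
                r += c[0]
                a += c[1]
        if r + a == 0:
            raise DataError(f"zero group depth at {site.chrom}:{site.pos}")
        return a / (r + a)

    return abs(group_freq(pools_a) - group_freq(pools_b))


def delta_af_table(
    table: SiteTable,
    pools_a: Sequence[str],
    pools_b: Sequence[str],
    regions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Vectorized ΔAF per biallelic SNP, optionally restricted to regions.

    Sites lacking depth in either group are skipped and tallied in the
    frame's ``attrs["n_skipped"]``.  Adds the 2-decimal rounded value and
    the 10%-bin index.
    """
    snp = table.subset(table.is_biallelic & ~table.is_indel)
    if regions is not None:
        keep = _sites_in_regions_mask(snp, regions)
        snp = snp.subset(keep)
    ra, aa = snp.group_counts(pools_a)
    rb, ab = snp.group_counts(pools_b)
    da, db = ra + aa, rb + ab
    usable = (da > 0) & (db > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.abs(aa / np.maximum(da, 1) - ab / np.maximum(db, 1))
    out = pd.DataFrame({
        "chrom": snp.chrom[usable],
        "pos": snp.pos[usable],
        "delta_af": d[usable],
    })
    rounded = _round2(out["delta_af"].to_numpy())
    out["delta_af_rounded"] = rounded / 100.0
    out["bin"] = np.minimum(rounded // 10, 9).astype(int)
    out.attrs["n_skipped"] = int((~usable).sum())
    return out


def _round2(x: np.ndarray | float) -> np.ndarray:
    """Half-up rounding to 2 decimals, returned as integer hundredths.

    A tiny epsilon absorbs binary-representation error so that values
    printed as .xx5 round up as a decimal half-up rule would.
    """
    return np.floor(np.asarray(x, dtype=float) * 100.0 + 0.5 + 1e-9).astype(int)


@dataclass
class DeltaAFSummary:
    """Ten-bin ΔAF histogram plus the low / high / fixed tallies."""

    histogram: tuple[int, ...]  # bins [0.00-0.10], (0.10-0.20] ... (0.90-1.00]
    low: int    # rounded <= 0.40
    high: int   # rounded >= 0.41
    fixed: int  # rounded >= 0.81
    total: int

    def __post_init__(self) -> None:
        if sum(self.histogram) != self.total or self.low + self.high != self.total:
            raise DataError("delta-AF tallies do not conserve the SNP count")

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{i / 10:.2f}-{(i + 1) / 10:.2f}" for i in range(10)]
        return pd.DataFrame({"bin": labels, "count": list(self.histogram)})


def bin_delta_af(values: Iterable[float] | np.ndarray | pd.DataFrame) -> DeltaAFSummary:
    """Bin ΔAF values (or a :func:`delta_af_table` frame) at 10% resolution."""
    if isinstance(values, pd.DataFrame):
        values = values["delta_af"].to_numpy()
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if arr.size == 0:
        return DeltaAFSummary(histogram=(0,) * 10, low=0, high=0, fixed=0, total=0)
    if np.any((arr < 0) | (arr > 1)):
        raise DataError("delta AF values must lie in [0, 1]")
    r = _round2(arr)
    bins = np.minimum(r // 10, 9)
    hist = np.bincount(bins, minlength=10)
    return DeltaAFSummary(
        histogram=tuple(int(h) for h in hist),
        low=int((r <= 40).sum()),
        high=int((r >= 41).sum()),
        fixed=int((r >= 81).sum()),
        total=int(arr.size),
    )


# ---------------------------------------------------------------------------
# Coding consequence


@dataclass(frozen=True)
class CodingEffect:
    """Consequence of a variant on its gene's protein."""

    category: str  # synonymous | missense | nonsense | frameshift | inframe_indel | noncoding
    ref_aa: str | None = None
    alt_aa: str | None = None
    protein_pos: int | None = None  # 1-based

    def __post_init__(self) -> None:
        aa_expected = self.category in ("synonymous", "missense", "nonsense")
        if aa_expected != (self.ref_aa is not None and self.alt_aa is not None):
            raise DataError("ref_aa/alt_aa must be set exactly for SNP coding categories")


def _cds_positions(gene: GeneModel) -> np.ndarray:
    """Genomic 0-based positions of CDS bases in transcription order."""
    if not gene.cds:
        raise AnnotationError(f"gene {gene.gene_id} has no CDS")
    segs = list(gene.cds)
    pos = np.concatenate([np.arange(s, e) for s, e in segs])
    if len(pos) % 3 != 0:
        raise AnnotationError(f"gene {gene.gene_id}: CDS length {len(pos)} not divisible by 3")
    return pos[::-1] if gene.strand == "-" else pos


def _fetch_base(genome: Mapping[str, object], chrom: str, pos0: int) -> str:
    seq = genome[chrom]
    b = seq[pos0]
    if isinstance(b, (bytes, np.bytes_)):
        b = b.decode()
    return str(b).upper()


def classify_coding_effect(
    variant,
    gene: GeneModel,
    genome: Mapping[str, object],
    companions: Sequence | None = None,
) -> CodingEffect:
    """Classify a variant against a gene model and reference sequence.

    ``variant`` needs ``chrom``/``pos`` (1-based)/``ref``/``alt``
    attributes.  A CDS SNP is translated ref vs alt codon with the standard
    genetic code (reverse strand handled by complementing into transcript
    orientation); a CDS indel is frameshift unless its length is a multiple
    of 3; anything inside the gene but outside the CDS is noncoding.
    ``companions`` are additional *phased* SNPs applied jointly when they
    hit the same codon — the mechanism for pairs of substitutions that
    together rewrite one amino acid.
    """
    pos0 = variant.pos - 1
    if variant.chrom != gene.chrom or not gene.start <= pos0 < gene.end:
        raise DataError(
            f"variant {variant.chrom}:{variant.pos} lies outside gene {gene.gene_id}")
    cds_pos = _cds_positions(gene)
    is_indel = len(variant.ref) != len(variant.alt)
    in_cds = any(s <= pos0 < e for s, e in gene.cds)
    if is_indel:
        if not in_cds:
            return CodingEffect(category="noncoding")
        delta = abs(len(variant.ref) - len(variant.alt))
        return CodingEffect(category="frameshift" if delta % 3 else "inframe_indel")
    if not in_cds:
        return CodingEffect(category="noncoding")

    index_of = {int(p): i for i, p in enumerate(cds_pos)}
    ci = index_of[pos0]
    codon_idx, offset = divmod(ci, 3)
    codon_genomic = cds_pos[codon_idx * 3: codon_idx * 3 + 3]

    def tx_base(raw: str) -> str:
        return raw.translate(_COMPLEMENT)[::-1] if gene.strand == "-" else raw

    ref_codon = list("".join(
        tx_base(_fetch_base(genome, gene.chrom, int(p))) for p in codon_genomic
    ))
    # sanity: the variant's own REF must match the reference sequence
    genome_ref = _fetch_base(genome, gene.chrom, pos0)
    if genome_ref != variant.ref.upper():
        raise DataError(
            f"REF mismatch at {variant.chrom}:{variant.pos}: "
            f"genome has {genome_ref}, variant says {variant.ref}")
    alt_codon = ref_codon.copy()
    alt_codon[offset] = tx_base(variant.alt.upper())
    for comp in companions or ():
        cp0 = comp.pos - 1
        if cp0 == pos0:
            continue
        if cp0 not in index_of:
            continue
        c_ci = index_of[cp0]
        if c_ci // 3 != codon_idx:
            continue
        alt_codon[c_ci % 3] = tx_base(comp.alt.upper())
    ref_aa = str(Seq("".join(ref_codon)).translate(table=_STANDARD_TABLE))
    alt_aa = str(Seq("".join(alt_codon)).translate(table=_STANDARD_TABLE))
    protein_pos = codon_idx + 1
    if alt_aa == ref_aa:
        category = "synonymous"
    elif alt_aa == "*":
        category = "nonsense"
    else:
        category = "missense"
    return CodingEffect(category=category, ref_aa=ref_aa, alt_aa=alt_aa, protein_pos=protein_pos)


# ---------------------------------------------------------------------------
# Conservation


@dataclass(frozen=True)
class ConservationCall:
    """Consensus identity of one alignment column (1-based focal protein position)."""

    alignment_id: str
    column: int
    identity: float
    conserved: bool
    undefined: bool = False


def column_conservation(
    alignment: Mapping[str, str],
    position: int,
    focal_id: str,
    threshold: float = 0.8,
    alignment_id: str = "",
) -> ConservationCall:
    """Score conservation of the column holding the focal protein's residue.

    ``position`` is the 1-based residue index in the *ungapped* focal
    sequence; it is mapped to its alignment column, then the identity
    fraction is the share of non-gap rows matching the column consensus
    (most frequent non-gap residue, ties broken alphabetically).  An
    all-gap column yields an undefined, non-conserved call.
    """
    if focal_id not in alignment:
        raise ConfigError(f"focal sequence {focal_id!r} not in alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise DataError("alignment rows have unequal lengths")
    focal = alignment[focal_id]
    residue_count = 0
    col = None
    for i, ch in enumerate(focal):
        if ch != "-":
            residue_count += 1
            if residue_count == position:
                col = i
                break
    if col is None:
        raise DataError(f"position {position} beyond focal sequence ({residue_count} residues)")
    column = [s[col] for s in alignment.values()]
    residues = [c for c in column if c != "-"]
    if not residues:
        return ConservationCall(alignment_id=alignment_id, column=position,
                                identity=float("nan"), conserved=False, undefined=True)
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    consensus = min(counts, key=lambda c: (-counts[c], c))
    identity = counts[consensus] / len(residues)
    return ConservationCall(alignment_id=alignment_id, column=position,
                            identity=identity, conserved=identity >= threshold)


# ---------------------------------------------------------------------------
# Candidate filter


@dataclass(frozen=True)
class CandidateVariant:
    """A variant passing all three prioritization criteria."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    effect: CodingEffect
    conservation: ConservationCall
    delta_af: float


def _sites_in_regions_mask(table: SiteTable, regions: pd.DataFrame) -> np.ndarray:
    trees: dict[str, IntervalTree] = {}
    for r in regions.itertuples(index=False):
        if r.end > r.start:
            trees.setdefault(r.chrom, IntervalTree()).addi(int(r.start), int(r.end))
    mask = np.zeros(len(table), dtype=bool)
    for i in range(len(table)):
        tree = trees.get(str(table.chrom[i]))
        if tree is not None and tree.overlaps(int(table.pos[i]) - 1):
            mask[i] = True
    return mask


def prioritize_variants(
    table: SiteTable,
    regions: pd.DataFrame,
    genes: Sequence[GeneModel],
    alignments: Mapping[str, Mapping[str, str]],
    genome: Mapping[str, object],
    pools_a: Sequence[str],
    pools_b: Sequence[str],
    conservation_threshold: float = 0.8,
    focal_ids: Mapping[str, str] | None = None,
) -> tuple[list[CandidateVariant], pd.DataFrame]:
    """Apply the three-criterion candidate filter and rank by ΔAF.

    Emits exactly the SNPs inside genes under selection (genes overlapping
    the given regions) whose coding effect is missense or nonsense and
    whose protein position is conserved in the gene's protein alignment.
    Genes without an alignment leave the conservation criterion
    unevaluable: those variants are excluded with reason
    ``no_alignment``.  Returns the candidates sorted by ΔAF descending and
    an exclusion table with one reason per rejected in-region variant.
    """
    from .annotation import genes_in_regions

    selected_ids = set(genes_in_regions(regions, genes))
    gene_by_id = {g.gene_id: g for g in genes}
    gene_trees: dict[str, IntervalTree] = {}
    for g in genes:
        if g.gene_id in selected_ids:
            gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)

    in_region = _sites_in_regions_mask(table, regions)
    sub = table.subset(in_region & table.is_biallelic)
    # pre-compute group frequencies for delta AF
    ra, aa = sub.group_counts(pools_a)
    rb, ab = sub.group_counts(pools_b)
    da, db = ra + aa, rb + ab

    candidates: list[CandidateVariant] = []
    exclusions: list[tuple[str, int, str]] = []
    same_codon_warned = False
    for i in range(len(sub)):
        chrom, pos = str(sub.chrom[i]), int(sub.pos[i])
        tree = gene_trees.get(chrom)
        hits = tree[pos - 1] if tree is not None else set()
        if not hits:
            exclusions.append((chrom, pos, "not_in_selected_gene"))
            continue
        gene = gene_by_id[sorted(hits)[0].data]
        site = sub.site(i)
        try:
            effect = classify_coding_effect(site, gene, genome)
        except DataError as exc:
            exclusions.append((chrom, pos, f"classification_error:{exc}"))
            continue
        if effect.category not in ("missense", "nonsense"):
            exclusions.append((chrom, pos, f"effect:{effect.category}"))
            continue
        aln = alignments.get(gene.gene_id)
        if aln is None:
            exclusions.append((chrom, pos, "no_alignment"))
            continue
        focal = (focal_ids or {}).get(gene.gene_id, gene.gene_id)
        call = column_conservation(aln, effect.protein_pos, focal,
                                   threshold=conservation_threshold,
                                   alignment_id=gene.gene_id)
        if not call.conserved:
            exclusions.append((chrom, pos, "not_conserved"))
            continue
        if da[i] == 0 or db[i] == 0:
            exclusions.append((chrom, pos, "missing_group_depth"))
            continue
        d = abs(aa[i] / da[i] - ab[i] / db[i])
        candidates.append(CandidateVariant(
            chrom=chrom, pos=pos, ref=str(sub.ref[i]), alt=str(sub.alt[i]),
            gene_id=gene.gene_id, effect=effect, conservation=call, delta_af=float(d),
        ))
    # pooled reads carry no phase: flag potential same-codon pairs once
    if not same_codon_warned:
        by_codon: dict[tuple[str, str, int], int] = {}
        for c in candidates:
            key = (c.gene_id, c.chrom, (c.effect.protein_pos or 0))
            by_codon[key] = by_codon.get(key, 0) + 1
        if any(v > 1 for v in by_codon.values()):
            warnings.warn(
                "multiple unphased SNPs hit the same codon; they were "
                "evaluated independently")
    candidates.sort(key=lambda c: (-c.delta_af, c.chrom, c.pos))
    excl = pd.DataFrame(exclusions, columns=["chrom", "pos", "reason"])
    return candidates, excl


def candidates_table(candidates: Sequence[CandidateVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.chrom, c.pos, c.ref, c.alt, c.gene_id, c.effect.category,
             c.effect.ref_aa, c.effect.alt_aa, c.effect.protein_pos,
             c.conservation.identity, c.delta_af)
            for c in candidates
        ],
        columns=["chrom", "pos", "ref", "alt", "gene_id", "effect", "ref_aa",
                 "alt_aa", "protein_pos", "conservation_identity", "delta_af"],
    )
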