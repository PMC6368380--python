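"""Gene models, region-gene overlap and GO-term enrichment.

Gene models come from GFF3 (via :mod:`gffutils`); when a gene has several
transcripts the canonical model is the one with the longest total CDS.
Enrichment of a query gene set against a whole-genome background uses the
hypergeometric upper tail (the probability of drawing at least the observed
overlap) with Benjamini-Hochberg correction across tested terms.  The
gene-to-term mapping is taken as already propagated through the ontology
graph; no parent-term inheritance is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import AnnotationError, ConfigError, DataError

__all__ = ["GeneModel", "EnrichmentResult", "read_gff", "genes_in_regions", "go_enrichment"]


@dataclass(frozen=True)
class GeneModel:
    """A gene span with its canonical CDS segments (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"gene {self.gene_id}: empty span")
        if self.strand not in "+-":
            raise AnnotationError(f"gene {self.gene_id}: strand must be + or -")
        segs = sorted(self.cds)
        for s, e in segs:
            if s < self.start or e > self.end:
                raise AnnotationError(f"gene {self.gene_id}: CDS outside gene span")
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 < e1:
                raise AnnotationError(f"gene {self.gene_id}: overlapping CDS segments")
        object.__setattr__(self, "cds", tuple(segs))

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features from GFF3 into gene models.

    GFF coordinates (1-based inclusive) are converted to 0-based half-open.
    CDS features may hang off an mRNA or directly off the gene; with several
    transcripts, the longest-CDS transcript wins.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such GFF3 file: {path}")
    if path.stat().st_size == 0 or not path.read_text().strip():
        return []
    db = gffutils.create_db(
        str(path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = g.attributes.get("Name", [g.id])[0] if "Name" in g.attributes else g.id
        best_cds: list[tuple[int, int]] = []
        transcripts = list(db.children(g, featuretype=("mRNA", "transcript"), level=1))
        if transcripts:
            candidates = [
                [(c.start - 1, c.end) for c in db.children(t, featuretype="CDS")]
                for t in transcripts
            ]
        else:
            candidates = [[(c.start - 1, c.end) for c in db.children(g, featuretype="CDS")]]
        for segs in candidates:
            if sum(e - s for s, e in segs) > sum(e - s for s, e in best_cds):
                best_cds = segs
        for s, e in best_cds:
            if s < g.start - 1 or e > g.end:
                raise AnnotationError(f"gene {gid}: CDS outside parent span")
        genes.append(GeneModel(
            gene_id=gid, chrom=g.seqid, start=g.start - 1, end=g.end,
            strand=g.strand if g.strand in "+-" else "+",
            cds=tuple(sorted(best_cds)),
        ))
    return genes


def genes_in_regions(regions: pd.DataFrame, genes: Sequence[GeneModel]) -> list[str]:
    """Genes whose span overlaps any region by at least 1 bp, each reported once.

    ``regions`` needs ``chrom``/``start``/``end`` columns in 0-based
    half-open coordinates; abutting intervals (gene start == region end) do
    not overlap.  Output is ordered by genomic position.
    """
    trees: dict[str, IntervalTree] = {}
    for r in regions.itertuples(index=False):
        if r.end > r.start:
            trees.setdefault(r.chrom, IntervalTree()).addi(int(r.start), int(r.end))
    hits = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        tree = trees.get(g.chrom)
        if tree is not None and tree.overlaps(g.start, g.end):
            hits.append(g.gene_id)
    return hits


@dataclass
class EnrichmentResult:
    """One GO term's overlap with the query set and its hypergeometric p-value."""

    term: str
    term_size: int
    overlap: int
    p_value: float
    adjusted_p: float
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.overlap > self.term_size:
            raise DataError("overlap cannot exceed term size")


def _as_term_map(gene_terms: Mapping[str, Iterable[str]] | pd.DataFrame) -> dict[str, set[str]]:
    if isinstance(gene_terms, pd.DataFrame):
        gcol, tcol = gene_terms.columns[:2]
        out: dict[str, set[str]] = {}
        for g, t in zip(gene_terms[gcol], gene_terms[tcol]):
            out.setdefault(str(g), set()).add(str(t))
        return out
    return {g: set(ts) for g, ts in gene_terms.items()}


def go_enrichment(
    query: Sequence[str],
    background: Sequence[str],
    gene_terms: Mapping[str, Iterable[str]] | pd.DataFrame,
    adjust: str | None = "BH",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test per GO term.

    For a term annotating K of N background genes, with n query genes and k
    of them in the term, p = P(X >= k) for X ~ Hypergeom(N, K, n).  Terms
    with zero overlap are skipped.  ``adjust="BH"`` applies
    Benjamini-Hochberg across the tested terms; ``None`` leaves raw
    p-values.  Results are sorted by raw p-value, ties by term id.
    """
    background_set = set(map(str, background))
    query_set = set(map(str, query))
    if not query_set <= background_set:
        missing = sorted(query_set - background_set)[:5]
        raise ConfigError(f"query genes missing from background, e.g. {missing}")
    term_map = _as_term_map(gene_terms)

    term_genes: dict[str, set[str]] = {}
    for g, terms in term_map.items():
        if g not in background_set:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(g)

    N, n = len(background_set), len(query_set)
    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        overlap = members & query_set
        if not overlap:
            continue
        K, k = len(members), len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, K, k, min(p, 1.0), tuple(sorted(overlap))))
    if not rows:
        return []
    raw = np.array([r[3] for r in rows])
    if adjust is None:
        adj = raw
    elif adjust.upper() in ("BH", "FDR_BH"):
        adj = multipletests(raw, method="fdr_bh")[1]
    else:
        raise ConfigError(f"unknown adjustment method {adjust!r}")
    results = [
        EnrichmentResult(term=t, term_size=K, overlap=k, p_value=p,
                         adjusted_p=float(max(a, p)), genes=genes)
        for (t, K, k, p, genes), a in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view: term, p, adjusted p, gene count (plus members)."""
    return pd.DataFrame(
        [(r.term, r.p_value, r.adjusted_p, r.overlap, r.term_size, ";".join(r.genes))
         for r in results],
        columns=["term", "p_value", "adjusted_p", "gene_count", "term_size", "genes"],
    )
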