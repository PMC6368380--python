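"""End-to-end orchestration: simulate -> filter -> scan -> select -> merge ->
genes -> enrich -> delta-AF -> prioritize, with a manifest of every stage
output.

All stage outputs are plain text (TSV/BED/VCF/GFF3/YAML/JSON) and the whole
run is a pure function of the configuration, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation, prioritize, scan, simulate, variant_io
from .errors import ConfigError

__all__ = ["PipelineConfig", "run_pipeline", "compare_to_truth", "RecoveryReport"]

log = logging.getLogger("poolsweep")

_FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    outdir: Path
    comparisons: list[scan.Comparison]
    variants: Path | None = None  # VCF path; None means simulate
    gff: Path | None = None
    go_map: Path | None = None
    genome: Path | None = None
    simulation: simulate.SimConfig | None = None
    window: int = 40_000
    step: int = 20_000
    min_snps: int = 10
    selection: scan.SelectionRule | None = None  # None -> scaled to scan size
    filters: variant_io.FilterConfig = field(default_factory=variant_io.FilterConfig)
    conservation_threshold: float = 0.8
    seed: int = 7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping, base: Path | None = None) -> "PipelineConfig":
        base = base or Path(".")

        def p(key: str) -> Path | None:
            v = raw.get(key)
            return None if v is None else (base / v)

        comparisons = []
        for c in raw.get("comparisons", []):
            comparisons.append(scan.Comparison(
                label_a=c["group_a"]["label"], pools_a=tuple(c["group_a"]["pools"]),
                label_b=c["group_b"]["label"], pools_b=tuple(c["group_b"]["pools"]),
            ))
        if not comparisons:
            raise ConfigError("config must define at least one comparison")
        sim = raw.get("simulate")
        selection = raw.get("selection")
        rule = None
        if selection and not selection.get("scale_to_windows", False):
            rule = scan.SelectionRule(top_k_fst=selection.get("top_k", 200),
                                      bottom_l_hp=selection.get("bottom_l", 400))
        filters = variant_io.FilterConfig(**raw.get("filters", {}))
        return cls(
            outdir=base / raw.get("outdir", "poolsweep_out"),
            comparisons=comparisons,
            variants=p("variants"),
            gff=p("gff"),
            go_map=p("go_map"),
            genome=p("genome"),
            simulation=simulate.SimConfig.from_dict(sim) if sim else None,
            window=int(raw.get("window", 40_000)),
            step=int(raw.get("step", 20_000)),
            min_snps=int(raw.get("min_snps", 10)),
            selection=rule,
            filters=filters,
            conservation_threshold=float(raw.get("conservation_threshold", 0.8)),
            seed=int(raw.get("seed", 7)),
        )

    def config_hash(self) -> str:
        blob = json.dumps(_describe(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _describe(cfg: PipelineConfig) -> dict:
    return {
        "comparisons": [c.name for c in cfg.comparisons],
        "window": cfg.window, "step": cfg.step, "min_snps": cfg.min_snps,
        "selection": None if cfg.selection is None else
            [cfg.selection.top_k_fst, cfg.selection.bottom_l_hp],
        "filters": vars(cfg.filters),
        "conservation_threshold": cfg.conservation_threshold,
        "seed": cfg.seed,
        "simulation": cfg.simulation.to_dict() if cfg.simulation else None,
        "variants": str(cfg.variants) if cfg.variants else None,
    }


@dataclass
class RecoveryReport:
    """Truth-based evaluation of called regions."""

    n_truth: int
    n_hit: int
    sensitivity: float
    n_regions: int
    false_positive_regions: int

    def to_dict(self) -> dict:
        return {
            "n_truth": self.n_truth, "n_truth_hit": self.n_hit,
            "sensitivity": self.sensitivity, "n_selected_regions": self.n_regions,
            "false_positive_regions": self.false_positive_regions,
        }


def _overlaps(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def compare_to_truth(
    regions: pd.DataFrame,
    truth: pd.DataFrame | Sequence[tuple[str, int, int]],
) -> RecoveryReport:
    """Sensitivity = fraction of truth regions hit by >= 1 called region;
    false positives = called regions hitting no truth region."""
    if isinstance(truth, pd.DataFrame):
        truth_list = [(str(r.chrom), int(r.start), int(r.end))
                      for r in truth.itertuples(index=False)]
    else:
        truth_list = [(str(c), int(s), int(e)) for c, s, e in truth]
    called = [(str(r.chrom), int(r.start), int(r.end))
              for r in regions.itertuples(index=False)] if len(regions) else []
    hits = sum(1 for t in truth_list if any(_overlaps(t, c) for c in called))
    fp = sum(1 for c in called if not any(_overlaps(c, t) for t in truth_list))
    sens = hits / len(truth_list) if truth_list else 0.0
    return RecoveryReport(
        n_truth=len(truth_list), n_hit=hits, sensitivity=sens,
        n_regions=len(called), false_positive_regions=fp,
    )


def read_truth_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        rows.append((fields[0], int(fields[1]), int(fields[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)
    return len(df)


def _read_fasta(path: Path) -> dict[str, np.ndarray]:
    genome: dict[str, np.ndarray] = {}
    name, chunks = None, []
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                genome[name] = np.frombuffer("".join(chunks).encode(), dtype="S1")
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if name is not None:
        genome[name] = np.frombuffer("".join(chunks).encode(), dtype="S1")
    return genome


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage, write all intermediates, return the manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "stages": {}}

    def record(stage: str, **outputs: int) -> None:
        manifest["stages"][stage] = {k: int(v) for k, v in outputs.items()}
        for k, v in outputs.items():
            log.info("%s: %s = %d", stage, k, v)

    # -- simulate (optional) ----------------------------------------------
    truth_df: pd.DataFrame | None = None
    genome: Mapping[str, np.ndarray] | None = None
    if cfg.simulation is not None:
        result = simulate.simulate_dataset(cfg.simulation, with_genome=True)
        sim_paths = simulate.write_simulation(result, out / "sim")
        genome = result.genome
        vcf_path = sim_paths["vcf"]
        gff_path = sim_paths["gff"]
        go_path = sim_paths["go_map"]
        truth_df = pd.DataFrame(
            [(r.spec.chrom, r.spec.start, r.spec.end) for r in result.truth.records],
            columns=["chrom", "start", "end"])
        record("simulate", sites=len(result.table), sweeps=len(result.truth.records))
    else:
        if cfg.variants is None:
            raise ConfigError("config needs either a simulate block or a variants path")
        vcf_path, gff_path, go_path = cfg.variants, cfg.gff, cfg.go_map
        if cfg.genome is not None:
            genome = _read_fasta(cfg.genome)

    pools = cfg.simulation.pool_names if cfg.simulation else tuple(
        p for c in cfg.comparisons for p in c.pools_a + c.pools_b)
    pools = tuple(dict.fromkeys(pools))  # unique, order-preserving

    # -- filter ------------------------------------------------------------
    table = variant_io.read_pooled_vcf(vcf_path, pools)
    table, report = variant_io.filter_variants(table, cfg.filters)
    variant_io.write_vcf(table, out / "filtered.vcf")
    report.to_tsv(out / "filter_report.tsv")
    record("filter", input=report.total, retained=report.retained)

    genes = annotation.read_gff(gff_path) if gff_path else []
    go_map = pd.read_csv(go_path, sep="\t") if go_path else None

    windows = scan.make_windows(
        table.contigs or _infer_contigs(table), cfg.window, cfg.step)

    for comp in cfg.comparisons:
        tag = comp.name
        # -- scan ----------------------------------------------------------
        stats, summary = scan.scan_genome(table, comp, windows, cfg.min_snps)
        _write_tsv(stats, out / f"windows_{tag}.tsv")
        _write_tsv(summary.to_frame(), out / f"scan_summary_{tag}.tsv")
        record(f"scan_{tag}", windows=len(stats), retained=summary.n_retained)

        # -- select ---------------------------------------------------------
        rule = cfg.selection or scan.SelectionRule.scaled(summary.n_retained)
        selected = scan.select_windows(stats, rule)
        _write_tsv(selected.drop(columns=["excluded"]), out / f"selected_windows_{tag}.tsv")
        record(f"select_{tag}", selected=len(selected),
               top_k=rule.top_k_fst, bottom_l=rule.bottom_l_hp)

        # -- regions --------------------------------------------------------
        regions = scan.merge_regions(selected)
        bed = regions[["chrom", "start", "end"]].copy()
        bed["name"] = [f"region_{i + 1}" for i in range(len(regions))]
        bed.to_csv(out / f"regions_{tag}.bed", sep="\t", index=False, header=False)
        record(f"regions_{tag}", regions=len(regions))

        # -- genes ----------------------------------------------------------
        sel_genes = annotation.genes_in_regions(regions, genes) if genes else []
        _write_tsv(pd.DataFrame({"gene_id": sel_genes}), out / f"genes_{tag}.tsv")
        record(f"genes_{tag}", genes=len(sel_genes))

        # -- enrich ----------------------------------------------------------
        if go_map is not None and genes:
            background = [g.gene_id for g in genes]
            results = annotation.go_enrichment(sel_genes, background, go_map)
            _write_tsv(annotation.enrichment_table(results), out / f"enrichment_{tag}.tsv")
            record(f"enrich_{tag}", terms=len(results))

        # -- delta AF --------------------------------------------------------
        daf = prioritize.delta_af_table(table, comp.pools_a, comp.pools_b, regions)
        _write_tsv(daf, out / f"delta_af_{tag}.tsv")
        hist = prioritize.bin_delta_af(daf)
        _write_tsv(hist.to_frame(), out / f"delta_af_bins_{tag}.tsv")
        record(f"deltaaf_{tag}", snps=hist.total, high=hist.high, fixed=hist.fixed)

        # -- prioritize -------------------------------------------------------
        if genes and genome is not None:
            alignments = _gene_alignments(sel_genes, genes, genome, cfg.seed)
            cands, excl = prioritize.prioritize_variants(
                table, regions, genes, alignments, genome,
                comp.pools_a, comp.pools_b, cfg.conservation_threshold)
            _write_tsv(prioritize.candidates_table(cands), out / f"candidates_{tag}.tsv")
            _write_tsv(excl, out / f"candidate_exclusions_{tag}.tsv")
            record(f"prioritize_{tag}", candidates=len(cands), excluded=len(excl))

        # -- evaluate ----------------------------------------------------------
        if truth_df is not None:
            report_t = compare_to_truth(regions, truth_df)
            (out / f"evaluation_{tag}.json").write_text(
                json.dumps(report_t.to_dict(), indent=2, sort_keys=True) + "\n")
            record(f"evaluate_{tag}", truth_hit=report_t.n_hit,
                   false_positives=report_t.false_positive_regions)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _infer_contigs(table: variant_io.SiteTable) -> dict[str, int]:
    contigs: dict[str, int] = {}
    for c, p in zip(table.chrom, table.pos):
        contigs[str(c)] = max(contigs.get(str(c), 0), int(p))
    return contigs


def _gene_alignments(
    gene_ids: Sequence[str],
    genes: Sequence[annotation.GeneModel],
    genome: Mapping[str, np.ndarray],
    seed: int,
) -> dict[str, dict[str, str]]:
    """Synthetic per-gene protein alignments for the conservation stage."""
    from Bio.Seq import Seq

    by_id = {g.gene_id: g for g in genes}
    out: dict[str, dict[str, str]] = {}
    for gid in gene_ids:
        gene = by_id[gid]
        if not gene.cds:
            continue
        seq = "".join(
            genome[gene.chrom][s:e].tobytes().decode() for s, e in gene.cds)
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        protein = str(Seq(seq).translate())
        # stable per-gene seed so alignments do not depend on gene order
        gene_seed = int(hashlib.sha256(f"{seed}:{gid}".encode()).hexdigest()[:8], 16)
        out[gid] = simulate.synthetic_protein_alignment(
            protein, focal_id=gid, seed=gene_seed)
    return out
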