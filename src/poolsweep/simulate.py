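"""Synthetic pooled-sequencing data with known drift structure and sweeps.

The generator emulates a four-population pool-seq design: each pool is a
library of 30 diploids sequenced to ~40x mean depth.  Per-site population
allele frequencies follow the Balding-Nichols model — an ancestral frequency
``p0 ~ Uniform(0.05, 0.95)`` and, for a pool with drift coefficient ``F``,

    p_pool ~ Beta(p0 (1-F)/F, (1-p0) (1-F)/F)

so that ``E[p_pool] = p0`` and ``Var[p_pool] = F p0 (1-p0)``.  Selective
sweeps are implanted as end states: inside each sweep region the selected
pools' frequency of one chosen allele is redrawn from
``Uniform(target_freq, 1)``, which is exactly what window statistics of a
completed sweep see (near-fixation, hence depressed heterozygosity in the
selected pools and elevated differentiation).

Read counts are sampled in two stages — first the 2N chromosomes of the
finite pool (Binomial), then reads on top of the sampled pool composition
(Poisson depth, Binomial allele split) — because a pool of 30 birds adds
variance that reads-from-frequency sampling would miss.

A single global seed feeds a hierarchical generator with one stream per
chromosome per purpose, so per-chromosome results are order-independent and
the whole dataset is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError, DataError
from .variant_io import SiteTable

__all__ = [
    "PoolSpec",
    "SweepSpec",
    "SweepRecord",
    "SweepTruth",
    "SimConfig",
    "AlleleFrequencies",
    "default_pools",
    "default_sweeps",
    "default_config",
    "simulate_allele_frequencies",
    "implant_sweeps",
    "sample_pool_counts",
    "synthetic_genome",
    "simulate_dataset",
    "write_simulation",
    "synthetic_go_map",
    "synthetic_protein_alignment",
]

AS_POOLS = ("FTPD", "LTPD", "CMD")  # artificially selected group
MARKER_GO_TERM = "GO:2000001"  # implanted "response to artificial selection" term


@dataclass(frozen=True)
class PoolSpec:
    """One sequenced pool: a population sample of diploid individuals."""

    name: str
    n_individuals: int = 30

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("pool must contain at least one individual")

    @property
    def haploid_n(self) -> int:
        return 2 * self.n_individuals


@dataclass(frozen=True)
class SweepSpec:
    """A region driven to near-fixation in the selected pools (0-based half-open)."""

    chrom: str
    start: int
    end: int
    selected_pools: tuple[str, ...]
    target_freq: float = 0.95

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigError("sweep end must exceed start")
        if not self.selected_pools:
            raise ConfigError("sweep needs at least one selected pool")
        if not 0.9 <= self.target_freq <= 1.0:
            raise ConfigError("target_freq must lie in [0.9, 1.0]")


@dataclass(frozen=True)
class SweepRecord:
    spec: SweepSpec
    n_sites: int
    realized_mean_freq: float


@dataclass
class SweepTruth:
    """Ground truth of implanted sweeps, one record per spec."""

    records: list[SweepRecord] = field(default_factory=list)

    def to_bed(self, path: str | Path) -> None:
        lines = [
            f"{r.spec.chrom}\t{r.spec.start}\t{r.spec.end}\t"
            f"{'+'.join(r.spec.selected_pools)}\t{r.realized_mean_freq:.4f}"
            for r in self.records
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    def regions(self) -> list[tuple[str, int, int]]:
        return [(r.spec.chrom, r.spec.start, r.spec.end) for r in self.records]


@dataclass
class SimConfig:
    """Full description of one simulated dataset."""

    n_chroms: int = 2
    chrom_len: int = 10_000_000
    snp_rate: float = 0.01
    pools: tuple[PoolSpec, ...] = ()
    baseline_F: float = 0.05
    sweeps: tuple[SweepSpec, ...] = ()
    mean_depth: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pools:
            self.pools = default_pools()
        if self.n_chroms < 1 or self.chrom_len < 1:
            raise ConfigError("need at least one chromosome of positive length")
        if self.snp_rate <= 0:
            raise ConfigError("snp_rate must be positive")
        if not 0 <= self.baseline_F < 1:
            raise ConfigError("baseline_F must lie in [0, 1)")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        names = [p.name for p in self.pools]
        if len(set(names)) != len(names):
            raise ConfigError("pool names must be unique")
        self._validate_sweeps()

    def _validate_sweeps(self) -> None:
        chroms = set(self.chrom_names)
        pool_names = {p.name for p in self.pools}
        by_chrom: dict[str, list[SweepSpec]] = {}
        for s in self.sweeps:
            if s.chrom not in chroms:
                raise ConfigError(f"sweep chromosome {s.chrom!r} not simulated")
            if s.start < 0 or s.end > self.chrom_len:
                raise ConfigError(f"sweep {s} lies outside chromosome bounds")
            if not set(s.selected_pools) <= pool_names:
                raise ConfigError(f"sweep selects unknown pools: {s.selected_pools}")
            by_chrom.setdefault(s.chrom, []).append(s)
        for specs in by_chrom.values():
            specs = sorted(specs, key=lambda s: s.start)
            for a, b in zip(specs, specs[1:]):
                if b.start < a.end:
                    raise ConfigError(f"overlapping sweeps {a} and {b}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_len for c in self.chrom_names}

    @property
    def pool_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.pools)

    def to_dict(self) -> dict:
        return {
            "n_chroms": self.n_chroms,
            "chrom_len": self.chrom_len,
            "snp_rate": self.snp_rate,
            "pools": [{"name": p.name, "n_individuals": p.n_individuals} for p in self.pools],
            "baseline_F": self.baseline_F,
            "sweeps": [
                {
                    "chrom": s.chrom, "start": s.start, "end": s.end,
                    "selected_pools": list(s.selected_pools),
                    "target_freq": s.target_freq,
                }
                for s in self.sweeps
            ],
            "mean_depth": self.mean_depth,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "pools" in d:
            d["pools"] = tuple(PoolSpec(**p) for p in d["pools"])
        if "sweeps" in d:
            d["sweeps"] = tuple(
                SweepSpec(**{**s, "selected_pools": tuple(s["selected_pools"])})
                for s in d["sweeps"]
            )
        return cls(**d)


def default_pools() -> tuple[PoolSpec, ...]:
    return tuple(PoolSpec(name) for name in ("M",) + AS_POOLS)


def default_sweeps(
    n_chroms: int = 2,
    chrom_len: int = 10_000_000,
    n_per_chrom: int = 5,
    width: int = 40_000,
    target_freq: float = 0.95,
    selected_pools: Sequence[str] = AS_POOLS,
    grid: int = 20_000,
) -> tuple[SweepSpec, ...]:
    """Evenly spaced sweep regions, one window wide, aligned to the scan grid.

    Aligning each region to the window step and giving it exactly the width
    of one scan window makes the truth set unambiguous for benchmarking: a
    sweep produces a single fully swept window rather than a ragged run of
    partially swept ones.
    """
    sweeps = []
    for c in range(n_chroms):
        spacing = chrom_len // (n_per_chrom + 1)
        for i in range(n_per_chrom):
            start = ((i + 1) * spacing) // grid * grid
            sweeps.append(SweepSpec(
                chrom=f"chr{c + 1}", start=start, end=start + width,
                selected_pools=tuple(selected_pools), target_freq=target_freq,
            ))
    return tuple(sweeps)


def default_config(seed: int = 7, with_sweeps: bool = True) -> SimConfig:
    """The benchmark dataset: 2 x 10 Mb, ~1 SNP / 100 bp, 4 pools of 30 at 40x."""
    sweeps = default_sweeps() if with_sweeps else ()
    return SimConfig(sweeps=sweeps, seed=seed)


# ---------------------------------------------------------------------------
# Frequency simulation


@dataclass
class ChromFreqs:
    """Per-chromosome site positions (1-based) and allele frequencies."""

    positions: np.ndarray  # 1-based, sorted unique
    p0: np.ndarray
    freqs: np.ndarray  # (n_sites, n_pools) alt-allele frequency per pool


@dataclass
class AlleleFrequencies:
    pools: tuple[str, ...]
    chroms: dict[str, ChromFreqs]

    @property
    def n_sites(self) -> int:
        return sum(len(c.positions) for c in self.chroms.values())

    def copy(self) -> "AlleleFrequencies":
        return AlleleFrequencies(
            pools=self.pools,
            chroms={
                name: ChromFreqs(c.positions.copy(), c.p0.copy(), c.freqs.copy())
                for name, c in self.chroms.items()
            },
        )


def _streams(config: SimConfig, purpose: int) -> list[np.random.Generator]:
    """One independent generator per chromosome for a given purpose index."""
    ss = np.random.SeedSequence([config.seed, purpose])
    return [np.random.default_rng(child) for child in ss.spawn(config.n_chroms)]


def simulate_allele_frequencies(config: SimConfig) -> AlleleFrequencies:
    """Place sites by a Poisson process and draw Balding-Nichols pool frequencies.

    With ``F = 0`` every pool's frequency equals the ancestral ``p0`` exactly
    (degenerate drift); identical configs (including seed) give identical
    output.
    """
    if not config.pools:
        raise ConfigError("at least one pool is required")
    rngs = _streams(config, purpose=0)
    F = config.baseline_F
    chroms: dict[str, ChromFreqs] = {}
    for name, rng in zip(config.chrom_names, rngs):
        n_sites = rng.poisson(config.snp_rate * config.chrom_len)
        pos = np.sort(rng.choice(config.chrom_len, size=min(n_sites, config.chrom_len),
                                 replace=False)) + 1
        p0 = rng.uniform(0.05, 0.95, size=len(pos))
        if F == 0:
            freqs = np.repeat(p0[:, None], len(config.pools), axis=1)
        else:
            scale = (1.0 - F) / F
            freqs = np.empty((len(pos), len(config.pools)))
            for j in range(len(config.pools)):
                freqs[:, j] = rng.beta(p0 * scale, (1.0 - p0) * scale)
        chroms[name] = ChromFreqs(positions=pos, p0=p0, freqs=freqs)
    return AlleleFrequencies(pools=config.pool_names, chroms=chroms)


def implant_sweeps(
    freqs: AlleleFrequencies,
    sweep_specs: Sequence[SweepSpec],
    seed: int,
) -> tuple[AlleleFrequencies, SweepTruth]:
    """Rewrite selected pools' frequencies inside sweep regions toward fixation.

    For each sweep one allele (reference or alternate, chosen at random per
    sweep) is driven to a per-site frequency drawn from
    ``Uniform(target_freq, 1)`` in every selected pool; non-selected pools
    are untouched.  Overlapping sweep specs are rejected.  Returns a new
    frequency set plus the realized truth.
    """
    by_chrom: dict[str, list[SweepSpec]] = {}
    for s in sweep_specs:
        if s.chrom not in freqs.chroms:
            raise ConfigError(f"sweep chromosome {s.chrom!r} not simulated")
        by_chrom.setdefault(s.chrom, []).append(s)
    for specs in by_chrom.values():
        specs_sorted = sorted(specs, key=lambda s: s.start)
        for a, b in zip(specs_sorted, specs_sorted[1:]):
            if b.start < a.end:
                raise ConfigError(f"overlapping sweeps {a} and {b}")

    out = freqs.copy()
    truth = SweepTruth()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    pool_index = {p: j for j, p in enumerate(freqs.pools)}
    for spec in sweep_specs:
        chrom = out.chroms[spec.chrom]
        pos0 = chrom.positions - 1  # 0-based
        mask = (pos0 >= spec.start) & (pos0 < spec.end)
        idx = np.flatnonzero(mask)
        swept_allele_is_alt = bool(rng.integers(2))
        u = rng.uniform(spec.target_freq, 1.0, size=len(idx))
        cols = [pool_index[p] for p in spec.selected_pools]
        new_freq = u if swept_allele_is_alt else 1.0 - u
        for c in cols:
            chrom.freqs[idx, c] = new_freq
        truth.records.append(SweepRecord(
            spec=spec, n_sites=len(idx),
            realized_mean_freq=float(u.mean()) if len(idx) else float("nan"),
        ))
    return out, truth


def sample_pool_counts(
    freqs: AlleleFrequencies,
    config: SimConfig,
    genome: Mapping[str, np.ndarray] | None = None,
) -> SiteTable:
    """Two-stage read sampling: pool chromosomes, then reads.

    Per site and pool: ``k ~ Binomial(2N, p)`` chromosomes carry the
    alternate allele, depth ``d ~ Poisson(mean_depth)``, alternate reads
    ``~ Binomial(d, k / 2N)`` and reference reads make up the rest.  REF/ALT
    bases are taken from the synthetic genome when given, otherwise drawn
    uniformly.
    """
    rngs = _streams(config, purpose=2)
    haploid = np.array([p.haploid_n for p in config.pools])
    all_chrom, all_pos, all_ref, all_alt = [], [], [], []
    ref_blocks, alt_blocks = [], []
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for name, rng in zip(config.chrom_names, rngs):
        chrom = freqs.chroms[name]
        n = len(chrom.positions)
        p = np.clip(chrom.freqs, 0.0, 1.0)
        k = rng.binomial(haploid[None, :], p)
        d = rng.poisson(config.mean_depth, size=(n, len(config.pools)))
        alt_reads = rng.binomial(d, k / haploid[None, :])
        ref_reads = d - alt_reads
        if genome is not None:
            ref_b = genome[name][chrom.positions - 1]
        else:
            ref_b = bases[rng.integers(0, 4, size=n)]
        # alternate: uniformly one of the other three bases
        shift = rng.integers(1, 4, size=n)
        base_idx = np.searchsorted(bases, ref_b)
        alt_b = bases[(base_idx + shift) % 4]
        all_chrom.append(np.full(n, name, dtype=object))
        all_pos.append(chrom.positions)
        all_ref.append(ref_b.astype("U1").astype(object))
        all_alt.append(alt_b.astype("U1").astype(object))
        ref_blocks.append(ref_reads)
        alt_blocks.append(alt_reads)
    n_total = sum(len(p_) for p_ in all_pos)
    return SiteTable(
        pools=config.pool_names,
        chrom=np.concatenate(all_chrom) if n_total else np.empty(0, object),
        pos=np.concatenate(all_pos).astype(np.int64) if n_total else np.empty(0, np.int64),
        ref=np.concatenate(all_ref) if n_total else np.empty(0, object),
        alt=np.concatenate(all_alt) if n_total else np.empty(0, object),
        ref_reads=np.vstack(ref_blocks).astype(np.int64),
        alt_reads=np.vstack(alt_blocks).astype(np.int64),
        is_indel=np.zeros(n_total, dtype=bool),
        indel_len=np.zeros(n_total, dtype=np.int64),
        is_biallelic=np.ones(n_total, dtype=bool),
        contigs=config.chrom_lengths,
    )


def synthetic_genome(config: SimConfig) -> dict[str, np.ndarray]:
    """Deterministic random genome as byte arrays (``S1`` dtype), one per chromosome."""
    rngs = _streams(config, purpose=3)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {
        name: bases[rng.integers(0, 4, size=config.chrom_len)]
        for name, rng in zip(config.chrom_names, rngs)
    }


@dataclass
class SimulationResult:
    config: SimConfig
    table: SiteTable
    truth: SweepTruth
    freqs: AlleleFrequencies
    genome: dict[str, np.ndarray] | None = None


def simulate_dataset(config: SimConfig, with_genome: bool = False) -> SimulationResult:
    """Run the full generator: frequencies, sweeps, read counts, alleles."""
    freqs = simulate_allele_frequencies(config)
    freqs, truth = implant_sweeps(freqs, config.sweeps, seed=config.seed)
    genome = synthetic_genome(config) if with_genome else None
    table = sample_pool_counts(freqs, config, genome=genome)
    return SimulationResult(config=config, table=table, truth=truth,
                            freqs=freqs, genome=genome)


# ---------------------------------------------------------------------------
# Synthetic annotation substrate

GENE_SPACING = 50_000
GENE_LENGTH = 20_000
CDS_OFFSET = 1_000
CDS_LENGTH = 18_000  # divisible by 3


def synthetic_gene_coords(config: SimConfig) -> list[tuple[str, str, int, int, str]]:
    """Fixed-length genes tiled across each chromosome.

    Returns ``(gene_id, chrom, start, end, strand)`` with 0-based half-open
    coordinates; strand alternates so both orientations are exercised.
    """
    genes = []
    for chrom in config.chrom_names:
        n_genes = (config.chrom_len - GENE_LENGTH) // GENE_SPACING + 1
        for i in range(n_genes):
            start = i * GENE_SPACING
            strand = "+" if i % 2 == 0 else "-"
            genes.append((f"{chrom}_g{i + 1:04d}", chrom, start, start + GENE_LENGTH, strand))
    return genes


def write_synthetic_gff(config: SimConfig, path: str | Path) -> int:
    """GFF3 of the synthetic genes (gene/mRNA/CDS, single CDS per gene)."""
    lines = ["##gff-version 3"]
    for name, length in config.chrom_lengths.items():
        lines.append(f"##sequence-region {name} 1 {length}")
    for gid, chrom, start, end, strand in synthetic_gene_coords(config):
        cds_start = start + CDS_OFFSET
        cds_end = cds_start + CDS_LENGTH
        lines.append("\t".join([
            chrom, "poolsweep", "gene", str(start + 1), str(end), ".", strand, ".",
            f"ID=gene:{gid};Name={gid}",
        ]))
        lines.append("\t".join([
            chrom, "poolsweep", "mRNA", str(start + 1), str(end), ".", strand, ".",
            f"ID=tx:{gid}.1;Parent=gene:{gid}",
        ]))
        lines.append("\t".join([
            chrom, "poolsweep", "CDS", str(cds_start + 1), str(cds_end), ".", strand, "0",
            f"ID=cds:{gid}.1;Parent=tx:{gid}.1",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
    return len(synthetic_gene_coords(config))


def synthetic_go_map(
    config: SimConfig,
    truth: SweepTruth,
    n_terms: int = 20,
    terms_per_gene: tuple[int, int] = (1, 4),
    marker_prob_in_sweep: float = 0.9,
    marker_prob_background: float = 0.03,
) -> "pd.DataFrame":
    """Two-column gene-to-GO mapping with an implanted marker term.

    Background terms are assigned uniformly at random; genes overlapping a
    truth sweep carry the marker term with high probability so the
    enrichment stage has a detectable signal.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    regions = truth.regions()
    rows = []
    for gid, chrom, start, end, _ in synthetic_gene_coords(config):
        k = rng.integers(terms_per_gene[0], terms_per_gene[1] + 1)
        for t in sorted(rng.choice(n_terms, size=k, replace=False)):
            rows.append((gid, f"GO:{1000001 + t}"))
        in_sweep = any(c == chrom and start < e and s < end for c, s, e in regions)
        p = marker_prob_in_sweep if in_sweep else marker_prob_background
        if rng.random() < p:
            rows.append((gid, MARKER_GO_TERM))
    return pd.DataFrame(rows, columns=["gene_id", "term"])


def synthetic_protein_alignment(
    protein: str,
    focal_id: str,
    n_other: int = 13,
    divergence: float = 0.03,
    seed: int = 0,
) -> dict[str, str]:
    """Gap-free multiple alignment of a focal protein against simulated orthologs.

    Each ortholog copies the focal sequence and substitutes residues
    independently with probability ``divergence``, so most columns stay
    conserved at the 0.8 identity level.  A synthetic stand-in for a real
    cross-species alignment; rows are named ``species01..``.
    """
    amino = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    base = np.frombuffer(protein.encode(), dtype="S1")
    aln = {focal_id: protein}
    for i in range(n_other):
        seq = base.copy()
        hit = rng.random(len(seq)) < divergence
        seq[hit] = amino[rng.integers(0, len(amino), size=int(hit.sum()))]
        aln[f"species{i + 1:02d}"] = seq.tobytes().decode()
    return aln


# ---------------------------------------------------------------------------
# Output


def write_fasta(genome: Mapping[str, np.ndarray], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            raw = seq.tobytes().decode()
            for i in range(0, len(raw), width):
                fh.write(raw[i:i + width] + "\n")


def write_simulation(
    result: SimulationResult,
    out_dir: str | Path,
    write_genome: bool | None = None,
) -> dict[str, Path]:
    """Write VCF, truth BED, synthetic GFF3, GO map, config YAML (and FASTA).

    VCF positions are 1-based, the truth BED is 0-based half-open.  Returns
    the mapping of logical names to paths.
    """
    from .variant_io import write_vcf

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out}: {exc}") from exc
    paths = {
        "vcf": out / "variants.vcf",
        "truth_bed": out / "truth_sweeps.bed",
        "gff": out / "genes.gff3",
        "go_map": out / "go_map.tsv",
        "config": out / "sim_config.yaml",
    }
    write_vcf(result.table, paths["vcf"])
    result.truth.to_bed(paths["truth_bed"])
    write_synthetic_gff(result.config, paths["gff"])
    synthetic_go_map(result.config, result.truth).to_csv(paths["go_map"], sep="\t", index=False)
    paths["config"].write_text(yaml.safe_dump(result.config.to_dict(), sort_keys=True))
    if write_genome is None:
        write_genome = result.genome is not None
    if write_genome:
        genome = result.genome if result.genome is not None else synthetic_genome(result.config)
        paths["genome"] = out / "genome.fa"
        write_fasta(genome, paths["genome"])
    return paths
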