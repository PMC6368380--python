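# Methods

`poolsweep` detects genomic regions under recent (artificial) selection from
pooled resequencing of a handful of populations, and drills down from
regions to genes to individual candidate variants. This note records the
statistical model, the defaults and why they were chosen, what the
synthetic benchmark does and does not emulate, and the numerical corner
cases.

## Statistics

**Allele frequencies.** Every pool is sequenced as one library, so a pool's
allele frequency at a site is estimated as the alternate read fraction
`alt / (ref + alt)`. A *group* of pools (e.g. the combined artificially
selected populations) is treated as one population by summing read counts
across its pools before taking the fraction; this weighs pools by their
realized coverage, which is how a merged library would behave.

**Fst.** For group frequencies `p_A`, `p_B` at one site,

    pi_S = (2 p_A q_A + 2 p_B q_B) / 2
    pi_T = 2 p̄ q̄,  p̄ = (p_A + p_B)/2
    Fst  = (pi_T − pi_S) / pi_T          (defined as 0 when pi_T = 0)

This is the classical two-population estimator on read frequencies; it
admits the identity `pi_T − pi_S = (p_A − p_B)² / 2`, which the test suite
uses as an independent computation route. Windows aggregate by ratio of
sums, `Σ(pi_T − pi_S) / Σ pi_T`, so monomorphic sites contribute nothing
and low-diversity sites do not blow up the ratio. No pool-size correction
is applied by default: with 60 chromosomes per pool and ~40× coverage the
finite-pool bias is a near-constant offset (~0.02 between two single
pools, ~0.014 for the 1-vs-3-pool comparison) that rank-based selection is
insensitive to.

**Hp (pooled heterozygosity).** Over a window's sites, with per-site major
and minor read counts taken within the scored group,

    Hp = 2 Σn_MAJ Σn_MIN / (Σn_MAJ + Σn_MIN)²

Hp lies in [0, 0.5]; completed sweeps drag it toward 0 in the selected
population. Hp is ranked raw, not Z-transformed.

**Window scheme.** Sliding windows of 40 kb with a 20 kb step, starting at
0 on every chromosome. The terminal window is truncated at the chromosome
end; truncated windows no longer than one step are dropped because they are
wholly contained in their predecessor. Windows with ≤ 10 SNPs are excluded
before any ranking (false-positive control for sparse windows).

**Selection rule.** A retained window is called selected when
(i) its Fst is among the top `k` values genome-wide, and (ii) its Hp in at
least one of the two compared groups is among the bottom `l` values for
that group. Both thresholds are *value*-based (the k-th largest Fst, the
l-th smallest Hp), so boundary ties are admitted and the result is
independent of row order. At the scale of a ~923 Mb anchored genome the
defaults are k = 200 and l = 400; `SelectionRule.scaled(n_windows)`
shrinks both proportionally against a reference count of 23,075 40-kb
bins, so a 20 Mb simulated scan (998 windows) uses k = 9, l = 17. The
reference is deliberately expressed in distinct 40-kb bins rather than
overlapping-window count: half-overlapping windows are not independent
tests, and scaling by overlapping-window count would drive k below the
number of distinct signals any small benchmark can contain.

**Regions.** Selected windows on one chromosome that overlap or abut are
merged into continuous regions (step < window already guarantees selected
neighbours overlap). Genes overlapping a region by ≥ 1 bp (full gene span,
half-open coordinates) are the genes under selection.

**ΔAF.** Per SNP, `|p_A − p_B|` on group read frequencies, rounded half-up
to 2 decimals and binned into ten 10% bins; rounded ΔAF ≤ 0.40 is "low",
≥ 0.41 "high", ≥ 0.81 "fixed or nearly fixed". The three thresholds
partition every scored SNP exactly once (low + high = total). Half-up
rounding is implemented as `floor(100x + 0.5 + 1e−9)`; the epsilon absorbs
binary-representation error so a value printed as 0.405 rounds up exactly
as its decimal rendering would.

**GO enrichment.** Hypergeometric upper tail per term (overlap ≥ observed)
against the whole-annotation background, Benjamini–Hochberg adjusted
across tested terms; zero-overlap terms are skipped. The gene→term map is
taken as already propagated through the ontology; no parent-term
inheritance is performed.

**Candidate variants.** Three conjunctive criteria: in a gene under
selection; coding consequence missense or nonsense (standard genetic code,
strand-aware; CDS indels are frameshift unless length ≡ 0 mod 3); and the
affected protein position conserved in a multiple protein alignment
(consensus identity ≥ 0.8 over non-gap rows, consensus ties broken
alphabetically — the 0.8 threshold is a package choice, exposed in
configuration, standing in for a qualitative "highly conserved" call).
Pooled reads carry no phase, so two SNPs hitting one codon are evaluated
independently with a warning unless explicitly passed as a phased pair, in
which case the codon is rewritten jointly (the mechanism behind
two-substitution amino-acid changes such as Trp→Arg via TGG→CGA).
Candidates are ranked by ΔAF descending.

## Hard filters

Applied in a fixed order, each site charged to the first rule that removes
it, so the filter report is deterministic: (1) non-biallelic records;
(2) any pool's depth outside [10, 500] (absent counts fail the minimum —
the conservative reading); (3) pooled minor-allele frequency across all
pools ≤ 0.05; (4) INDELs of 5 bp or longer; (5) caller annotation
thresholds, evaluated only when the annotation is present — SNPs fail on
QD < 2, FS > 60, MQ < 40, MQRankSum < −12.5 or ReadPosRankSum < −8;
INDELs on QD < 2, FS > 200 or ReadPosRankSum < −20. Synthetic data
carries no annotations, so rule (5) is exercised by hand-built fixtures.
The filter is idempotent and conserves counts (removed + retained =
input), both under property test.

## Synthetic benchmark

The generator emulates a four-population pool-seq design: pools `M`
(ancestral) and `FTPD`, `LTPD`, `CMD` (artificially selected, jointly
"AS"), 30 diploids per pool, mean depth 40×, ~1 SNP per 100 bp, two 10 Mb
chromosomes.

*Drift.* Ancestral frequency `p0 ~ Uniform(0.05, 0.95)` per site; each
pool draws `p ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F)` (Balding–Nichols), which
has mean `p0` and variance `F p0 (1−p0)`. Default `F = 0.05` per pool is a
free parameter expressing "recently diverged breeds", not an estimate of
any real population's divergence.

*Sweeps.* A sweep is an end state, not a trajectory: inside the region the
selected pools' frequency of one randomly chosen allele is redrawn from
`Uniform(target_freq, 1)` per site (default target 0.95). The default
benchmark implants 10 sweeps (5 per chromosome, evenly spaced), each
exactly one window wide (40 kb) and aligned to the 20 kb step grid, in all
three AS pools. Grid alignment makes the truth set crisp — each sweep
yields exactly one fully swept window — so recovery measures the selection
rule rather than the accident of window phase.

*Reads.* Two-stage sampling per site and pool: `k ~ Binomial(2N, p)`
chromosomes carry the alternate allele, depth `d ~ Poisson(40)`, alternate
reads `~ Binomial(d, k/2N)`. The binomial pool stage reproduces the extra
variance of a 30-bird pool that direct read sampling from `p` would miss.

*Annotation substrate.* 20 kb genes every 50 kb (alternating strand, one
18 kb CDS), a 20-term random GO map plus a marker term assigned to
sweep-overlapping genes with probability 0.9 (background 0.03) so the
enrichment stage has a planted signal, and per-gene synthetic protein
"alignments" of 14 rows at 3% divergence for the conservation stage.

*Determinism.* One global seed feeds a hierarchical `SeedSequence` with an
independent stream per chromosome and purpose, so outputs are
byte-identical across reruns and per-chromosome results do not depend on
how many chromosomes are simulated.

*What the benchmark does not emulate:* sequencing error and base-quality
structure, mapping artefacts, linkage disequilibrium within pools (sites
are independent given `p0`), partial or soft sweeps, INDEL generation, and
real gene structure (no multi-exon CDS in the generator, though the GFF
reader and classifier support them). Passing the recovery test therefore
shows the statistics and selection machinery behave as designed under the
stated noise model — not that real data of this design will yield 90%
sensitivity.

## Benchmark results recomputed by `scripts/acceptance.py`

On the default benchmark the scan retains 998 windows, selects 9 (k = 9,
l = 17), merges them into 9 regions, recovers 9 of 10 implanted sweeps
(sensitivity 0.9 — the top-9 Fst cutoff excludes exactly one of ten
near-tied fully swept windows) with 0 false-positive regions. The
sweep-free control selects ≤ 2 windows, reports 0 true positives, and its
window-Fst mean matches the genome-wide aggregate Fst; a drift-free
(`F = 0`) run has mean window Fst ≈ 0.014, pure read-sampling noise. All
of these numbers are recomputed at run time by the acceptance script and
asserted by the test suite; problem sizes (2 × 10 Mb, ~200k SNPs) were
chosen so the whole chain runs in seconds.

## Numerical and degenerate-input choices

- Zero-depth pools raise an explicit error in scalar accessors and are
  skipped (and tallied) in vectorized paths.
- A window with Σpi_T = 0 reports Fst 0 with a monomorphic-window warning;
  windows with no usable sites are excluded by the SNP-count rule.
- If fewer windows are retained than k or l, thresholds clamp to all
  windows with a warning.
- Unsorted variant input is an error, never silently sorted.
- Coordinates are 1-based only at the VCF/sync boundary; everywhere else
  0-based half-open. Abutting intervals do not overlap.
- Sync sites fixed for a single non-reference base are biallelic with that
  base as the alternate; sites fixed for the reference keep a placeholder
  alternate `N` with zero alternate reads, so VCF↔sync round trips
  preserve counts exactly.
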