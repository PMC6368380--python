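"""ΔAF computation/binning, coding consequences, conservation, candidate filter."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from poolsweep.annotation import GeneModel
from poolsweep.errors import AnnotationError, DataError
from poolsweep.prioritize import (
    bin_delta_af,
    classify_coding_effect,
    column_conservation,
    delta_af,
    delta_af_table,
    prioritize_variants,
)
from poolsweep.variant_io import SiteTable

from conftest import make_site


def var(pos, ref, alt, chrom="chr1"):
    return SimpleNamespace(chrom=chrom, pos=pos, ref=ref, alt=alt)


class TestDeltaAF:
    def test_equal_frequencies_zero(self):
        s = make_site({"A": (30, 30), "B": (10, 10)})
        assert delta_af(s, ("A",), ("B",)) == 0.0

    def test_reported_igf2r_frequencies(self):
        # group frequencies 0.9130 and 0.2955 differ by 0.6175
        s = make_site({"A": (87, 913), "B": (7045, 2955)})
        assert delta_af(s, ("A",), ("B",)) == pytest.approx(0.6175)

    def test_full_fixation_boundary(self):
        s = make_site({"A": (0, 50), "B": (50, 0)})
        assert delta_af(s, ("A",), ("B",)) == 1.0

    def test_missing_depth_raises(self):
        s = make_site({"A": (0, 0), "B": (10, 10)})
        with pytest.raises(DataError):
            delta_af(s, ("A",), ("B",))

    @given(st.tuples(*[st.integers(0, 300)] * 4))
    def test_symmetry_and_relabeling(self, c):
        ra, aa, rb, ab = c
        if ra + aa == 0 or rb + ab == 0:
            return
        s = make_site({"A": (ra, aa), "B": (rb, ab)})
        swapped = make_site({"A": (rb, ab), "B": (ra, aa)})
        relabeled = make_site({"A": (aa, ra), "B": (ab, rb)})
        d = delta_af(s, ("A",), ("B",))
        assert d == pytest.approx(delta_af(swapped, ("A",), ("B",)))
        assert d == pytest.approx(delta_af(relabeled, ("A",), ("B",)))
        assert 0.0 <= d <= 1.0


class TestBinning:
    def test_bin_placement(self):
        s = bin_delta_af([0.05, 0.15, 0.95])
        assert s.histogram == (1, 1, 0, 0, 0, 0, 0, 0, 0, 1)
        assert (s.low, s.high, s.fixed, s.total) == (2, 1, 1, 3)

    def test_half_up_rounding_at_boundary(self):
        # 0.405 rounds to 0.41 (half-up) -> high bin
        s = bin_delta_af([0.405])
        assert s.high == 1 and s.low == 0
        s2 = bin_delta_af([0.404])
        assert s2.low == 1

    def test_fixed_threshold(self):
        s = bin_delta_af([0.805, 0.80, 0.81])
        assert s.fixed == 2  # 0.805 -> 0.81, 0.81 -> 0.81; 0.80 stays low of threshold

    def test_empty_input(self):
        s = bin_delta_af([])
        assert s.histogram == (0,) * 10 and s.total == 0

    @given(st.lists(st.floats(0, 1, allow_nan=False), max_size=200))
    def test_conservation_and_partition(self, values):
        s = bin_delta_af(values)
        assert sum(s.histogram) == s.total == len(values)
        assert s.low + s.high == s.total  # <=0.40 / >=0.41 partition is exhaustive
        assert s.fixed <= s.high

    def test_table_bins_match_scalar_binning(self, small_sim):
        t = small_sim.table
        df = delta_af_table(t, ("M",), ("FTPD", "LTPD", "CMD"))
        s = bin_delta_af(df)
        assert s.total == len(df)
        assert np.array_equal(
            np.bincount(df["bin"], minlength=10), np.array(s.histogram))


def forward_gene(cds=((100, 130),), start=0, end=300, strand="+"):
    return GeneModel(gene_id="g1", chrom="chr1", start=start, end=end,
                     strand=strand, cds=cds)


def genome_from(seq, chrom="chr1"):
    return {chrom: np.frombuffer(seq.encode(), dtype="S1")}


class TestCodingEffect:
    def make_genome(self, codons, pad=100, length=300):
        seq = "A" * pad + codons + "A" * (length - pad - len(codons))
        return genome_from(seq)

    def test_synonymous_third_position(self):
        genome = self.make_genome("GCTGGG", pad=100)
        gene = forward_gene(cds=((100, 106),), end=200)
        eff = classify_coding_effect(var(103, "T", "C"), gene, genome)
        assert eff.category == "synonymous" and eff.ref_aa == eff.alt_aa == "A"

    def test_nonsense_stop_gained(self):
        genome = self.make_genome("TGGGGG")
        gene = forward_gene(cds=((100, 106),), end=200)
        eff = classify_coding_effect(var(103, "G", "A"), gene, genome)
        assert eff.category == "nonsense" and eff.ref_aa == "W" and eff.alt_aa == "*"

    def test_joint_phased_snps_rewrite_one_codon(self):
        # TGG (Trp) with phased changes at codon positions 1 and 3 -> CGA (Arg)
        genome = self.make_genome("TGGGGG")
        gene = forward_gene(cds=((100, 106),), end=200)
        first, third = var(101, "T", "C"), var(103, "G", "A")
        eff = classify_coding_effect(first, gene, genome, companions=[third])
        assert eff.category == "missense"
        assert (eff.ref_aa, eff.alt_aa) == ("W", "R")
        # independently the two changes are synonymous-of-other-aa / nonsense-free
        solo = classify_coding_effect(third, gene, genome)
        assert solo.alt_aa == "*"  # TGA without phasing: a stop

    def test_frameshift_and_inframe_indels(self):
        genome = self.make_genome("TGGGGG")
        gene = forward_gene(cds=((100, 106),), end=200)
        two_bp = SimpleNamespace(chrom="chr1", pos=101, ref="TGC", alt="T")
        assert classify_coding_effect(two_bp, gene, genome).category == "frameshift"
        three_bp = SimpleNamespace(chrom="chr1", pos=101, ref="TGCA", alt="T")
        assert classify_coding_effect(three_bp, gene, genome).category == "inframe_indel"

    def test_noncoding_within_gene(self):
        genome = self.make_genome("TGGGGG")
        gene = forward_gene(cds=((100, 106),), end=200)
        assert classify_coding_effect(var(50, "A", "G"), gene, genome).category == "noncoding"

    def test_outside_gene_is_contract_violation(self):
        genome = self.make_genome("TGGGGG")
        gene = forward_gene(cds=((100, 106),), start=90, end=200)
        with pytest.raises(DataError):
            classify_coding_effect(var(10, "A", "G"), gene, genome)

    def test_cds_length_must_be_codon_multiple(self):
        genome = self.make_genome("TGGGG")
        gene = forward_gene(cds=((100, 105),), end=200)
        with pytest.raises(AnnotationError):
            classify_coding_effect(var(101, "T", "C"), gene, genome)

    def test_reverse_strand_equals_forward_of_revcomp(self):
        # minus-strand CDS reading CAT|TGG from the reverse complement
        from Bio.Seq import Seq

        core = "CCATGA"  # genome plus strand; revcomp = TCATGG
        genome = self.make_genome(core)
        gene_rev = forward_gene(cds=((100, 106),), end=200, strand="-")
        # variant G>C at genomic pos 105 (1-based 106): transcript base C>G at codon 1 pos 2
        eff_rev = classify_coding_effect(var(105, "G", "C"), gene_rev, genome)
        # equivalent forward construct: transcript sequence TCATGG with A>G? build directly
        fwd_genome = genome_from("A" * 100 + str(Seq(core).reverse_complement()) + "A" * 94)
        gene_fwd = forward_gene(cds=((100, 106),), end=200, strand="+")
        eff_fwd = classify_coding_effect(var(102, "C", "G"), gene_fwd, fwd_genome)
        assert (eff_rev.category, eff_rev.ref_aa, eff_rev.alt_aa, eff_rev.protein_pos) == \
               (eff_fwd.category, eff_fwd.ref_aa, eff_fwd.alt_aa, eff_fwd.protein_pos)

    def test_exhaustive_sense_codon_substitutions_against_code_oracle(self):
        from oracles import GENETIC_CODE

        n_checked = 0
        for codon, ref_aa in GENETIC_CODE.items():
            if ref_aa == "*":
                continue  # only sense source codons
            genome = self.make_genome(codon + "GGG")
            gene = forward_gene(cds=((100, 106),), end=200)
            for offset in range(3):
                for base in "ACGT":
                    if base == codon[offset]:
                        continue
                    alt_codon = codon[:offset] + base + codon[offset + 1:]
                    eff = classify_coding_effect(
                        var(101 + offset, codon[offset], base), gene, genome)
                    expected_aa = GENETIC_CODE[alt_codon]
                    if expected_aa == ref_aa:
                        expected = "synonymous"
                    elif expected_aa == "*":
                        expected = "nonsense"
                    else:
                        expected = "missense"
                    assert eff.category == expected, (codon, alt_codon)
                    assert eff.ref_aa == ref_aa and eff.alt_aa == expected_aa
                    n_checked += 1
        assert n_checked == 61 * 9


class TestConservation:
    def test_fully_identical_column(self):
        aln = {f"s{i}": "MKV" for i in range(13)} | {"duck": "MKV"}
        call = column_conservation(aln, 2, "duck")
        assert call.identity == 1.0 and call.conserved

    def test_half_matching_not_conserved(self):
        rows = {f"s{i}": ("MKV" if i < 7 else "MRV") for i in range(13)}
        aln = rows | {"duck": "MKV"}
        # column 2: 8 of 14 are K -> 0.571 < 0.8
        call = column_conservation(aln, 2, "duck", threshold=0.8)
        assert call.identity == pytest.approx(8 / 14) and not call.conserved

    def test_gaps_excluded_from_denominator(self):
        # 10 rows, 2 gaps in the column, 7 of the 8 residues match the consensus
        aln = {f"s{i}": "AK" for i in range(7)}
        aln |= {"s7": "A-", "s8": "A-", "duck": "AR"}
        call = column_conservation(aln, 2, "duck")
        assert call.identity == pytest.approx(7 / 8)  # 0.875, conserved at 0.8
        assert call.conserved

    def test_focal_gaps_shift_columns(self):
        aln = {"duck": "M-KV", "s1": "MAKV", "s2": "MAKV"}
        call = column_conservation(aln, 2, "duck")  # duck residue 2 = K, column 3
        assert call.identity == 1.0

    def test_position_beyond_focal_sequence_rejected(self):
        aln = {"duck": "M-V", "s1": "M-V"}
        with pytest.raises(DataError):
            column_conservation(aln, 5, "duck")

    def test_gapped_orthologs_leave_singleton_consensus(self):
        aln = {"duck": "MKV", "s1": "M-V", "s2": "M-V"}
        call = column_conservation(aln, 2, "duck")
        assert call.identity == pytest.approx(1.0)


class TestPrioritizeVariants:
    def build_dataset(self):
        """200 SNPs in one selected region; 5 planted qualifying variants."""
        rng = np.random.default_rng(42)
        n = 200
        L = 40_000
        # gene covering [1000, 31000) with CDS [1000, 30999+1)? use CDS length 27000
        gene = GeneModel(gene_id="G", chrom="chr1", start=500, end=31_000,
                         strand="+", cds=((1_000, 28_000),))
        bases = np.frombuffer(b"ACGT", dtype="S1")
        genome_arr = bases[np.random.default_rng(1).integers(0, 4, size=L)].copy()
        genome = {"chr1": genome_arr}
        # plant 5 missense sites with conserved columns: force codon TGG -> CGG (W->R)
        planted_pos = [1_300 + 300 * i for i in range(5)]  # codon-start offsets in CDS
        for p in planted_pos:
            ci = p - 1_000
            assert ci % 3 == 0
            genome_arr[p:p + 3] = np.frombuffer(b"TGG", dtype="S1")
        positions = sorted(set(rng.integers(600, 39_000, size=n * 2).tolist()) -
                           set(q for p in planted_pos for q in (p, p + 1, p + 2)))[:n - 5]
        positions = sorted(positions + [p for p in planted_pos])
        records = []
        for pos0 in positions:
            ref = genome_arr[pos0].decode()
            if pos0 in planted_pos:
                alt = "C"  # TGG -> CGG missense
            else:
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            records.append(make_site({"A": (5, 45), "B": (45, 5)}, pos=pos0 + 1,
                                     ref=ref, alt=alt))
        table = SiteTable.from_records(records, ("A", "B"))
        regions = pd.DataFrame([("chr1", 0, L)], columns=["chrom", "start", "end"])
        # alignment conserving every position
        from Bio.Seq import Seq

        protein = str(Seq(genome_arr[1_000:28_000].tobytes().decode()).translate())
        aln = {"G": protein} | {f"s{i}": protein for i in range(13)}
        return table, regions, [gene], {"G": aln}, genome, planted_pos

    def test_planted_variants_recovered_exactly(self):
        table, regions, genes, alns, genome, planted = self.build_dataset()
        cands, excl = prioritize_variants(
            table, regions, genes, alns, genome, ("A",), ("B",))
        got = sorted(c.pos - 1 for c in cands)
        # brute-force oracle: evaluate the three criteria per site
        expected = []
        gene = genes[0]
        for site in table:
            pos0 = site.pos - 1
            if not (gene.start <= pos0 < gene.end):
                continue
            from poolsweep.prioritize import classify_coding_effect as cce

            eff = cce(site, gene, genome)
            if eff.category in ("missense", "nonsense"):
                expected.append(pos0)
        assert got == sorted(expected)
        assert set(planted) <= set(got)
        # non-candidates have recorded reasons
        assert len(excl) + len(cands) == sum(
            1 for _ in table if True)

    def test_sorted_by_delta_af_descending(self):
        table, regions, genes, alns, genome, _ = self.build_dataset()
        cands, _ = prioritize_variants(table, regions, genes, alns, genome, ("A",), ("B",))
        dafs = [c.delta_af for c in cands]
        assert dafs == sorted(dafs, reverse=True)

    def test_gene_without_alignment_unevaluable(self):
        table, regions, genes, alns, genome, _ = self.build_dataset()
        cands, excl = prioritize_variants(table, regions, genes, {}, genome, ("A",), ("B",))
        assert cands == []
        assert (excl["reason"] == "no_alignment").sum() > 0

    def test_output_subset_of_region_sites(self):
        table, regions, genes, alns, genome, _ = self.build_dataset()
        cands, _ = prioritize_variants(table, regions, genes, alns, genome, ("A",), ("B",))
        region_positions = set()
        for r in regions.itertuples():
            region_positions |= {int(p) for p in table.pos
                                 if r.start <= int(p) - 1 < r.end}
        assert {c.pos for c in cands} <= region_positions
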