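import numpy as np
import pytest

from asescan.context_annotation import (
    FeatureClass,
    classify_location,
    distance_to_tss,
    methylation_ase_crosscheck,
    methylation_percent,
)
from asescan.io_formats import GeneModel
from asescan.synthetic_data import SimulationConfig, simulate_population
from asescan.types import AlleleCountRecord, MethylationRecord, Variant
from conftest import make_matrix


def V(vid, pos, chrom="chr1", ref="A", alt="G"):
    return Variant(vid, chrom, pos, ref, alt)


GENE_PLUS = GeneModel(
    gene_id="gplus",
    chrom="chr1",
    start=999,     # 1-based 1000..5000
    end=5000,
    strand="+",
    exons=((999, 1500), (2999, 3500), (4499, 5000)),
    five_prime_utrs=((999, 1100),),
    three_prime_utrs=((4899, 5000),),
)

GENE_MINUS = GeneModel(
    gene_id="gminus", chrom="chr1", start=99, end=900, strand="-",
    exons=((99, 900),),
)

GENE_NC = GeneModel(
    gene_id="gnc", chrom="chr1", start=9999, end=12000, strand="+",
    exons=((9999, 12000),), coding=False,
)


class TestDistanceToTss:
    def test_plus_strand_uses_leftmost_base(self):
        assert GENE_PLUS.tss == 1000
        assert distance_to_tss(V("v", 1_500_000), GeneModel(
            "g", "chr1", 999_999, 2_000_000, "+")) == 500_000

    def test_zero_at_tss(self):
        assert distance_to_tss(V("v", 1000), GENE_PLUS) == 0

    def test_minus_strand_uses_rightmost_base(self):
        # gene spans 1-based 100..900 on -, variant at 950 -> distance 50
        assert GENE_MINUS.tss == 900
        assert distance_to_tss(V("v", 950), GENE_MINUS) == 50


class TestClassifyLocation:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (7000, FeatureClass.INTERGENIC),       # between genes
            (2000, FeatureClass.INTRONIC),          # middle of intron 1
            (1050, FeatureClass.FIVE_PRIME_UTR),
            (4950, FeatureClass.THREE_PRIME_UTR),
            (3200, FeatureClass.EXONIC),            # internal exon body
            (10_500, FeatureClass.NON_CODING_TRANSCRIPT),
        ],
    )
    def test_priority_classes(self, pos, expected):
        models = [GENE_PLUS, GENE_NC]
        assert classify_location(V("v", pos), models) == expected

    def test_splice_region_two_bases_into_intron(self):
        # exon 1 ends at 0-based 1500; 1-based 1502 is 2 bp into the intron
        assert classify_location(V("v", 1502), [GENE_PLUS]) == FeatureClass.SPLICE_REGION

    def test_splice_region_exonic_side_window(self):
        # within 3 bp of the junction on the exonic side
        assert classify_location(V("v", 1500), [GENE_PLUS]) == FeatureClass.SPLICE_REGION
        assert classify_location(V("v", 3001), [GENE_PLUS]) == FeatureClass.SPLICE_REGION

    def test_deep_intron_beyond_splice_window_is_intronic(self):
        # 9 bp into the intron: outside the 8 bp intronic window
        assert classify_location(V("v", 1509), [GENE_PLUS]) == FeatureClass.INTRONIC

    def test_single_exon_gene_has_no_splice_region(self):
        assert classify_location(V("v", 900), [GENE_MINUS]) == FeatureClass.EXONIC

    def test_classes_partition_variants(self):
        models = [GENE_PLUS, GENE_MINUS, GENE_NC]
        variants = [V(f"v{p}", p) for p in range(500, 13_000, 37)]
        classes = [classify_location(v, models) for v in variants]
        assert len(classes) == len(variants)  # exactly one class each
        assert set(classes) >= {FeatureClass.INTRONIC, FeatureClass.INTERGENIC}


class TestMethylationPercent:
    @pytest.mark.parametrize(
        "m,u,expected", [(5, 15, 25.0), (7, 0, 100.0), (0, 9, 0.0)]
    )
    def test_quoted_formula(self, m, u, expected):
        rec = MethylationRecord("S1", "chr1", 100, m, u)
        assert methylation_percent(rec) == pytest.approx(expected)

    def test_zero_total_rejected_at_construction(self):
        with pytest.raises(ValueError):
            MethylationRecord("S1", "chr1", 100, 0, 0)


def crosscheck_setup():
    """One sample het at both SNPs: aseQTL alt allele is the methylatable C,
    carried on haplotype B together with the ASE alt allele."""
    aseqtl = Variant("q", "chr1", 100, "T", "C")
    ase = Variant("a", "chr1", 500, "A", "G")
    matrix = make_matrix(
        [[(0, 1), (0, 1)], [(0, 1), (0, 0)]],
        variants=[aseqtl, ase],
        samples=["S1", "S2"],
    )
    return aseqtl, ase, matrix


class TestMethylationAseCrosscheck:
    def test_silenced_in_phase_allele_is_consistent(self):
        aseqtl, ase, matrix = crosscheck_setup()
        counts = {("S1", "a"): AlleleCountRecord("S1", "a", 30, 0)}
        meth = [MethylationRecord("S1", "chr1", 100, 18, 2)]  # 90%
        (rep,) = methylation_ase_crosscheck(aseqtl, ase, matrix, counts, meth)
        # methylated C on hap B, in phase with ASE alt; alt is unexpressed
        assert rep.in_phase_ase_allele == "alt"
        assert rep.verdict == "consistent"

    def test_balanced_expression_with_full_methylation_is_inconsistent(self):
        aseqtl, ase, matrix = crosscheck_setup()
        counts = {("S1", "a"): AlleleCountRecord("S1", "a", 15, 15)}
        meth = [MethylationRecord("S1", "chr1", 100, 20, 0)]  # 100%
        (rep,) = methylation_ase_crosscheck(aseqtl, ase, matrix, counts, meth)
        assert rep.verdict == "inconsistent"

    def test_homozygous_ase_snp_uninformative(self):
        aseqtl, ase, matrix = crosscheck_setup()
        counts = {("S2", "a"): AlleleCountRecord("S2", "a", 20, 0)}
        meth = [MethylationRecord("S2", "chr1", 100, 20, 0)]
        (rep,) = methylation_ase_crosscheck(aseqtl, ase, matrix, counts, meth)
        assert rep.verdict == "uninformative"

    def test_low_methylation_uninformative(self):
        aseqtl, ase, matrix = crosscheck_setup()
        counts = {("S1", "a"): AlleleCountRecord("S1", "a", 30, 0)}
        meth = [MethylationRecord("S1", "chr1", 100, 1, 19)]  # 5%
        (rep,) = methylation_ase_crosscheck(aseqtl, ase, matrix, counts, meth)
        assert rep.verdict == "uninformative"

    def test_unphased_genotype_uninformative(self):
        aseqtl, ase, matrix = crosscheck_setup()
        matrix.phased[0, 0] = False
        counts = {("S1", "a"): AlleleCountRecord("S1", "a", 30, 0)}
        meth = [MethylationRecord("S1", "chr1", 100, 18, 2)]
        (rep,) = methylation_ase_crosscheck(aseqtl, ase, matrix, counts, meth)
        assert rep.verdict == "uninformative"

    def test_ambiguous_when_neither_allele_is_cytosine(self):
        aseqtl = Variant("q", "chr1", 100, "A", "G")
        ase = Variant("a", "chr1", 500, "A", "G")
        matrix = make_matrix(
            [[(0, 1), (0, 1)]], variants=[aseqtl, ase], samples=["S1"]
        )
        counts = {("S1", "a"): AlleleCountRecord("S1", "a", 30, 0)}
        meth = [MethylationRecord("S1", "chr1", 100, 18, 2)]
        (rep,) = methylation_ase_crosscheck(aseqtl, ase, matrix, counts, meth)
        assert rep.methylated_allele == "ambiguous"
        assert rep.verdict == "uninformative"


def test_synthetic_methylation_mostly_consistent():
    """With complete cis silencing and methylation planted on the silenced
    haplotype, nearly all informative samples read as consistent."""
    cfg = SimulationConfig(causal_effect=1.0, n_genes=4, rng_seed=23)
    ds = simulate_population(cfg)
    counts = {(c.sample, c.variant): c for c in ds.counts}
    n_consistent = n_informative = 0
    for g in ds.truth.genes:
        aseqtl = ds.matrix.variant(g.causal_id)
        ase = ds.matrix.variant(g.marker_id)
        reports = methylation_ase_crosscheck(
            aseqtl, ase, ds.matrix, counts, ds.methylation
        )
        for rep in reports:
            if rep.verdict == "uninformative":
                continue
            n_informative += 1
            n_consistent += rep.verdict == "consistent"
    assert n_informative > 0
    assert n_consistent >= 0.9 * n_informative
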