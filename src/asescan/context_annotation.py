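"""Genomic context for aseQTLs: TSS distance, feature-class annotation and
phase-aware methylation/ASE cross-checks.

Feature classification is a minimal transparent classifier over GFF3 gene
models (priority: splice_region > UTRs > exonic > intronic >
non_coding_transcript > intergenic; splice regions are within 3 bp on the
exonic side or 8 bp on the intronic side of an exon/intron junction). It is
deliberately simpler than a full consequence predictor: exonic variants are
not translated, only flagged as potentially missense-capable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .io_formats import GeneModel
from .types import (
    MISSING,
    AlleleCountRecord,
    MethylationRecord,
    PhasedGenotypeMatrix,
    Variant,
)

SPLICE_EXONIC_BP = 3
SPLICE_INTRONIC_BP = 8


class FeatureClass(str, Enum):
    SPLICE_REGION = "splice_region"
    FIVE_PRIME_UTR = "5_prime_UTR"
    THREE_PRIME_UTR = "3_prime_UTR"
    EXONIC = "exonic"
    INTRONIC = "intronic"
    NON_CODING_TRANSCRIPT = "non_coding_transcript"
    INTERGENIC = "intergenic"


def distance_to_tss(variant: Variant, gene: GeneModel) -> int:
    """Unsigned distance in bp from the variant to the gene's TSS (leftmost
    base of + strand genes, rightmost of - strand genes)."""
    return abs(variant.pos - gene.tss)


def _near_junction(pos0: int, gene: GeneModel) -> bool:
    """Is a 0-based position within the splice window of an internal
    exon/intron junction?"""
    if len(gene.exons) < 2:
        return False
    junctions = []
    for idx, (start, end) in enumerate(gene.exons):
        if idx > 0:
            junctions.append(("acceptor", start))  # intron | exon boundary
        if idx < len(gene.exons) - 1:
            junctions.append(("donor", end))  # exon | intron boundary
    for kind, bound in junctions:
        if kind == "donor":
            exonic = bound - SPLICE_EXONIC_BP <= pos0 < bound
            intronic = bound <= pos0 < bound + SPLICE_INTRONIC_BP
        else:
            exonic = bound <= pos0 < bound + SPLICE_EXONIC_BP
            intronic = bound - SPLICE_INTRONIC_BP <= pos0 < bound
        if exonic or intronic:
            return True
    return False


def classify_location(variant: Variant, gene_models: list[GeneModel]) -> FeatureClass:
    """Assign exactly one feature class to a variant.

    When the variant falls in several genes, the highest-priority class
    across them wins.
    """
    pos0 = variant.pos - 1
    classes: list[FeatureClass] = []
    for gene in gene_models:
        if gene.chrom != variant.chrom or not (gene.start <= pos0 < gene.end):
            continue
        if _near_junction(pos0, gene):
            classes.append(FeatureClass.SPLICE_REGION)
            continue
        if any(s <= pos0 < e for s, e in gene.five_prime_utrs):
            classes.append(FeatureClass.FIVE_PRIME_UTR)
            continue
        if any(s <= pos0 < e for s, e in gene.three_prime_utrs):
            classes.append(FeatureClass.THREE_PRIME_UTR)
            continue
        in_exon = any(s <= pos0 < e for s, e in gene.exons)
        if not gene.coding:
            classes.append(FeatureClass.NON_CODING_TRANSCRIPT)
        elif in_exon:
            classes.append(FeatureClass.EXONIC)
        else:
            classes.append(FeatureClass.INTRONIC)
    if not classes:
        return FeatureClass.INTERGENIC
    priority = list(FeatureClass)
    return min(classes, key=priority.index)


def methylation_percent(record: MethylationRecord) -> float:
    """Percent methylation: 100 * methylated / (methylated + unmethylated)."""
    total = record.methylated_count + record.unmethylated_count
    return 100.0 * record.methylated_count / total


@dataclass(frozen=True)
class CrosscheckReport:
    sample: str
    aseqtl_variant: str
    ase_variant: str
    methylation_percent: float
    methylated_allele: str  # "ref", "alt" or "ambiguous"
    in_phase_ase_allele: str  # ASE-SNP allele on the methylated haplotype
    expressed_fraction_in_phase: float | None
    verdict: str  # consistent | inconsistent | uninformative
    note: str = ""


def methylation_ase_crosscheck(
    aseqtl: Variant,
    ase_snp: Variant,
    matrix: PhasedGenotypeMatrix,
    counts: dict[tuple[str, str], AlleleCountRecord],
    methylation: list[MethylationRecord],
    methylated_min_percent: float = 30.0,
    silenced_max_fraction: float = 0.35,
) -> list[CrosscheckReport]:
    """Phase-aware consistency check between aseQTL methylation and ASE.

    For each sample with methylation data at the aseQTL position and
    heterozygous, phased genotypes at both SNPs: the methylated aseQTL
    allele is the one carrying the cytosine (only unambiguous when exactly
    one allele is a C); the ASE-SNP allele in phase with it should be
    silenced, so its expressed read fraction should be low. Verdicts:

    - ``consistent``: in-phase allele fraction <= ``silenced_max_fraction``;
    - ``inconsistent``: methylated but expression balanced or skewed the
      wrong way (in-phase fraction above the silencing bound);
    - ``uninformative``: homozygous/unphased/uncovered/ambiguous allele or
      methylation below ``methylated_min_percent``.
    """
    j_q = matrix.variant_index(aseqtl.id)
    j_a = matrix.variant_index(ase_snp.id)
    if aseqtl.ref_allele == "C" and aseqtl.alt_allele != "C":
        meth_allele, meth_code = "ref", 0
    elif aseqtl.alt_allele == "C" and aseqtl.ref_allele != "C":
        meth_allele, meth_code = "alt", 1
    else:
        meth_allele, meth_code = "ambiguous", None

    reports: list[CrosscheckReport] = []
    for rec in methylation:
        if rec.chrom != aseqtl.chrom or rec.pos != aseqtl.pos:
            continue
        pct = methylation_percent(rec)
        if rec.sample not in matrix._sidx:
            continue
        i = matrix.sample_index(rec.sample)

        def report(verdict: str, note: str = "", in_phase: str = "",
                   frac: float | None = None) -> CrosscheckReport:
            return CrosscheckReport(
                rec.sample, aseqtl.id, ase_snp.id, pct, meth_allele,
                in_phase, frac, verdict, note,
            )

        if meth_code is None:
            reports.append(report("uninformative", "ambiguous methylated allele"))
            continue
        if pct < methylated_min_percent:
            reports.append(report("uninformative", "below methylation threshold"))
            continue
        if not matrix.het_mask(j_a)[i]:
            reports.append(report("uninformative", "ASE SNP not heterozygous"))
            continue
        if not matrix.het_mask(j_q)[i]:
            reports.append(report("uninformative", "aseQTL not heterozygous"))
            continue
        if not (matrix.phased[i, j_q] and matrix.phased[i, j_a]):
            reports.append(report("uninformative", "unphased genotype"))
            continue
        count = counts.get((rec.sample, ase_snp.id))
        if count is None or count.depth == 0:
            reports.append(report("uninformative", "no expression data"))
            continue
        hap = 0 if matrix.haps[i, j_q, 0] == meth_code else 1
        ase_allele_code = int(matrix.haps[i, j_a, hap])
        in_phase = "ref" if ase_allele_code == 0 else "alt"
        frac = (count.ref_count if ase_allele_code == 0 else count.alt_count) / count.depth
        verdict = "consistent" if frac <= silenced_max_fraction else "inconsistent"
        reports.append(report(verdict, in_phase=in_phase, frac=frac))
    return reports
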