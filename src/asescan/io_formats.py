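"""Readers and writers for every on-disk format the pipeline touches.

All interval-like inputs (BED, 1-based inclusive TSV, GFF3 gene models) are
normalised to the internal 0-based half-open convention on read and converted
back on write; variant positions stay 1-based as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    AlleleCountRecord,
    GenomicInterval,
    MethylationRecord,
    PhasedGenotypeMatrix,
    Variant,
)

logger = logging.getLogger(__name__)

COUNTS_COLUMNS = ["sample", "variant", "ref_count", "alt_count"]
METHYLATION_COLUMNS = ["sample", "chrom", "pos", "methylated_count", "unmethylated_count"]


class UnphasedGenotypeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str | Path, require_phased: bool = True) -> PhasedGenotypeMatrix:
    """Load biallelic SNVs from a VCF 4.x into a :class:`PhasedGenotypeMatrix`.

    Multi-allelic and non-SNV records are skipped (counts logged). Missing
    genotypes ("./.") are recorded as missing. With ``require_phased`` an
    unphased non-missing, non-homozygous genotype raises
    :class:`UnphasedGenotypeError` naming the record (homozygous calls carry
    no phase information, so "1/1" is accepted and marked unphased).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[Variant] = []
    hap_rows: list[np.ndarray] = []
    phased_rows: list[np.ndarray] = []
    n_multi = n_nonsnv = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1 or rec.ALT[0] not in "ACGT":
            n_nonsnv += 1
            continue
        gts = np.array(rec.genotypes, dtype=object)  # rows of [a, b, phased]
        a = np.array([g[0] for g in gts], dtype=np.int8)
        b = np.array([g[1] for g in gts], dtype=np.int8)
        ph = np.array([bool(g[2]) for g in gts])
        miss = (a < 0) | (b < 0)
        a[miss] = MISSING
        b[miss] = MISSING
        ph[miss] = False
        hom = (~miss) & (a == b)
        if require_phased:
            bad = (~miss) & (~hom) & (~ph)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise UnphasedGenotypeError(
                    f"unphased heterozygous genotype at {rec.CHROM}:{rec.POS} "
                    f"({rec.ID or '.'}) sample {samples[i]}"
                )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(Variant(vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        hap_rows.append(np.stack([a, b], axis=1))
        phased_rows.append(ph)
    vcf.close()
    if n_multi or n_nonsnv:
        logger.warning(
            "skipped %d multi-allelic and %d non-SNV records in %s",
            n_multi, n_nonsnv, path,
        )
    if variants:
        haps = np.stack(hap_rows, axis=1)  # (n_samples, n_variants, 2)
        phased = np.stack(phased_rows, axis=1)
    else:
        haps = np.empty((len(samples), 0, 2), dtype=np.int8)
        phased = np.empty((len(samples), 0), dtype=bool)
    return PhasedGenotypeMatrix(samples, variants, haps, phased)


# ---------------------------------------------------------------------------
# allele count tables
# ---------------------------------------------------------------------------

def read_counts_table(
    path: str | Path, known_variants: set[str] | None = None
) -> list[AlleleCountRecord]:
    """Read a TSV with header sample/variant/ref_count/alt_count.

    Duplicate (sample, variant) keys and negative counts are errors; if
    ``known_variants`` is given, unknown variant ids are an error listing the
    offenders.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "variant": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing_cols = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"counts table {path} missing columns: {missing_cols}")
    dup = df.duplicated(subset=["sample", "variant"])
    if dup.any():
        keys = df.loc[dup, ["sample", "variant"]].itertuples(index=False)
        raise ValueError(
            "duplicate (sample, variant) keys: "
            + ", ".join(f"({s}, {v})" for s, v in keys)
        )
    if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
        raise ValueError(f"negative read counts in {path}")
    if known_variants is not None:
        unknown = sorted(set(df["variant"]) - known_variants)
        if unknown:
            raise ValueError(f"unknown variant ids in {path}: {unknown}")
    return [
        AlleleCountRecord(r.sample, r.variant, int(r.ref_count), int(r.alt_count))
        for r in df.itertuples(index=False)
    ]


def write_counts_table(records: list[AlleleCountRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.sample, r.variant, r.ref_count, r.alt_count) for r in records],
        columns=COUNTS_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path, one_based: bool = False) -> list[GenomicInterval]:
    """Read intervals from BED (0-based half-open) or, with ``one_based``,
    from a 1-based inclusive TSV; normalised to internal half-open."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, a, b = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            start, end = (a - 1, b) if one_based else (a, b)
            if start >= end:
                raise ValueError(f"empty or inverted interval in {path}: {line!r}")
            out.append(GenomicInterval(chrom, start, end, label))
    return out


def write_intervals(
    intervals: list[GenomicInterval], path: str | Path, one_based: bool = False
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            a, b = (iv.start + 1, iv.end) if one_based else (iv.start, iv.end)
            fh.write(f"{iv.chrom}\t{a}\t{b}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# methylation tables
# ---------------------------------------------------------------------------

def read_methylation_table(path: str | Path) -> list[MethylationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing_cols = [c for c in METHYLATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"methylation table {path} missing columns: {missing_cols}")
    return [
        MethylationRecord(
            r.sample, r.chrom, int(r.pos), int(r.methylated_count), int(r.unmethylated_count)
        )
        for r in df.itertuples(index=False)
    ]


def write_methylation_table(records: list[MethylationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.sample, r.chrom, r.pos, r.methylated_count, r.unmethylated_count)
            for r in records
        ],
        columns=METHYLATION_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model for TSS distance and feature classification.

    Coordinates are internal 0-based half-open; ``exons`` etc. are sorted
    (start, end) tuples. ``coding`` distinguishes protein-coding genes from
    non-coding transcripts.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    five_prime_utrs: tuple[tuple[int, int], ...] = ()
    three_prime_utrs: tuple[tuple[int, int], ...] = ()
    coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span")

    @property
    def tss(self) -> int:
        """1-based transcription start site: leftmost base for + strand
        genes, rightmost for - strand."""
        return self.start + 1 if self.strand == "+" else self.end


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene/exon/UTR features from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons, utr5, utr3 = [], [], []
        coding = False
        for child in db.children(gene.id):
            span = (child.start - 1, child.end)  # GFF3 is 1-based inclusive
            if child.featuretype == "exon":
                exons.append(span)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(span)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(span)
            elif child.featuretype in ("CDS", "mRNA"):
                coding = True
        biotype = gene.attributes.get("biotype", ["protein_coding"])[0]
        if biotype != "protein_coding":
            coding = False
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                exons=tuple(sorted(exons)),
                five_prime_utrs=tuple(sorted(utr5)),
                three_prime_utrs=tuple(sorted(utr3)),
                coding=coding,
            )
        )
    return models


# ---------------------------------------------------------------------------
# chromosome sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
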