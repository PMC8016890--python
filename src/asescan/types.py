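"""Core in-memory containers shared across the pipeline.

Coordinate conventions
----------------------
Variant and methylation positions are stored 1-based, as in VCF.
Intervals (QTL regions, gene models) are stored 0-based half-open
internally; converters live in :mod:`asescan.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1  # missing haplotype allele code

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV. ``pos`` is 1-based as in VCF."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"variant {self.id}: only single-base SNV alleles supported")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"variant {self.id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class AlleleCountRecord:
    """RNA-seq read counts supporting each allele of one sample at one variant.

    Only meaningful for samples heterozygous at the variant; counts are keyed
    to the ref/alt alleles, phase is carried by the genotype matrix.
    """

    sample: str
    variant: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError(
                f"negative read count for ({self.sample}, {self.variant})"
            )

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class GenomicInterval:
    """Trait-labelled region, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def contains_pos(self, pos: int) -> bool:
        """Whether a 1-based point position falls inside this interval."""
        return self.start < pos <= self.end


@dataclass(frozen=True)
class MethylationRecord:
    """Per-sample, per-cytosine bisulfite counts (RRBS output). 1-based pos."""

    sample: str
    chrom: str
    pos: int
    methylated_count: int
    unmethylated_count: int

    def __post_init__(self) -> None:
        if self.methylated_count + self.unmethylated_count < 1:
            raise ValueError(
                f"methylation record ({self.sample}, {self.chrom}:{self.pos}): "
                "total count must be >= 1"
            )


class PhasedGenotypeMatrix:
    """Samples x variants matrix of ordered haplotype allele pairs.

    ``haps`` has shape (n_samples, n_variants, 2) with entries in
    {0, 1, MISSING}; ``phased`` flags whether the within-cell order is
    meaningful. Genotype-based grouping uses the unordered pair, so it is
    valid on unphased cells too; phase-aware operations (methylation
    cross-checks, synthetic truth) require ``phased``.
    """

    def __init__(
        self,
        samples: list[str],
        variants: list[Variant],
        haps: np.ndarray,
        phased: np.ndarray | None = None,
    ) -> None:
        haps = np.asarray(haps, dtype=np.int8)
        if haps.shape != (len(samples), len(variants), 2):
            raise ValueError(
                f"haps shape {haps.shape} inconsistent with "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        if phased is None:
            phased = np.ones((len(samples), len(variants)), dtype=bool)
        phased = np.asarray(phased, dtype=bool)
        if phased.shape != (len(samples), len(variants)):
            raise ValueError("phased flag array shape mismatch")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids")
        self.samples = list(samples)
        self.variants = list(variants)
        self.haps = haps
        self.phased = phased
        self._vidx = {v.id: j for j, v in enumerate(variants)}
        self._sidx = {s: i for i, s in enumerate(samples)}

    # -- indexing ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        return self._vidx[variant_id]

    def sample_index(self, sample_id: str) -> int:
        return self._sidx[sample_id]

    def variant(self, variant_id: str) -> Variant:
        return self.variants[self._vidx[variant_id]]

    # -- per-variant summaries -------------------------------------------
    def genotype_sums(self, j: int) -> np.ndarray:
        """Alt-allele dosage per sample at variant column j; MISSING if any
        haplotype allele is missing."""
        col = self.haps[:, j, :]
        miss = (col == MISSING).any(axis=1)
        out = col.sum(axis=1).astype(np.int16)
        out[miss] = MISSING
        return out

    def het_mask(self, j: int) -> np.ndarray:
        col = self.haps[:, j, :]
        ok = (col != MISSING).all(axis=1)
        return ok & (col[:, 0] != col[:, 1])

    def alt_frequency(self, j: int) -> float:
        col = self.haps[:, j, :]
        obs = col[col != MISSING]
        if obs.size == 0:
            return float("nan")
        return float(obs.mean())

    def ref_frequency(self, j: int) -> float:
        return 1.0 - self.alt_frequency(j)

    def maf(self, j: int) -> float:
        p = self.alt_frequency(j)
        return min(p, 1.0 - p)

    def variant_call_rate(self, j: int) -> float:
        col = self.haps[:, j, :]
        called = (col != MISSING).all(axis=1)
        return float(called.mean())

    def sample_call_rate(self, i: int) -> float:
        row = self.haps[i, :, :]
        called = (row != MISSING).all(axis=1)
        return float(called.mean())

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_hom_ref, n_het, n_hom_alt) over non-missing samples."""
        g = self.genotype_sums(j)
        g = g[g != MISSING]
        return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())

    # -- subsetting -------------------------------------------------------
    def subset(
        self,
        sample_ids: list[str] | None = None,
        variant_ids: list[str] | None = None,
    ) -> "PhasedGenotypeMatrix":
        rows = (
            np.arange(self.n_samples)
            if sample_ids is None
            else np.array([self._sidx[s] for s in sample_ids])
        )
        cols = (
            np.arange(self.n_variants)
            if variant_ids is None
            else np.array([self._vidx[v] for v in variant_ids])
        )
        return PhasedGenotypeMatrix(
            [self.samples[i] for i in rows],
            [self.variants[j] for j in cols],
            self.haps[np.ix_(rows, cols)],
            self.phased[np.ix_(rows, cols)],
        )
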