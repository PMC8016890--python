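"""Synthetic populations with the statistical structure the scan assumes.

Each simulated gene lives on its own chromosome and carries:

- background SNPs organised in LD blocks: every block draws its sample
  haplotypes from a small ancestral haplotype pool, which creates strong
  within-block D' while leaving blocks mutually independent;
- one transcribed ASE marker SNP, segregating independently of the blocks;
- one causal cis-variant inside one block, within the scan window of the
  marker.

The cis effect is parameterised by ``causal_effect`` (beta): in a sample
heterozygous at the causal variant, the transcript haplotype in phase with
the causal alternative allele is expressed at relative rate (1 - beta), so
the expressed fraction of the marker allele on that haplotype is
(1 - beta) / (2 - beta); causal homozygotes are balanced (r = 0.5). Read
counts at the marker are binomial at that fraction, with negative-binomial
total depth. Methylation records are emitted at the causal position with an
elevated rate on carriers of the (silenced-haplotype) alternative allele,
and trait QTL intervals are planted over a configurable subset of causal
variants. Everything is deterministic under ``rng_seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_formats import (
    write_chrom_sizes,
    write_counts_table,
    write_intervals,
    write_methylation_table,
)
from .types import (
    AlleleCountRecord,
    GenomicInterval,
    MethylationRecord,
    PhasedGenotypeMatrix,
    Variant,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate the study design: 190
    phased animals, a 1 Mb scan window, overdispersed ~30x allelic
    coverage, and 12 animals with bisulfite data."""

    n_samples: int = 190
    n_genes: int = 1
    n_blocks: int = 5
    snps_per_block: int = 12
    block_haplotype_pool_size: int = 8
    causal_effect: float = 0.8  # beta: fraction silenced on the alt-phased haplotype
    causal_maf: float = 0.3
    marker_maf: float = 0.45
    background_maf_range: tuple[float, float] = (0.1, 0.5)
    read_depth_mean: float = 30.0
    read_depth_dispersion: float = 5.0
    window_bp: int = 1_000_000
    snp_spacing_bp: int = 2_000
    methylation_background_rate: float = 0.05
    methylation_silenced_rate: float = 0.8
    methylation_coverage_mean: float = 20.0
    n_methylation_samples: int = 12
    qtl_cover_fraction: float = 0.8
    qtl_width_bp: int = 50_000
    n_background_qtl_per_chrom: int = 2
    chrom_margin_bp: int = 1_000_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.causal_effect <= 1.0:
            raise ValueError("causal_effect (beta) must lie in [0, 1]")
        for name in ("causal_maf", "marker_maf"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.read_depth_mean < 1:
            raise ValueError("read_depth_mean must be >= 1")


@dataclass
class GeneTruth:
    gene: str
    chrom: str
    marker_id: str
    causal_id: str
    causal_block: int
    expressed_ref_fraction: dict[str, float]  # marker-het samples only


@dataclass
class SyntheticTruth:
    genes: list[GeneTruth]
    config: SimulationConfig

    def causal_ids(self) -> list[str]:
        return [g.causal_id for g in self.genes]

    def marker_ids(self) -> list[str]:
        return [g.marker_id for g in self.genes]


@dataclass
class SyntheticDataset:
    matrix: PhasedGenotypeMatrix
    counts: list[AlleleCountRecord]
    truth: SyntheticTruth
    methylation: list[MethylationRecord]
    qtl_intervals: list[GenomicInterval]
    chrom_sizes: dict[str, int]


def expressed_ref_fraction(beta: float, ref_hap_silenced: bool) -> float:
    """Expected reference-allele read fraction for a marker heterozygote
    given which haplotype the causal alternative allele silences."""
    r_silenced = (1.0 - beta) / (2.0 - beta)
    return r_silenced if ref_hap_silenced else 1.0 - r_silenced


def _nb_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    """Negative-binomial depths with the given mean and dispersion k
    (variance mean + mean^2/k), floored at 1."""
    p = dispersion / (dispersion + mean)
    d = rng.negative_binomial(dispersion, p, size=n)
    return np.maximum(d, 1)


def _draw_block_haplotypes(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    causal_slot: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one block: an ancestral pool and two pool picks per sample.

    Returns (alleles, pool_freqs) where alleles has shape (n_samples, 2,
    snps_per_block).
    """
    lo, hi = cfg.background_maf_range
    freqs = rng.uniform(lo, hi, size=cfg.snps_per_block)
    if causal_slot is not None:
        freqs[causal_slot] = cfg.causal_maf
    pool = rng.binomial(1, freqs, size=(cfg.block_haplotype_pool_size, cfg.snps_per_block))
    picks = rng.integers(0, cfg.block_haplotype_pool_size, size=(cfg.n_samples, 2))
    return pool[picks], freqs


def simulate_population(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full dataset: phased genotypes, allele counts at each ASE
    marker, ground truth, methylation records and trait QTL intervals."""
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]

    variants: list[Variant] = []
    hap_cols: list[np.ndarray] = []  # each (n_samples, 2)
    genes: list[GeneTruth] = []
    counts: list[AlleleCountRecord] = []
    methylation: list[MethylationRecord] = []
    qtl_intervals: list[GenomicInterval] = []
    chrom_sizes: dict[str, int] = {}

    for g in range(cfg.n_genes):
        chrom = f"chr{g + 1}"
        causal_block = cfg.n_blocks // 2
        causal_slot = cfg.snps_per_block // 2

        # -- haplotypes: blocks from pools, marker independent ------------
        block_alleles = []
        for b in range(cfg.n_blocks):
            slot = causal_slot if b == causal_block else None
            for attempt in range(20):
                alleles, _ = _draw_block_haplotypes(rng, cfg, slot)
                if slot is None:
                    break
                col = alleles[:, :, slot]
                if 0 < col.sum() < col.size:  # causal polymorphic in sample
                    break
                logger.info("resampling monomorphic causal draw (gene %s)", g)
            block_alleles.append(alleles)
        marker_hap = rng.binomial(1, cfg.marker_maf, size=(cfg.n_samples, 2)).astype(np.int8)

        # -- genome layout: blocks laid out left to right, marker in the
        #    middle of the region so every SNP is inside the scan window --
        n_block_snps = cfg.n_blocks * cfg.snps_per_block
        positions = 10_000 + cfg.snp_spacing_bp * np.arange(n_block_snps + 1)
        marker_order_index = causal_block * cfg.snps_per_block + causal_slot + 1
        chrom_sizes[chrom] = int(positions[-1] + cfg.chrom_margin_bp)

        gene_variant_ids: list[str] = []
        order = 0
        causal_id = marker_id = None
        marker_col = causal_col = None
        for b in range(cfg.n_blocks):
            for s in range(cfg.snps_per_block):
                if order == marker_order_index:
                    marker_id = f"g{g}_ase"
                    ref, alt = "A", "G"
                    variants.append(Variant(marker_id, chrom, int(positions[order]), ref, alt))
                    hap_cols.append(marker_hap)
                    marker_col = marker_hap
                    order += 1
                vid = f"g{g}_b{b}_s{s}"
                col = block_alleles[b][:, :, s].astype(np.int8)
                if b == causal_block and s == causal_slot:
                    causal_id = vid
                    ref, alt = "T", "C"  # alt carries the methylatable cytosine
                    causal_col = col
                else:
                    ref, alt = rng.choice(4, size=2, replace=False), None
                    ref, alt = str(_BASES[ref[0]]), str(_BASES[ref[1]])
                variants.append(Variant(vid, chrom, int(positions[order]), ref, alt))
                hap_cols.append(col)
                gene_variant_ids.append(vid)
                order += 1
        if order == marker_order_index:  # marker lands at the very end
            marker_id = f"g{g}_ase"
            variants.append(Variant(marker_id, chrom, int(positions[order]), "A", "G"))
            hap_cols.append(marker_hap)
            marker_col = marker_hap

        # -- allele-specific read counts at the marker --------------------
        marker_het = marker_col[:, 0] != marker_col[:, 1]
        causal_het = causal_col[:, 0] != causal_col[:, 1]
        depths = _nb_depths(rng, cfg.n_samples, cfg.read_depth_mean, cfg.read_depth_dispersion)
        fractions: dict[str, float] = {}
        for i in np.flatnonzero(marker_het):
            if causal_het[i]:
                alt_hap = 0 if causal_col[i, 0] == 1 else 1  # hap carrying causal alt
                ref_hap_silenced = marker_col[i, alt_hap] == 0
                r = expressed_ref_fraction(cfg.causal_effect, ref_hap_silenced)
            else:
                r = 0.5
            fractions[samples[i]] = r
            depth = int(depths[i])
            ref_count = int(rng.binomial(depth, r))
            counts.append(
                AlleleCountRecord(samples[i], marker_id, ref_count, depth - ref_count)
            )

        # -- methylation at the causal position ---------------------------
        causal_pos = next(v.pos for v in variants if v.id == causal_id)
        for i, sample in enumerate(samples[: cfg.n_methylation_samples]):
            cov = max(1, int(rng.poisson(cfg.methylation_coverage_mean)))
            n_alt = int((causal_col[i] == 1).sum())
            rate = {
                0: cfg.methylation_background_rate,
                1: (cfg.methylation_background_rate + cfg.methylation_silenced_rate) / 2,
                2: cfg.methylation_silenced_rate,
            }[n_alt]
            m = int(rng.binomial(cov, rate))
            methylation.append(
                MethylationRecord(sample, chrom, causal_pos, m, cov - m)
            )

        # -- trait QTL intervals -------------------------------------------
        covered = rng.random() < cfg.qtl_cover_fraction if cfg.n_genes > 1 else True
        if cfg.qtl_cover_fraction <= 0:
            covered = False
        if covered:
            half = cfg.qtl_width_bp // 2
            start = max(0, causal_pos - 1 - half)
            qtl_intervals.append(
                GenomicInterval(chrom, start, causal_pos + half, f"trait_g{g}")
            )
        for k in range(cfg.n_background_qtl_per_chrom):
            start = int(rng.integers(0, chrom_sizes[chrom] - cfg.qtl_width_bp))
            qtl_intervals.append(
                GenomicInterval(chrom, start, start + cfg.qtl_width_bp, f"background_{chrom}_{k}")
            )

        genes.append(
            GeneTruth(
                gene=f"gene{g}",
                chrom=chrom,
                marker_id=marker_id,
                causal_id=causal_id,
                causal_block=causal_block,
                expressed_ref_fraction=fractions,
            )
        )

    haps = np.stack(hap_cols, axis=1)  # (n_samples, n_variants, 2)
    matrix = PhasedGenotypeMatrix(samples, variants, haps)
    truth = SyntheticTruth(genes=genes, config=cfg)
    return SyntheticDataset(matrix, counts, truth, methylation, qtl_intervals, chrom_sizes)


# ---------------------------------------------------------------------------
# on-disk output
# ---------------------------------------------------------------------------

def write_phased_vcf(matrix: PhasedGenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal phased VCF 4.2 (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j, v in enumerate(matrix.variants):
            gts = []
            for i in range(matrix.n_samples):
                a, b = matrix.haps[i, j]
                if a < 0 or b < 0:
                    gts.append(".|." if matrix.phased[i, j] else "./.")
                else:
                    sep = "|" if matrix.phased[i, j] else "/"
                    gts.append(f"{a}{sep}{b}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                "\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_flank_fasta(
    dataset: SyntheticDataset, path: str | Path, w: int = 25, seed: int = 0
) -> None:
    """Write per-chromosome sequences covering every variant +/- w bases
    (coordinates preserved by naming contigs with their offset is avoided:
    whole chromosomes up to the last variant + w are emitted, with random
    bases everywhere except variant positions, which carry the ref allele)."""
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[Variant]] = {}
    for v in dataset.matrix.variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    with open(path, "w") as fh:
        for chrom, vs in by_chrom.items():
            length = max(v.pos for v in vs) + w
            seq = _BASES[rng.integers(0, 4, size=length)]
            for v in vs:
                seq[v.pos - 1] = v.ref_allele
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for k in range(0, length, 60):
                fh.write(s[k:k + 60] + "\n")


def write_dataset(dataset: SyntheticDataset, outdir: str | Path, flank_w: int = 25) -> dict[str, Path]:
    """Write every on-disk artifact of a synthetic dataset; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "counts": outdir / "allele_counts.tsv",
        "methylation": outdir / "methylation.tsv",
        "qtl": outdir / "qtl_regions.bed",
        "chrom_sizes": outdir / "chrom.sizes",
        "truth": outdir / "truth.json",
        "fasta": outdir / "genome.fa",
    }
    write_phased_vcf(dataset.matrix, paths["vcf"])
    write_counts_table(dataset.counts, paths["counts"])
    write_methylation_table(dataset.methylation, paths["methylation"])
    write_intervals(dataset.qtl_intervals, paths["qtl"])
    write_chrom_sizes(dataset.chrom_sizes, paths["chrom_sizes"])
    truth_doc = {
        "config": asdict(dataset.truth.config),
        "genes": [
            {
                "gene": t.gene,
                "chrom": t.chrom,
                "marker_id": t.marker_id,
                "causal_id": t.causal_id,
                "causal_block": t.causal_block,
                "expressed_ref_fraction": t.expressed_ref_fraction,
            }
            for t in dataset.truth.genes
        ],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=1)
    write_flank_fasta(dataset, paths["fasta"], w=flank_w, seed=dataset.truth.config.rng_seed)
    return paths
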