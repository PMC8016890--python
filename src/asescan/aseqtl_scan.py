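"""Genotype-stratified scan for cis-regulatory variants behind ASE.

For every SNP marking allelic imbalance, every other SNP within a +/- 1 Mb
window is a candidate regulator. The logic exploits a simple consequence of
cis action: a regulatory allele silences only the transcript haplotype it
sits on, so heterozygous carriers of the candidate show imbalance at the
marker while homozygous carriers (either class) do not. Imbalance values of
marker-heterozygous animals, split by candidate genotype, are compared with
a one-sided Wilcoxon rank-sum (Mann-Whitney U) test, heterozygotes against
the larger homozygous class. Raw p <= alpha declares an aseQTL; no
multiple-testing correction is applied by default (a BH column is emitted
for reference), matching the screening character of the procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ase_detection import bh_fdr
from .io_formats import GeneModel
from .types import MISSING, AlleleCountRecord, PhasedGenotypeMatrix, Variant

DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class AseqtlResult:
    ase_variant: str
    candidate_variant: str
    n_het: int
    hom_group_used: str  # "0/0" or "1/1"
    n_hom: int
    statistic: float
    p_value: float
    candidate_ref_allele_frequency: float
    distance_to_ase_snp: int
    distance_to_tss: int | None = None
    significant: bool = False
    q_value: float = float("nan")


@dataclass(frozen=True)
class SkipRecord:
    ase_variant: str
    candidate_variant: str
    reason: str  # min_het_candidate | min_het_ase | min_hom | degenerate


def build_windows(
    ase_snps: list[Variant],
    all_variants: list[Variant],
    half_width: int = DEFAULT_WINDOW_BP,
) -> dict[str, list[str]]:
    """Map each ASE SNP id to candidate variant ids within +/- half_width bp.

    The bound is closed (a candidate exactly 1 Mb away is included), the ASE
    SNP itself is excluded, and an ASE SNP may appear as a candidate for a
    neighbouring ASE SNP.
    """
    by_chrom: dict[str, list[Variant]] = {}
    for v in all_variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    pos_by_chrom = {}
    for chrom, vs in by_chrom.items():
        vs.sort(key=lambda v: v.pos)
        pos_by_chrom[chrom] = np.array([v.pos for v in vs])
    windows: dict[str, list[str]] = {}
    for ase in ase_snps:
        vs = by_chrom.get(ase.chrom, [])
        if not vs:
            windows[ase.id] = []
            continue
        pos = pos_by_chrom[ase.chrom]
        lo = int(np.searchsorted(pos, ase.pos - half_width, side="left"))
        hi = int(np.searchsorted(pos, ase.pos + half_width, side="right"))
        windows[ase.id] = [v.id for v in vs[lo:hi] if v.id != ase.id]
    return windows


def imbalance_ratio(ref_count: int, alt_count: int) -> float:
    """Folded allelic imbalance |ref/(ref+alt) - 0.5| in [0, 0.5].

    0 means balanced expression; 0.5 means monoallelic expression (e.g. an
    animal expressing only the alternative allele: counts (0, 30) -> 0.5).
    """
    total = ref_count + alt_count
    if total == 0:
        raise ValueError("undefined imbalance: zero total depth")
    # algebraically |ref/total - 0.5|; this form rounds identically under
    # ref/alt relabeling, keeping rank ties exact
    return abs(ref_count - alt_count) / (2.0 * total)


def ref_fraction(ref_count: int, alt_count: int) -> float:
    """Unfolded reference-allele read fraction, for phase-aware checks."""
    total = ref_count + alt_count
    if total == 0:
        raise ValueError("undefined fraction: zero total depth")
    return ref_count / total


def group_samples(
    candidate_id: str,
    ase_id: str,
    matrix: PhasedGenotypeMatrix,
    imbalance_by_sample: dict[str, float],
    min_het: int = 10,
    min_hom: int = 3,
) -> tuple[np.ndarray, np.ndarray, str] | SkipRecord:
    """Split marker-heterozygous samples by candidate genotype.

    Only samples heterozygous at the ASE SNP (with a measurable imbalance
    value) enter either group. Heterozygotes at the candidate form the test
    group; the larger homozygous class forms the reference group, ties going
    to 0/0. Returns a :class:`SkipRecord` when group-size floors
    (``min_het`` heterozygotes at both SNPs, ``min_hom`` homozygotes) are
    not met.
    """
    j_c = matrix.variant_index(candidate_id)
    g = matrix.genotype_sums(j_c)
    het_vals, hom0_vals, hom2_vals = [], [], []
    n_ase_het = 0
    for i, sample in enumerate(matrix.samples):
        val = imbalance_by_sample.get(sample)
        if val is None:
            continue
        n_ase_het += 1
        if g[i] == MISSING:
            continue
        if g[i] == 1:
            het_vals.append(val)
        elif g[i] == 0:
            hom0_vals.append(val)
        else:
            hom2_vals.append(val)
    if n_ase_het < min_het:
        return SkipRecord(ase_id, candidate_id, "min_het_ase")
    if len(het_vals) < min_het:
        return SkipRecord(ase_id, candidate_id, "min_het_candidate")
    if len(hom0_vals) >= len(hom2_vals):
        hom_vals, hom_label = hom0_vals, "0/0"
    else:
        hom_vals, hom_label = hom2_vals, "1/1"
    if len(hom_vals) < min_hom:
        return SkipRecord(ase_id, candidate_id, "min_hom")
    return np.asarray(het_vals), np.asarray(hom_vals), hom_label


def wilcoxon_rank_sum(
    het_values: np.ndarray,
    hom_values: np.ndarray,
    alternative: str = "greater",
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test (het imbalance > hom imbalance).

    Uses the exact null distribution when n_het * n_hom <= 400 and there
    are no ties, otherwise the normal approximation with tie and continuity
    corrections. The fully degenerate case (every value identical in both
    groups) returns p = 1 by convention.
    """
    het_values = np.asarray(het_values, dtype=float)
    hom_values = np.asarray(hom_values, dtype=float)
    if het_values.size == 0 or hom_values.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([het_values, hom_values])
    if np.all(combined == combined[0]):
        return het_values.size * hom_values.size / 2.0, 1.0
    has_ties = np.unique(combined).size < combined.size
    small = het_values.size * hom_values.size <= 400
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        het_values, hom_values, alternative=alternative, method=method
    )
    return float(res.statistic), float(res.pvalue)


def compute_imbalance_profiles(
    counts: list[AlleleCountRecord],
    matrix: PhasedGenotypeMatrix,
    min_depth: int = 10,
) -> dict[str, dict[str, float]]:
    """Per ASE SNP: imbalance value for each heterozygous, covered sample."""
    profiles: dict[str, dict[str, float]] = {}
    for rec in counts:
        if rec.depth < min_depth:
            continue
        if rec.variant not in matrix._vidx or rec.sample not in matrix._sidx:
            continue  # counts at variants/samples outside this matrix
        j = matrix.variant_index(rec.variant)
        i = matrix.sample_index(rec.sample)
        if not matrix.het_mask(j)[i]:
            continue
        profiles.setdefault(rec.variant, {})[rec.sample] = imbalance_ratio(
            rec.ref_count, rec.alt_count
        )
    return profiles


def scan(
    ase_snp_ids: list[str],
    matrix: PhasedGenotypeMatrix,
    counts: list[AlleleCountRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
    min_het: int = 10,
    min_hom: int = 3,
    min_depth: int = 10,
    alpha: float = 0.05,
    gene_models: dict[str, GeneModel] | None = None,
) -> tuple[list[AseqtlResult], list[SkipRecord]]:
    """Run the full cis-window scan for every ASE SNP.

    ``gene_models`` optionally maps ASE SNP id -> the ASE gene's model so a
    TSS distance can be attached to each candidate. Significance is at raw
    p <= alpha; a BH-adjusted column is attached for reference only.
    """
    profiles = compute_imbalance_profiles(counts, matrix, min_depth=min_depth)
    ase_variants = [matrix.variant(a) for a in ase_snp_ids]
    windows = build_windows(ase_variants, matrix.variants, half_width=window_bp)
    results: list[AseqtlResult] = []
    skips: list[SkipRecord] = []
    for ase in ase_variants:
        imb = profiles.get(ase.id, {})
        for cand_id in windows[ase.id]:
            grouped = group_samples(
                cand_id, ase.id, matrix, imb, min_het=min_het, min_hom=min_hom
            )
            if isinstance(grouped, SkipRecord):
                skips.append(grouped)
                continue
            het_vals, hom_vals, hom_label = grouped
            u, p = wilcoxon_rank_sum(het_vals, hom_vals)
            cand = matrix.variant(cand_id)
            j_c = matrix.variant_index(cand_id)
            tss_dist = None
            if gene_models and ase.id in gene_models:
                tss_dist = abs(cand.pos - gene_models[ase.id].tss)
            results.append(
                AseqtlResult(
                    ase_variant=ase.id,
                    candidate_variant=cand_id,
                    n_het=het_vals.size,
                    hom_group_used=hom_label,
                    n_hom=hom_vals.size,
                    statistic=u,
                    p_value=p,
                    candidate_ref_allele_frequency=matrix.ref_frequency(j_c),
                    distance_to_ase_snp=abs(cand.pos - ase.pos),
                    distance_to_tss=tss_dist,
                    significant=p <= alpha,
                )
            )
    if results:
        q = bh_fdr([r.p_value for r in results])
        results = [
            AseqtlResult(**{**r.__dict__, "q_value": float(qi)})
            for r, qi in zip(results, q)
        ]
    return results, skips


def results_to_frame(results: list[AseqtlResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def summarize(results: list[AseqtlResult]) -> pd.DataFrame:
    """Per-ASE-SNP summary: number of significant aseQTLs and their mean
    reference-allele frequency."""
    df = results_to_frame(results)
    if df.empty:
        return pd.DataFrame(
            columns=["ase_variant", "n_tested", "n_aseqtl", "mean_ref_freq"]
        )
    sig = df[df["significant"]]
    out = (
        df.groupby("ase_variant")
        .size()
        .rename("n_tested")
        .to_frame()
        .join(sig.groupby("ase_variant").size().rename("n_aseqtl"))
        .join(
            sig.groupby("ase_variant")["candidate_ref_allele_frequency"]
            .mean()
            .rename("mean_ref_freq")
        )
        .reset_index()
    )
    out["n_aseqtl"] = out["n_aseqtl"].fillna(0).astype(int)
    return out
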