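"""Marker and sample quality control for BeadChip-style genotype matrices.

Filters mirror common GWAS practice for this kind of panel: minor allele
frequency, per-sample and per-variant call rate, and a Hardy-Weinberg
equilibrium goodness-of-fit test. Thresholds are strict exactly as stated:
MAF < 0.05 removed, call rate < 0.95 removed, HWE p <= 1e-4 removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import PhasedGenotypeMatrix


@dataclass
class QCReport:
    """Per-variant and per-sample QC metrics with pass/fail reason codes."""

    variant_table: pd.DataFrame
    sample_table: pd.DataFrame
    n_variants_in: int = 0
    n_variants_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0


def compute_maf(variant_id: str, matrix: PhasedGenotypeMatrix) -> float:
    """Minor allele frequency min(p, 1-p) over non-missing allele copies.

    All-missing columns return NaN (the variant then fails QC with reason
    ``undefined``).
    """
    j = matrix.variant_index(variant_id)
    p = matrix.alt_frequency(j)
    if np.isnan(p):
        return float("nan")
    return min(p, 1.0 - p)


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-d.f. chi-square goodness-of-fit p-value against p^2 : 2pq : q^2.

    No continuity correction. Monomorphic counts return p = 1 by convention
    (no heterozygote deficit/excess is definable).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("HWE test needs at least one genotype")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE test: sum of conditional probabilities of heterozygote
    counts no more likely than the observed one, given the allele counts.

    Available as an alternative to the chi-square test; both agree on which
    side of any practical threshold a table falls for all but borderline
    tables.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("HWE test needs at least one genotype")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0
    # P(n_het | allele counts) up to a constant, computed in log space.
    from scipy.special import gammaln

    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_homs = (n_rare - hets) // 2
    common_homs = n - hets - rare_homs
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(rare_homs + 1)
        - gammaln(common_homs + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    return float(probs[probs <= observed * (1 + 1e-12)].sum())


def apply_filters(
    matrix: PhasedGenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 1e-4,
    exact_hwe: bool = False,
) -> tuple[PhasedGenotypeMatrix, QCReport]:
    """Apply sample call-rate filter, then variant MAF/call-rate/HWE filters.

    The sample filter runs first (conventional order), so variant statistics
    are computed on surviving samples only. Raises if no variant survives.
    """
    n_samples_in, n_variants_in = matrix.n_samples, matrix.n_variants

    sample_rates = np.array([matrix.sample_call_rate(i) for i in range(matrix.n_samples)])
    sample_pass = sample_rates >= call_rate_min
    sample_table = pd.DataFrame(
        {
            "sample": matrix.samples,
            "call_rate": sample_rates,
            "passed": sample_pass,
            "reason": np.where(sample_pass, "", "call_rate"),
        }
    )
    kept_samples = [s for s, ok in zip(matrix.samples, sample_pass) if ok]
    if not kept_samples:
        raise ValueError("no samples survive the call-rate filter")
    m = matrix.subset(sample_ids=kept_samples)

    hwe = hwe_exact_test if exact_hwe else hwe_test
    rows = []
    for j, v in enumerate(m.variants):
        p_alt = m.alt_frequency(j)
        maf = float("nan") if np.isnan(p_alt) else min(p_alt, 1.0 - p_alt)
        call_rate = m.variant_call_rate(j)
        if np.isnan(p_alt):
            hwe_p = float("nan")
        else:
            hwe_p = hwe(*m.genotype_counts(j))
        reasons = []
        if np.isnan(maf):
            reasons.append("undefined")
        else:
            if maf < maf_min:
                reasons.append("maf")
            if hwe_p <= hwe_alpha:
                reasons.append("hwe")
        if call_rate < call_rate_min:
            reasons.append("call_rate")
        rows.append((v.id, maf, call_rate, hwe_p, not reasons, ",".join(reasons)))
    variant_table = pd.DataFrame(
        rows, columns=["variant", "maf", "call_rate", "hwe_p", "passed", "reason"]
    )
    kept_variants = variant_table.loc[variant_table["passed"], "variant"].tolist()
    if not kept_variants:
        raise ValueError("no variants survive QC filters")
    filtered = m.subset(variant_ids=kept_variants)
    report = QCReport(
        variant_table=variant_table,
        sample_table=sample_table,
        n_variants_in=n_variants_in,
        n_variants_out=len(kept_variants),
        n_samples_in=n_samples_in,
        n_samples_out=len(kept_samples),
    )
    return filtered, report
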