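"""Per-animal binomial tests of allelic imbalance and SNP-level ASE calls.

A heterozygous animal with balanced expression of its two alleles should
produce reference/alternative RNA-seq read counts that look like a fair
coin. Each (sample, SNP) pair with enough depth is tested with a two-sided
exact binomial test against p = 0.5; Benjamini-Hochberg FDR is applied over
the full set of tests, and a SNP is called ASE when enough of its
heterozygous carriers are individually significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AlleleCountRecord, PhasedGenotypeMatrix


@dataclass(frozen=True)
class AseTestResult:
    sample: str
    variant: str
    ref_count: int
    alt_count: int
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


@dataclass(frozen=True)
class AseSnpCall:
    variant: str
    n_het_samples_tested: int
    n_significant_samples: int
    is_ase: bool


def binomial_ase_test(ref_count: int, alt_count: int) -> float:
    """Two-sided exact binomial p-value for allele counts under p = 0.5.

    Equivalent to summing both tails of Bin(ref+alt, 0.5) beyond the
    observed count; capped at 1 for balanced counts.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    n = ref_count + alt_count
    if n == 0:
        raise ValueError("zero total depth")
    return float(stats.binomtest(ref_count, n, p=0.5).pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ase_tests(
    counts: list[AlleleCountRecord],
    matrix: PhasedGenotypeMatrix | None = None,
    min_depth: int = 10,
    alpha: float = 0.05,
) -> tuple[list[AseTestResult], list[AlleleCountRecord]]:
    """Test every sufficiently covered heterozygous (sample, SNP) pair.

    Records below ``min_depth``, or from samples not heterozygous at the
    variant when a genotype matrix is supplied, are returned untested. FDR
    is applied globally across all tests performed.
    """
    tested: list[AlleleCountRecord] = []
    untested: list[AlleleCountRecord] = []
    for rec in counts:
        if rec.depth < min_depth:
            untested.append(rec)
            continue
        if matrix is not None:
            j = matrix.variant_index(rec.variant)
            i = matrix.sample_index(rec.sample)
            if not matrix.het_mask(j)[i]:
                untested.append(rec)
                continue
        tested.append(rec)
    p = np.array([binomial_ase_test(r.ref_count, r.alt_count) for r in tested])
    q = bh_fdr(p) if p.size else np.empty(0)
    results = [
        AseTestResult(r.sample, r.variant, r.ref_count, r.alt_count,
                      float(pi), float(qi), bool(qi < alpha))
        for r, pi, qi in zip(tested, p, q)
    ]
    return results, untested


def call_ase_snps(
    results: list[AseTestResult],
    alpha: float = 0.05,
    min_significant_samples: int = 1,
) -> list[AseSnpCall]:
    """Aggregate per-animal results into SNP-level ASE calls.

    A variant is ASE when at least ``min_significant_samples`` heterozygous
    animals have q < alpha. Variants never tested are simply absent.
    """
    by_variant: dict[str, list[AseTestResult]] = {}
    for r in results:
        by_variant.setdefault(r.variant, []).append(r)
    calls = []
    for variant, rs in by_variant.items():
        n_sig = sum(r.q_value < alpha for r in rs)
        calls.append(
            AseSnpCall(variant, len(rs), n_sig, n_sig >= min_significant_samples)
        )
    return calls
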