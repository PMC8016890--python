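"""Pairwise D' from phased haplotypes and threshold-based LD block detection.

D' = |D| / D_max is preferred over r^2 here because it is less sensitive to
allele frequency, so complete disequilibrium is visible even for rare
alleles. Block detection is a transparent greedy rule — grow a run of
genomically ordered variants while every within-run pair stays above a D'
threshold — and is NOT the Gabriel confidence-interval method used by
Haploview; block counts from the two algorithms are not comparable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .types import MISSING, PhasedGenotypeMatrix, Variant

LD_MODES = ("aseqtl_vs_ase", "among_aseqtls", "among_ase")


@dataclass(frozen=True)
class LDPair:
    variant_a: str
    variant_b: str
    haplotype_counts: tuple[int, int, int, int]  # (n_AB, n_Ab, n_aB, n_ab); A/B = ref
    D: float
    D_prime: float
    r_squared: float
    defined: bool = True
    reason: str = ""


@dataclass(frozen=True)
class LDBlock:
    variant_ids: tuple[str, ...]
    chrom: str
    min_d_prime: float


def _haplotype_counts(
    matrix: PhasedGenotypeMatrix, j_a: int, j_b: int
) -> tuple[int, int, int, int]:
    """Tabulate two-locus haplotypes, dropping haplotypes with a missing
    allele at either locus (pairwise deletion)."""
    a = matrix.haps[:, j_a, :].ravel()
    b = matrix.haps[:, j_b, :].ravel()
    phased = matrix.phased[:, j_a] & matrix.phased[:, j_b]
    keep = np.repeat(phased, 2) & (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    n_AB = int(((a == 0) & (b == 0)).sum())
    n_Ab = int(((a == 0) & (b == 1)).sum())
    n_aB = int(((a == 1) & (b == 0)).sum())
    n_ab = int(((a == 1) & (b == 1)).sum())
    return n_AB, n_Ab, n_aB, n_ab


def d_prime_from_counts(
    counts: tuple[int, int, int, int]
) -> tuple[float, float, float, bool, str]:
    """(D, D', r^2, defined, reason) from two-locus haplotype counts."""
    n_AB, n_Ab, n_aB, n_ab = counts
    n = n_AB + n_Ab + n_aB + n_ab
    if n == 0:
        return np.nan, np.nan, np.nan, False, "no haplotypes"
    p_A = (n_AB + n_Ab) / n
    p_B = (n_AB + n_aB) / n
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        return np.nan, np.nan, np.nan, False, "monomorphic"
    p_AB = n_AB / n
    D = p_AB - p_A * p_B
    if D > 0:
        d_max = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    else:
        d_max = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    d_prime_val = 0.0 if D == 0 else abs(D) / d_max
    r2 = D * D / (p_A * (1 - p_A) * p_B * (1 - p_B))
    return D, min(d_prime_val, 1.0), r2, True, ""


def d_prime(
    variant_a: str, variant_b: str, matrix: PhasedGenotypeMatrix
) -> LDPair:
    """Compute D' between two phased variants."""
    j_a = matrix.variant_index(variant_a)
    j_b = matrix.variant_index(variant_b)
    counts = _haplotype_counts(matrix, j_a, j_b)
    D, dp, r2, defined, reason = d_prime_from_counts(counts)
    return LDPair(variant_a, variant_b, counts, D, dp, r2, defined, reason)


def pairwise_ld(
    matrix: PhasedGenotypeMatrix,
    mode: str,
    ase_ids: list[str] | None = None,
    aseqtl_ids: list[str] | None = None,
    associations: list[tuple[str, str]] | None = None,
) -> tuple[list[LDPair], dict[str, int]]:
    """Run one of the three LD comparison schemes.

    - ``aseqtl_vs_ase``: the supplied (ase_id, aseqtl_id) association pairs;
    - ``among_aseqtls``: all within-chromosome pairs of aseQTLs;
    - ``among_ase``: all within-chromosome pairs of ASE SNPs.

    Returns the pairs plus a summary counting D' > 0.8 and D' == 1.
    """
    if mode not in LD_MODES:
        raise ValueError(f"mode must be one of {LD_MODES}")
    if mode == "aseqtl_vs_ase":
        if associations is None:
            raise ValueError("aseqtl_vs_ase mode needs association pairs")
        id_pairs = associations
    else:
        ids = aseqtl_ids if mode == "among_aseqtls" else ase_ids
        if ids is None:
            raise ValueError(f"{mode} mode needs a variant id list")
        id_pairs = list(itertools.combinations(ids, 2))
    pairs: list[LDPair] = []
    for a, b in id_pairs:
        if matrix.variant(a).chrom != matrix.variant(b).chrom:
            continue
        pairs.append(d_prime(a, b, matrix))
    defined = [p for p in pairs if p.defined]
    summary = {
        "n_pairs": len(pairs),
        "n_defined": len(defined),
        "n_dprime_gt_0.8": sum(p.D_prime > 0.8 for p in defined),
        "n_dprime_eq_1": sum(np.isclose(p.D_prime, 1.0) for p in defined),
    }
    return pairs, summary


def find_blocks(
    ld_pairs: list[LDPair],
    matrix: PhasedGenotypeMatrix,
    threshold: float = 0.8,
) -> list[LDBlock]:
    """Greedy D'-threshold block detection over genomically ordered variants.

    A window of contiguous variants grows while every pairwise D' inside it
    is >= threshold; maximal runs of size >= 2 are emitted. Pairs absent
    from ``ld_pairs`` or with undefined D' fail the threshold.
    """
    lookup: dict[frozenset, float] = {}
    members: set[str] = set()
    for p in ld_pairs:
        members.update((p.variant_a, p.variant_b))
        if p.defined:
            lookup[frozenset((p.variant_a, p.variant_b))] = p.D_prime
    ordered = sorted(
        (matrix.variant(v) for v in members), key=lambda v: (v.chrom, v.pos)
    )
    blocks: list[LDBlock] = []
    i = 0
    while i < len(ordered):
        run = [ordered[i]]
        k = i + 1
        while k < len(ordered) and ordered[k].chrom == ordered[i].chrom:
            nxt = ordered[k]
            ok = all(
                lookup.get(frozenset((v.id, nxt.id)), -1.0) >= threshold
                for v in run
            )
            if not ok:
                break
            run.append(nxt)
            k += 1
        if len(run) >= 2:
            dmin = min(
                lookup[frozenset((a.id, b.id))]
                for a, b in itertools.combinations(run, 2)
            )
            blocks.append(
                LDBlock(tuple(v.id for v in run), run[0].chrom, dmin)
            )
        i = max(k, i + 1)
    return blocks
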