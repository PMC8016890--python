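"""Allele-specific flank construction and differential binding-site
filtering for TFs and miRNAs.

The heavy prediction machinery (biophysical TF affinity models,
miRNA-target hybridization energies) is consumed from external hit tables;
this module owns the integration logic: building the two allelic 51-bp
flanks, filtering miRNA interactions by minimum free energy, reducing hit
tables to allele-differential interactions, and intersecting with
muscle-expressed factor lists. A simple log-odds PWM scanner is included so
the differential pipeline can be exercised end-to-end without external
software; it is not an affinity model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Variant

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 25
DEFAULT_MFE_THRESHOLD = -18.0

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FlankPair:
    """The two allelic sequences around a variant: ref allele at the center
    of ``ref_sequence``, alt allele at the same offset of ``alt_sequence``."""

    variant: str
    ref_sequence: str
    alt_sequence: str
    center_offset: int
    truncated: bool = False


@dataclass(frozen=True)
class BindingInteraction:
    variant: str
    factor_id: str
    allele: str  # "ref", "alt" or "both"
    score: float = float("nan")  # PWM log-odds or MFE kcal/mol
    source: str = "external_table"


def extract_flanks(variant: Variant, genome_fasta, w: int = DEFAULT_FLANK_BP) -> FlankPair:
    """Build ref- and alt-allele sequences of up to ``2w + 1`` bases around
    a variant from an indexed FASTA (a :class:`pyfaidx.Fasta` or path).

    The genome base at the variant position must equal the VCF ref allele;
    a mismatch is a hard error. Near contig edges the window is truncated
    and flagged.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(genome_fasta)) if isinstance(genome_fasta, (str, Path)) else genome_fasta
    if variant.chrom not in fa:
        raise KeyError(f"contig {variant.chrom} absent from FASTA")
    contig = fa[variant.chrom]
    contig_len = len(contig)
    pos0 = variant.pos - 1
    if not (0 <= pos0 < contig_len):
        raise ValueError(f"variant {variant.id} outside contig {variant.chrom}")
    genome_base = str(contig[pos0]).upper()
    if genome_base != variant.ref_allele.upper():
        raise ValueError(
            f"reference mismatch for {variant.id} at {variant.chrom}:{variant.pos}: "
            f"genome has {genome_base}, VCF says {variant.ref_allele}"
        )
    lo = max(0, pos0 - w)
    hi = min(contig_len, pos0 + w + 1)
    seq = str(contig[lo:hi]).upper()
    center = pos0 - lo
    truncated = (hi - lo) < 2 * w + 1
    alt_seq = seq[:center] + variant.alt_allele.upper() + seq[center + 1:]
    return FlankPair(variant.id, seq, alt_seq, center, truncated)


def mfe_filter(
    interactions: list[BindingInteraction],
    threshold: float = DEFAULT_MFE_THRESHOLD,
) -> list[BindingInteraction]:
    """Keep miRNA interactions with MFE strictly below the threshold
    (an MFE of exactly -18.0 is dropped); missing MFE values are dropped
    with a warning."""
    kept = []
    n_missing = 0
    for it in interactions:
        if np.isnan(it.score):
            n_missing += 1
            continue
        if it.score < threshold:
            kept.append(it)
    if n_missing:
        logger.warning("dropped %d interactions without an MFE value", n_missing)
    return kept


def differential_hits(
    hits_ref: list[BindingInteraction],
    hits_alt: list[BindingInteraction],
) -> list[BindingInteraction]:
    """Reduce per-allele hit tables to allele-differential interactions.

    A (variant, factor) key present for one allele only yields an
    allele-specific interaction; keys present for both alleles are excluded
    from the differential report.
    """
    ref_keys = {(h.variant, h.factor_id): h for h in hits_ref}
    alt_keys = {(h.variant, h.factor_id): h for h in hits_alt}
    out = []
    for key, h in ref_keys.items():
        if key not in alt_keys:
            out.append(BindingInteraction(h.variant, h.factor_id, "ref", h.score, h.source))
    for key, h in alt_keys.items():
        if key not in ref_keys:
            out.append(BindingInteraction(h.variant, h.factor_id, "alt", h.score, h.source))
    return out


def intersect_expressed(
    interactions: list[BindingInteraction],
    expressed_ids: list[str],
) -> tuple[list[BindingInteraction], pd.Series]:
    """Keep interactions whose factor is in the expressed-factor list;
    returns the filtered list and per-factor interaction counts."""
    ids = set(expressed_ids)
    if not ids:
        logger.warning("empty expressed-factor list: nothing retained")
    kept = [it for it in interactions if it.factor_id in ids]
    counts = pd.Series(
        [it.factor_id for it in kept], dtype=object
    ).value_counts()
    return kept, counts


# ---------------------------------------------------------------------------
# PWM scanning (stand-in engine for end-to-end tests)
# ---------------------------------------------------------------------------

def _scores(seq: str, logodds: np.ndarray) -> np.ndarray:
    L = logodds.shape[0]
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq])
    out = np.full(n, -np.inf)
    for start in range(n):
        window = idx[start:start + L]
        if (window < 0).any():
            continue
        out[start] = logodds[np.arange(L), window].sum()
    return out


def pwm_scan(
    flank_pair: FlankPair,
    pwm: np.ndarray,
    background: np.ndarray | None = None,
    score_min: float = 0.0,
    factor_id: str = "PWM",
) -> dict[str, list[tuple[int, str, float]]]:
    """Scan both allelic flanks, both strands, with a log-odds PWM.

    ``pwm`` is an (L, 4) matrix of base probabilities (columns A, C, G, T;
    rows sum to 1); the score at an offset is sum_i log(p_b,i / q_b). Hits
    are offsets scoring >= ``score_min`` on either strand; returned per
    allele as (offset, strand, score) tuples. Zero-probability entries give
    -inf scores, so they simply never match.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("PWM must have shape (L, 4)")
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("PWM rows must sum to 1")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    with np.errstate(divide="ignore"):
        logodds = np.log(pwm) - np.log(background)
    hits: dict[str, list[tuple[int, str, float]]] = {"ref": [], "alt": []}
    for allele, seq in (("ref", flank_pair.ref_sequence), ("alt", flank_pair.alt_sequence)):
        fwd = _scores(seq, logodds)
        rev = _scores(reverse_complement(seq), logodds)
        for off, s in enumerate(fwd):
            if s >= score_min:
                hits[allele].append((off, "+", float(s)))
        n = len(rev)
        for off, s in enumerate(rev):
            if s >= score_min:
                # report in forward coordinates of the original sequence
                hits[allele].append((n - 1 - off, "-", float(s)))
    return hits


def pwm_differential(
    flank_pair: FlankPair,
    pwm: np.ndarray,
    background: np.ndarray | None = None,
    score_min: float = 0.0,
    factor_id: str = "PWM",
) -> list[BindingInteraction]:
    """Differential call from the built-in scanner: which allele(s) carry at
    least one hit for this PWM."""
    hits = pwm_scan(flank_pair, pwm, background, score_min, factor_id)
    has_ref, has_alt = bool(hits["ref"]), bool(hits["alt"])
    if not (has_ref or has_alt):
        return []
    if has_ref and has_alt:
        allele = "both"
        score = max(s for _, _, s in hits["ref"] + hits["alt"])
    elif has_ref:
        allele, score = "ref", max(s for _, _, s in hits["ref"])
    else:
        allele, score = "alt", max(s for _, _, s in hits["alt"])
    return [BindingInteraction(flank_pair.variant, factor_id, allele, score, "builtin_pwm")]


# ---------------------------------------------------------------------------
# external hit tables
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path) -> list[BindingInteraction]:
    """Read an external TSV of binding-site hits with columns
    variant/factor/allele and optionally score or mfe."""
    df = pd.read_csv(path, sep="\t")
    for col in ("variant", "factor", "allele"):
        if col not in df.columns:
            raise ValueError(f"hit table {path} missing column {col}")
    score_col = "mfe" if "mfe" in df.columns else ("score" if "score" in df.columns else None)
    out = []
    for r in df.itertuples(index=False):
        score = float(getattr(r, score_col)) if score_col else float("nan")
        out.append(BindingInteraction(str(r.variant), str(r.factor), str(r.allele), score))
    return out
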