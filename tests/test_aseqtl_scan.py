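import itertools

import numpy as np
import pytest

from asescan import aseqtl_scan
from asescan.aseqtl_scan import (
    SkipRecord,
    build_windows,
    group_samples,
    imbalance_ratio,
    scan,
    wilcoxon_rank_sum,
)
from asescan.synthetic_data import SimulationConfig, simulate_population
from asescan.types import Variant
from conftest import make_matrix


def V(vid, chrom, pos):
    return Variant(vid, chrom, pos, "A", "G")


class TestBuildWindows:
    def test_closed_bound_and_chromosome_restriction(self):
        ase = V("ase", "chr1", 2_000_000)
        candidates = [
            ase,
            V("at_edge", "chr1", 1_000_000),          # exactly 1 Mb away
            V("beyond", "chr1", 3_000_001),           # 1 Mb + 1
            V("other_chrom", "chr2", 2_000_000),
            V("inside", "chr1", 2_500_000),
        ]
        windows = build_windows([ase], candidates)
        assert sorted(windows["ase"]) == ["at_edge", "inside"]

    def test_ase_snp_can_be_candidate_for_neighbour_but_not_itself(self):
        a = V("ase1", "chr1", 1_000_000)
        b = V("ase2", "chr1", 1_500_000)
        windows = build_windows([a, b], [a, b])
        assert windows["ase1"] == ["ase2"]
        assert windows["ase2"] == ["ase1"]


class TestImbalanceRatio:
    def test_monoallelic_alternative_is_half(self):
        assert imbalance_ratio(0, 30) == pytest.approx(0.5)

    def test_balanced_is_zero(self):
        assert imbalance_ratio(15, 15) == pytest.approx(0.0)

    def test_nine_three(self):
        assert imbalance_ratio(9, 3) == pytest.approx(0.25)

    def test_zero_depth_undefined(self):
        with pytest.raises(ValueError):
            imbalance_ratio(0, 0)

    def test_invariant_under_allele_relabeling(self):
        for a, b in [(0, 30), (9, 3), (7, 13)]:
            assert imbalance_ratio(a, b) == pytest.approx(imbalance_ratio(b, a))


def grouping_matrix(n_het_candidate, n_hom0, n_hom2, n_extra_ase_het=0):
    """Matrix with an ASE SNP (v0, all listed samples het) and a candidate
    (v1) with the requested genotype class sizes."""
    rows = []
    for _ in range(n_het_candidate):
        rows.append([(0, 1), (0, 1)])
    for _ in range(n_hom0):
        rows.append([(0, 1), (0, 0)])
    for _ in range(n_hom2):
        rows.append([(0, 1), (1, 1)])
    for _ in range(n_extra_ase_het):
        rows.append([(0, 0), (0, 1)])  # hom at ASE SNP: no imbalance value
    return make_matrix(rows)


def imbalance_for(matrix, values):
    return {matrix.samples[i]: v for i, v in enumerate(values)}


class TestGroupSamples:
    def test_too_few_candidate_heterozygotes_skips(self):
        m = grouping_matrix(9, 20, 5)
        imb = imbalance_for(m, np.linspace(0, 0.5, m.n_samples))
        out = group_samples("v1", "v0", m, imb)
        assert isinstance(out, SkipRecord) and out.reason == "min_het_candidate"

    def test_too_few_ase_heterozygotes_skips(self):
        m = grouping_matrix(5, 3, 1)
        imb = imbalance_for(m, np.linspace(0, 0.5, m.n_samples))
        out = group_samples("v1", "v0", m, imb)
        assert isinstance(out, SkipRecord) and out.reason == "min_het_ase"

    def test_larger_homozygous_group_used(self):
        m = grouping_matrix(12, 30, 12)
        imb = imbalance_for(m, np.linspace(0, 0.5, m.n_samples))
        het, hom, label = group_samples("v1", "v0", m, imb)
        assert label == "0/0"
        assert len(hom) == 30
        m2 = grouping_matrix(12, 12, 30)
        imb2 = imbalance_for(m2, np.linspace(0, 0.5, m2.n_samples))
        _, hom2, label2 = group_samples("v1", "v0", m2, imb2)
        assert label2 == "1/1" and len(hom2) == 30

    def test_tied_homozygous_groups_break_to_ref(self):
        m = grouping_matrix(12, 15, 15)
        imb = imbalance_for(m, np.linspace(0, 0.5, m.n_samples))
        _, _, label = group_samples("v1", "v0", m, imb)
        assert label == "0/0"

    def test_small_homozygous_group_skips(self):
        m = grouping_matrix(12, 2, 2)
        imb = imbalance_for(m, np.linspace(0, 0.5, m.n_samples))
        out = group_samples("v1", "v0", m, imb)
        assert isinstance(out, SkipRecord) and out.reason == "min_hom"

    def test_only_ase_heterozygotes_enter_groups(self):
        m = grouping_matrix(12, 10, 3, n_extra_ase_het=5)
        imb = imbalance_for(
            m, np.linspace(0, 0.5, m.n_samples - 5).tolist() + [None] * 5
        )
        imb = {k: v for k, v in imb.items() if v is not None}
        het, hom, _ = group_samples("v1", "v0", m, imb)
        assert len(het) + len(hom) <= m.n_samples - 5


def enumeration_p(het, hom):
    """Exact one-sided Mann-Whitney p by enumerating all group splits."""
    combined = list(het) + list(hom)
    n = len(het)
    obs_u = sum(1 for h in het for o in hom if h > o) + 0.5 * sum(
        1 for h in het for o in hom if h == o
    )
    us = []
    for idx in itertools.combinations(range(len(combined)), n):
        grp = [combined[i] for i in idx]
        rest = [combined[i] for i in range(len(combined)) if i not in idx]
        us.append(
            sum(1 for h in grp for o in rest if h > o)
            + 0.5 * sum(1 for h in grp for o in rest if h == o)
        )
    return sum(u >= obs_u - 1e-12 for u in us) / len(us)


class TestWilcoxonRankSum:
    def test_fully_separated_groups_of_three(self):
        u, p = wilcoxon_rank_sum([0.40, 0.45, 0.50], [0.05, 0.10, 0.15])
        assert u == 9
        assert p == pytest.approx(1 / 20)

    def test_identical_multisets_give_no_evidence(self):
        _, p = wilcoxon_rank_sum([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        assert p >= 0.5

    def test_reversed_ordering_approaches_one(self):
        _, p = wilcoxon_rank_sum([0.05, 0.10, 0.15], [0.40, 0.45, 0.50])
        assert p == pytest.approx(1.0)

    def test_degenerate_identical_values_p_one(self):
        _, p = wilcoxon_rank_sum([0.2] * 5, [0.2] * 5)
        assert p == 1.0

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for n, m in [(3, 4), (5, 5), (8, 8), (2, 8)]:
            het = rng.permutation(np.linspace(0.01, 0.99, n + m))[:n]
            hom = np.setdiff1d(np.linspace(0.01, 0.99, n + m), het)
            _, p = wilcoxon_rank_sum(het, hom)
            assert p == pytest.approx(enumeration_p(het, hom), abs=1e-9)

    def test_exact_and_asymptotic_branches_agree_without_ties(self):
        # tie-free 8 vs 8: exact enumeration vs the normal approximation
        rng = np.random.default_rng(9)
        vals = rng.permutation(np.arange(16)) / 16.0
        het, hom = vals[:8], vals[8:]
        _, p_exact = wilcoxon_rank_sum(het, hom)
        from scipy import stats

        p_asym = stats.mannwhitneyu(
            het, hom, alternative="greater", method="asymptotic"
        ).pvalue
        assert p_exact == pytest.approx(enumeration_p(het, hom), abs=1e-9)
        assert p_asym == pytest.approx(p_exact, abs=0.02)


class TestScan:
    def test_causal_variant_significant_when_fully_silencing(self, small_dataset=None):
        cfg = SimulationConfig(causal_effect=1.0, rng_seed=1)
        ds = simulate_population(cfg)
        truth = ds.truth.genes[0]
        results, _ = scan([truth.marker_id], ds.matrix, ds.counts)
        by_cand = {r.candidate_variant: r for r in results}
        assert by_cand[truth.causal_id].significant
        assert by_cand[truth.causal_id].p_value < 1e-6

    def test_relabeling_ase_alleles_leaves_pvalues_unchanged(self):
        cfg = SimulationConfig(rng_seed=5)
        ds = simulate_population(cfg)
        truth = ds.truth.genes[0]
        results, _ = scan([truth.marker_id], ds.matrix, ds.counts)
        # swap ref/alt at the ASE SNP: haplotype codes flip and each count
        # record swaps its ref/alt counts
        j = ds.matrix.variant_index(truth.marker_id)
        ds.matrix.haps[:, j, :] = 1 - ds.matrix.haps[:, j, :]
        from asescan.types import AlleleCountRecord

        flipped = [
            AlleleCountRecord(c.sample, c.variant, c.alt_count, c.ref_count)
            if c.variant == truth.marker_id
            else c
            for c in ds.counts
        ]
        results2, _ = scan([truth.marker_id], ds.matrix, flipped)
        p1 = {r.candidate_variant: r.p_value for r in results}
        p2 = {r.candidate_variant: r.p_value for r in results2}
        assert p1.keys() == p2.keys()
        for k in p1:
            assert p1[k] == pytest.approx(p2[k], abs=1e-12)

    def test_no_testable_candidates_yields_empty_results(self):
        # marker het in only a few animals: every pair skips on min_het_ase
        cfg = SimulationConfig(n_samples=30, marker_maf=0.05, rng_seed=2)
        ds = simulate_population(cfg)
        truth = ds.truth.genes[0]
        results, skips = scan([truth.marker_id], ds.matrix, ds.counts)
        assert results == []
        assert len(skips) > 0

    def test_distances_attached(self):
        cfg = SimulationConfig(rng_seed=4)
        ds = simulate_population(cfg)
        truth = ds.truth.genes[0]
        results, _ = scan([truth.marker_id], ds.matrix, ds.counts)
        marker_pos = ds.matrix.variant(truth.marker_id).pos
        for r in results:
            cand_pos = ds.matrix.variant(r.candidate_variant).pos
            assert r.distance_to_ase_snp == abs(cand_pos - marker_pos)
            assert r.distance_to_ase_snp <= 1_000_000

    def test_summary_counts_significant_pairs(self):
        cfg = SimulationConfig(causal_effect=1.0, rng_seed=1)
        ds = simulate_population(cfg)
        truth = ds.truth.genes[0]
        results, _ = scan([truth.marker_id], ds.matrix, ds.counts)
        summary = aseqtl_scan.summarize(results)
        row = summary.set_index("ase_variant").loc[truth.marker_id]
        assert row["n_tested"] == len(results)
        assert row["n_aseqtl"] == sum(r.significant for r in results)
        assert 0.0 <= row["mean_ref_freq"] <= 1.0
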