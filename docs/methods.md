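# Methods

## Model and assumptions

The pipeline targets the canonical cis-regulation signature in a diploid
outbred population. Let an ASE marker SNP sit in a transcript and a
candidate regulatory SNP sit within the same cis window. If the candidate's
alternative allele attenuates expression of its own haplotype by a factor
`beta ∈ [0, 1]`, then in an animal heterozygous at both SNPs the two
transcript haplotypes are expressed at relative rates `(1 − beta) : 1`, so
the marker allele in phase with the regulatory alternative allele is read
at fraction

    r = (1 − beta) / (2 − beta)

(`r = 1/2` at beta = 0, `r = 1/3` at beta = 0.5, `r = 0` at beta = 1). In
candidate homozygotes both haplotypes carry the same regulatory allele and
expression is balanced regardless of beta. This asymmetry — imbalance in
candidate heterozygotes only — is the entire basis of the scan; it assumes
one RNA-seq library per animal (the per-animal imbalance value is a single
ratio, not a mean over repeated measurements), no mapping bias, and
binomially distributed allelic reads (no overdispersion beyond sequencing
depth variation).

## Statistical procedures

**Per-animal ASE test.** Two-sided exact binomial test of the reference
count against Bin(depth, 1/2), depth ≥ `min_depth` (default 10 reads — a
power floor below which the test is uninformative). Benjamini–Hochberg
FDR is applied globally across all animal × SNP tests; a SNP is called ASE
when ≥ `min_significant_samples` (default 1, configurable) heterozygous
animals pass q < 0.05. Per-SNP FDR pooling is available behind the same
interface by subsetting inputs.

**aseQTL scan.** Windows are closed at ±1 Mb around each ASE SNP (a
candidate exactly at the bound is included); the ASE SNP is excluded as its
own candidate but may be a candidate for a neighbouring ASE SNP. Only
marker-heterozygous animals (imbalance measurable) enter the groups; they
are split by candidate genotype into heterozygotes and the larger
homozygous class (ties broken toward 0/0; any fixed rule works since the
choice only matters for exactly tied class sizes). A test requires ≥ 10 heterozygotes at both SNPs and ≥ `min_hom`
(default 3) homozygotes: a homozygous floor is needed for the rank test to
be defined at all, and 3 is the smallest group with a non-trivial rank
distribution. The one-sided Mann–Whitney U test (het > hom) uses the exact
null when `n_het · n_hom ≤ 400` and the data are tie-free, otherwise the
normal approximation with tie and continuity corrections; the fully
degenerate case (all values identical) is reported as p = 1. Significance
is at raw p ≤ 0.05 with **no** multiple-testing correction — deliberate,
since the heterozygote-count requirement already restricts the test set
and the scan feeds downstream prioritisation, not inference; a BH column
is emitted for users who want it.

**LD.** D′ is computed from directly tabulated phased haplotypes (pairwise
deletion of missing alleles; no EM frequency estimation), with
D_max = min(p_A·p_b, p_a·p_B) for D > 0 and min(p_A·p_B, p_a·p_b)
otherwise; r² is emitted alongside. Monomorphic loci are undefined and
flagged. Block detection is a greedy rule — extend a genomically contiguous
run while *every* within-run pair has D′ ≥ 0.8 — chosen for transparency.
It is **not** Haploview's Gabriel confidence-interval method; block counts
are not comparable between the two algorithms.

**Overlap permutation test.** Observed statistic: number of distinct
aseQTL positions inside any trait interval (point/interval pairs are
reported separately, since one position can sit in several traits' QTLs).
Null: each point re-placed uniformly within its own chromosome, preserving
per-chromosome point counts, K = 1000 iterations by default. The add-one
estimator p = (b + 1)/(K + 1) is used, so the smallest attainable p at
K = 1000 is 1/1001 ≈ 0.000999; reported p-values can never be 0. No
assembly-gap masking is applied unless a mask is supplied, and QTL
confidence intervals are not padded.

**Methylation.** Percent methylation is 100·m/(m + u) per cytosine and
sample. The cross-check attributes methylation to an aseQTL allele only
when exactly one allele is a cytosine (otherwise per-haplotype-ambiguous →
uninformative); for each doubly heterozygous, phased, methylated
(≥ 30%) sample it asks whether the ASE-SNP allele in phase with the
methylated aseQTL allele is silenced (expressed fraction ≤ 0.35). The 30%
floor keeps partially methylated sites informative while excluding
background; 0.35 separates silencing from balance halfway between the
monoallelic (0) and balanced (0.5) expectations, with slack for binomial
noise at ~30× depth. The report is descriptive (consistent / inconsistent /
uninformative); no p-value is attached, as the per-variant sample counts
are tiny by design.

**Feature classification.** Priority order splice_region > 5′/3′ UTR >
exonic > intronic > non_coding_transcript > intergenic, with splice regions
defined as within 3 bp (exonic side) or 8 bp (intronic side) of an
exon/intron junction. This is a minimal transparent stand-in for a full
consequence predictor: it does not translate codons, so exonic variants
are not split into synonymous/missense.

**Binding-site screen.** Allelic flank pairs are 2w + 1 bases (w = 25,
i.e. 51-mers) with the variant at the center, truncated and flagged at
contig edges; the genome base must match the VCF reference allele. External
TF/miRNA hit tables are reduced to allele-differential interactions
(factor hits one allele's flank only), miRNA interactions require
MFE strictly < −18.0 kcal/mol, and factors are intersected with
muscle-expressed lists. The built-in PWM log-odds scanner (both strands,
score = Σ log(p_b,i/q_b)) exists so the differential logic is testable
end-to-end; it is a motif matcher, not a binding-affinity model.

**Genotype QC.** Sample call-rate filter first, then per-variant MAF,
call-rate and HWE filters, recomputed on surviving samples. Thresholds are
strict as printed: MAF < 0.05 removed, call rate < 0.95 removed, HWE
p ≤ 1e-4 removed. The HWE test is the 1-d.f. chi-square goodness-of-fit
(no continuity correction), the PLINK-era default; an exact conditional
test is available (`exact_hwe=True`) and agrees with the chi-square
classification on all but borderline tables.

## Synthetic data generator

The generator emulates the study conditions: 190 phased diploid animals,
a cis window of 1 Mb, overdispersed ~30× allelic read depth, and 12 animals
with bisulfite data. Per gene (one chromosome each):

- **LD structure**: 5 blocks × 12 SNPs, each block drawing sample
  haplotypes from its own 8-haplotype ancestral pool (within-block D′ high,
  between-block independence — free recombination between blocks). SNP
  spacing 2 kb, background allele frequencies uniform on (0.1, 0.5).
- **Causal variant**: the middle SNP of the middle block, pool frequency
  0.3 (resampled with a logged retry if the sample draw is monomorphic);
  its alleles are T/C so the alternative allele carries the methylatable
  cytosine.
- **ASE marker**: an independent SNP adjacent to the causal block,
  alternative-allele frequency 0.45 — high heterozygosity so the ≥10-het
  requirement is comfortably met at n = 190.
- **Reads**: depth ~ NegativeBinomial(mean 30, dispersion 5, floor 1) —
  overdispersed RNA-seq coverage; reference count ~ Bin(depth, r) with r
  from the phase-aware formula above. Counts are emitted for
  marker-heterozygous animals only.
- **Methylation**: at the causal position for the first 12 animals,
  coverage ~ Poisson(20), methylation rate 5% (no alternative allele), 80%
  (homozygous alternative) or their average (heterozygous) — a bulk-reads
  view of methylation riding on the silenced haplotype.
- **QTL intervals**: a 50 kb interval planted over the causal variant with
  probability 0.8 per gene, plus 2 background intervals per chromosome;
  chromosomes extend 1 Mb past the last SNP so planted intervals are far
  from covering the null space.

Everything is deterministic under `rng_seed`. What the generator does
*not* model: mapping bias toward the reference allele, beta-binomial
overdispersion of allelic counts, relatedness/population structure,
coalescent-realistic LD decay, and read-level artifacts. Passing tests
therefore validate the inference machinery under its own assumptions, not
robustness to those real-data complications.

## Problem sizes used in validation

The statistical test-suite scenarios were sized to give stable Monte Carlo
estimates while keeping the suite quick: type-I calibration uses 40
null genes (~2,400 valid tests) at n = 190; causal-variant recovery uses
200 single-gene replicates at beta = 1, causal MAF 0.3, depth 30; the
planted-overlap check uses 100 replicates of 8 genes at K = 1000
permutations. Oracle-equivalence checks enumerate the binomial test to
depth 30, the Wilcoxon null for all group sizes up to 8 × 8, D′ on 500
random matrices and BH on 1,000 random vectors.

## Known limitations

- The aseQTL scan conditions on heterozygosity at the marker *and*
  candidate exactly as described; other intersection rules (e.g. requiring
  phased double heterozygotes) would change group sizes slightly.
- The greedy LD-block rule and the splice-region window are documented
  stand-ins, not re-implementations of Haploview or VEP.
- The permutation p-value floor of 1/(K + 1) means very strong enrichment
  saturates at ≈ 0.001 for K = 1000; raise K for finer resolution.
- Methylation is attributed to a variant only at exact positional identity
  (a ± window option exists, default 0), and allele assignment needs an
  allele-unique cytosine.
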