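# Methods

## The interaction model

All association machinery rests on one regression.  For a SNP pair (A, B)
with per-sample dosages a, b ∈ {0, 1, 2} of each SNP's A1 allele and binary
disease status Y,

    logit P(Y = 1) = b0 + b1·a + b2·b + b3·a·b .

b3 is the departure of the joint log-odds from additivity of the two
single-locus log-odds — the allelic-by-allelic interaction.  The model is
fitted by Newton/IRLS maximum likelihood and b3 is tested with the 1-df
Wald chi-square (b3/se)².  The model deliberately carries no covariates
and no genotypic (8-df) terms; dosage enters linearly on the logit scale,
so a pair interacts only through the product term.

Assumptions worth keeping in mind: samples are unrelated and exchangeable
(no population-structure adjustment is provided — structure checks such as
PCA or IBS/IBD pruning are out of scope); missingness is handled
pairwise-complete per tested pair, which is unbiased under missingness at
random with respect to phenotype given the pair; and the Wald test relies
on large-sample normality of the MLE, which at a few hundred samples is
slightly conservative for low-MAF pairs (measured below).

### Allele orientation

Dosage counts the minor allele as determined in controls at load time
(frequency ties break to the lexicographically smaller base).  This makes
b3 and the odds-ratio grids interpretable against a major-allele-homozygote
baseline, and makes the orientation reproducible across files.  When two
cohorts are combined or a replication panel is tested, allele coding is
harmonised to the discovery map: swapped A1/A2 flips dosage d → 2−d,
strand flips resolvable by base complement are relabelled, and
strand-ambiguous (A/T, C/G) markers with discordant allele sets are
dropped with a warning rather than guessed — a silent strand error would
flip the sign of b3.

### Numerical choices

* IRLS: at most 25 Newton iterations, convergence when max |Δcoef| < 1e-8.
* Rank deficiency (a constant SNP, or a product column in the span of the
  others) is detected up front from the smallest eigenvalue of XᵀX
  (relative cut 1e-9) → status `collinear`.
* Quasi-separation is flagged when any |coef| exceeds 15 on the logit
  scale (odds ratios beyond e¹⁵ are never estimable from these designs)
  → status `insufficient_data`, as are fits with fewer than 4 usable
  samples or a missing phenotype class.  Failed fits report their status;
  numeric fields are never fabricated.
* Pairs are fitted in vectorised batches (2,048 designs per solve); the
  scalar `interaction_test` runs the same code path with batch size 1, so
  scan results and single calls agree exactly.

## Quality control

Sample call-rate filtering (< 99% removed) runs before marker filtering,
so marker statistics reflect retained samples.  Markers are then removed
when missing rate > 3%, MAF < 0.1 (computed on all retained samples,
missing genotypes excluded from the denominator), or the exact
Hardy-Weinberg p in controls < 5e-5.  HWE uses the exact Levene–Haldane
test — the conditional distribution of the heterozygote count given allele
counts — evaluated by the standard stable multiplicative recurrence; at a
threshold as extreme as 5e-5 the chi-square approximation is
anti-conservative for rare alleles, which would over-remove markers.
Results are cached per genotype-count triple, so genome-scale panels cost
only as many evaluations as there are distinct triples.

## Two-stage design

The scan partitions markers into chromosome sets (24 for a standard human
autosome+X panel) and tests within-set and between-set pairs, each
unordered pair exactly once.  Because an unfiltered genome-scale scan
would emit ~n²/2 rows, only results with P below a reporting threshold
(default 1e-4) are streamed, plus every non-ok status.  The top 10,000
pairs by discovery P are re-tested in the independent cohort (pairs whose
SNPs are absent from the replication panel are reported untestable, not
errors), and in the pooled sample on the intersection panel.  A pair is
selected when stage-2 P < 0.01, combined P < 5e-7, and all three
permutation p-values < 0.01.

### Permutation p-values

Phenotype labels are permuted at the dataset level — one shared stream of
m permuted label vectors for all pairs, from a counter-based (Philox)
generator so runs are reproducible from a single seed.  For each
permutation the interaction p is recomputed and

    p_perm = (b + 1) / (m + 1),

where b counts permutations with pseudo-p ≤ observed p (ties count as
extreme; non-ok pseudo-fits count as non-extreme).  Pseudo-results are
compared on p rather than the raw statistic: per-permutation missingness
can change n_used, and p is the scale on which the observed result is
reported.  An arithmetic consequence worth noting: the attainable minimum
is 1/(m+1), so the strict cutoff p_perm < 0.01 requires m ≥ 100; the
default m = 10,000 gives a floor of 1.0e-4, and scaled-down runs in the
tests use m = 399 (floor 2.5e-3) rather than m = 99, whose floor 0.01 can
never pass.

## Clustering into regions

Interacting pairs concentrate in region-by-region blocks, so passing
pairs are grouped: after orienting each pair so its lower (chromosome,
position) endpoint comes first, two pairs link when both A-endpoints are
within a window (default 100 kb) on the same chromosome and likewise both
B-endpoints; clusters are connected components of that relation.  The
dual-endpoint window rule with a distance default matching the regional
plots' span is a design choice — linkage through LD rather than distance
would be a reasonable alternative and is left as future work.  Each
cluster reports its best pair (smallest combined p), region bounds, and
the member count ("suggestive interaction number").  Nearest-gene
annotation takes a user-supplied BED/GFF3 file (1-based inclusive
internally); no genome build is bundled.

## Haplotype and LD analysis

Haplotype frequencies over 2–8 loci are estimated from unphased genotypes
by EM over the diplotype expansions consistent with each multilocus
genotype; samples missing any of the loci are excluded.  Initialisation is
the product of single-locus allele frequencies plus a deterministic jitter
(1e-6 × rank) — a uniform or exactly-symmetric start is a stationary
saddle for data like a lone double heterozygote.  Iteration stops when the
log-likelihood gain falls below 1e-10 (cap 1,000 iterations); the
likelihood is non-decreasing by construction and the tests assert it.

Pairwise D, D′ = |D|/D_max and r² = D²/(p_A q_A p_B q_B) are derived from
the two-locus EM frequencies (composite genotypic estimators are not
used, matching D′ heatmaps built from EM phasing); callers pass control
samples to mirror the convention of computing LD in controls.

The case-control haplotype test scores each sample's expected haplotype
dosage — the posterior diplotype expectation at the converged frequencies
— against case status, avoiding best-guess phase-call bias.  Haplotypes
below 1% frequency are pooled into one "rare" class, keeping the sample
size fixed; the global test is the quadratic form of the non-rare score
vector with df = (non-rare haplotypes − 1).

## Odds-ratio reporting

The 3×3 genotype-combination grid reports OR and Woolf (log-normal) 95%
intervals for every two-locus genotype cell relative to the
double-homozygote-of-major-alleles baseline, whose OR is 1 by
construction.  Cells touching a zero count are flagged undefined by
default; the Haldane–Anscombe 0.5 correction is opt-in (`--haldane`)
because a silent correction changes estimates invisibly.  Woolf intervals
(rather than profile likelihood) are the declared choice.  Single-locus
association is the same logistic machinery on intercept + dosage.

## The synthetic-data generator

The generator produces the statistical structure the analysis assumes and
nothing more:

* **LD blocks** from founder-haplotype pools: each block of up to 20 SNPs
  carries k founder haplotypes drawn once from the MAF law; each
  individual receives two independent founder haplotypes per block.
  Hardy-Weinberg therefore holds within blocks, blocks are independent,
  and a 2-founder block shows D′ = 1 between its SNPs.  This is a
  parameter-controlled desk-scale device, not a coalescent simulation.
* **MAF spectrum**: uniform(0.1, 0.5) by default — the roughly flat
  spectrum of a genotyping-array panel after a MAF ≥ 0.1 filter.
* **Disease model**: logit P(case) = b0 + Σ (b1·a + b2·b + b3·a·b) over
  planted pairs — exactly the scan's model, so effect recovery is a
  well-posed inverse problem.  Case/control status is filled by
  retrospective quota sampling (draws until both cohort quotas are met,
  with a bounded draw budget), which matches case-control ascertainment
  and gives exact cohort sizes; named presets carry the study-scale
  cohort sizes (277/285 discovery, 181/187 replication).
* **Two-stage structure**: both cohorts share founder pools and planted
  effects; samples are independent; the replication panel drops a seeded
  random fraction of markers, reproducing untestable pairs downstream.
* **Missingness**: independent uniform dropout; **truth files** echo the
  full configuration, realized allele frequencies and realized prevalence
  and are sufficient to re-run an identical simulation.

Not emulated: population stratification, relatedness, batch effects,
sex-chromosome dosage, genotyping-error HWE distortion, and realistic
recombination gradients.  Passing tests therefore demonstrate the
statistical machinery under clean ascertainment, not robustness to
structure or artefacts.

A separate benchmark constructor (`qc_benchmark_panel`) builds a
genome-scale marker panel in which a requested number of markers each
violate exactly one QC rule (rotating missingness so sample call rates
stay above threshold), used to verify QC bookkeeping at the 620,901-marker
scale.

## Verification strategy and measured behaviour

Every statistic is checked against an independent route: the saturated
2×2×2 closed form (b3 = log three-way cross-product ratio, se = √Σ1/n)
and a direct likelihood-maximisation oracle for the interaction test
(agreement to 1e-6); exact-fraction enumeration for HWE (1e-12); a
simplex-search likelihood oracle for EM (frequencies to 1e-4); phased
counts for LD and haplotype scores; brute-force recounts for permutation
b; and transitive-closure/linear-scan oracles for clustering and
nearest-gene.  Scaled-down problem sizes used by the test-suite
simulations — 600-sample null panels of 500 SNPs, 600+600 recovery
cohorts, 200-SNP end-to-end runs, m = 199–399 permutations — were chosen
as the smallest sizes at which each property is sharply testable.

Measured calibration: on no-effect panels (600 samples × 500 SNPs,
MAF uniform(0.1, 0.5), 5 seeds) the scan's type-I error at α = 0.05 is
≈ 0.049.  The small deficit concentrates in low-MAF pairs (min MAF < 0.15
reject at ≈ 0.046; MAF ≥ 0.2 pairs at ≈ 0.050): with n = 600 the
highest product-dosage cells are nearly empty and the Wald test is
finitely conservative there.  This is a property of the Wald statistic
itself — the fitted coefficients match the ML oracle to 1e-6 — and it is
large enough that a Kolmogorov–Smirnov uniformity check over all ~6×10⁵
pooled (and mutually correlated) pair p-values rejects, which the
acceptance suite reports rather than hides.  Users filtering at
genome-wide thresholds are unaffected in practice; users needing exact
small-sample calibration should rely on the permutation p-values, which
are exact by construction.

## Known limitations

* No covariate adjustment; confounding by structure must be handled
  upstream.
* The Wald interaction test is conservative for low-MAF pairs at small n
  (see above); no likelihood-ratio or Firth variant is provided.
* Clustering is distance-based, not LD-based.
* Haplotype analysis is capped at 8 loci (diplotype expansion grows as
  2^(het−1)).
* BED I/O supports the SNP-major variant-mode layout only; VCF and
  dosage-imputation formats are out of scope.
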