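# epipair

Two-stage genome-wide SNP–SNP interaction analysis for case–control
genotype data.

`epipair` is for statistical geneticists who want to run — or study the
statistical behaviour of — an exhaustive two-locus epistasis scan of the
kind used in genome-wide association studies of complex disease: quality
control of PLINK-format genotype panels, an allelic-dosage logistic
regression interaction test over every marker pair, replication of top
pairs in an independent cohort, a pooled combined analysis, phenotype
permutation p-values, clustering of interacting pairs into genomic
regions, EM haplotype/LD analysis, and genotype-combination odds-ratio
reporting.  A synthetic-data module generates two-cohort case–control
panels with LD blocks and planted epistatic effects, so the whole workflow
is testable without any genotype download.

## The statistic

For SNPs A and B with per-sample minor-allele dosages
a, b ∈ {0, 1, 2} and disease status Y, the package fits

    logit P(Y = 1) = b0 + b1·a + b2·b + b3·a·b

by maximum likelihood and tests the interaction with the 1-df Wald
chi-square on b3 (OR_int = exp(b3)).  Samples missing either dosage or the
phenotype are excluded per pair.  The genome-wide scan partitions markers
into chromosome sets, tests every unordered pair exactly once, and streams
results below a reporting threshold (default P < 1e-4).  Downstream, the
two-stage design keeps a pair when it replicates (stage-2 P < 0.01), is
strong in the pooled sample (combined P < 5e-7), and survives permutation
(P_perm = (b+1)/(m+1) < 0.01 in all three datasets, default m = 10,000).

## Worked example

Simulate two cohorts sharing one planted interaction (OR_int = 3 per
allele×allele, both MAF 0.3), then run the full workflow:

```python
import numpy as np
from epipair import (SimulationConfig, PlantedEffect, simulate_two_stage,
                     write_genotypes)
from epipair.pipeline import PipelineConfig, run_pipeline

eff = [PlantedEffect(10, 150, 0.0, 0.0, np.log(3))]
c1 = SimulationConfig(n_cases=300, n_controls=300, n_snps=200, seed=41,
                      planted_effects=eff, effect_maf=0.3, missing_rate=0.005)
c2 = SimulationConfig(n_cases=300, n_controls=300, n_snps=200, seed=42,
                      planted_effects=eff, effect_maf=0.3, missing_rate=0.005)
d1, d2, truth = simulate_two_stage(c1, c2, stage2_overlap=0.95)
write_genotypes(d1, "work/s1", "ped_map")
write_genotypes(d2, "work/s2", "ped_map")

run_pipeline(PipelineConfig(
    in1_prefix="work/s1", in2_prefix="work/s2", out_dir="work/out",
    report_threshold=1e-2, top_k=100, perm_m=399, seed=13))
```

`work/out/candidates.tsv` then contains the planted pair as its passing
row (output of the run above):

```
SNP1  SNP2   P_STAGE1  P_STAGE2  P_COMBINED    P_PERM_S1  P_PERM_S2  P_PERM_COMB  TESTABLE  PASS
rs11  rs151  0.000348  0.000342  4.876785e-07  0.0025     0.0025     0.0025       True      True
```

read as: the pair was detected in the discovery scan (P_STAGE1), replicated
in the independent cohort below the 0.01 cutoff, reached combined
P < 5e-7 in the pooled 1,200-sample analysis, and no permutation in any
dataset beat the observed statistic (floor p = 1/(m+1) = 0.0025 at
m = 399).  `work/out/clusters.tsv` groups passing pairs into interaction
regions with the best pair, region bounds and member count per row.

Single components are available directly (`interaction_test`, `apply_qc`,
`em_haplotypes`, `ld_pair`, `genotype_or_table`, ...), and the same stages
are exposed on the command line:

```sh
epipair simulate --n-cases 300 --n-controls 300 --n-snps 200 --seed 41 \
    --effect 10,150,0,0,1.0986 --out work/s1
epipair qc --in work/s1 --out work/s1c --report work/qc.json
epipair scan --in work/s1c --threshold 1e-4 --out work/scan.tsv
epipair top --in work/scan.tsv -k 10000 --out work/top.tsv
```

## Layout

| module | contents |
| --- | --- |
| `epipair.datatypes` | `GenotypeDataset`, marker records, QC thresholds/report |
| `epipair.io_plink` | PED/MAP and BED/BIM/FAM readers and writers |
| `epipair.qc` | marker statistics, exact (Levene–Haldane) HWE test, QC filter |
| `epipair.scan` | interaction test, chromosome-set pairwise scan, top-K |
| `epipair.staged` | replication, cohort combining, permutation p, filter chain |
| `epipair.clustering` | interaction-region clustering, nearest gene, region table |
| `epipair.ldhap` | EM haplotype frequencies, D′/r², haplotype score tests |
| `epipair.reporting` | 3×3 genotype OR grids, single-locus association |
| `epipair.simulate` | two-cohort synthetic genotypes with planted epistasis |
| `epipair.pipeline` / `epipair.cli` | end-to-end orchestration, `epipair` CLI |

See `docs/methods.md` for the statistical model, the generator's design,
and numerical choices.
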