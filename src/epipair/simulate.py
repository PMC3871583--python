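"""Synthetic two-cohort case-control genotype data with planted epistasis.

The generator emulates the statistical structure the analysis assumes:

* LD blocks built from small founder-haplotype pools (each individual
  receives two independent founder haplotypes per block, so Hardy-Weinberg
  holds within blocks and blocks are independent);
* a MAF spectrum drawn from a uniform law, by default uniform(0.1, 0.5),
  the roughly flat spectrum of a genotyping array panel after a MAF >= 0.1
  quality filter;
* a logistic disease model on allele dosages,
  logit P(case) = b0 + sum(b1*A + b2*B + b3*A*B) over planted pairs, with
  case/control status filled by retrospective quota sampling so cohort
  sizes are exact;
* independent missingness.

Every dataset ships with a :class:`TruthRecord` echoing the planted
effects, realized allele frequencies and realized prevalence, sufficient
to re-run an identical simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.special import expit

from .datatypes import GenotypeDataset, snp_frame

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
_MAX_DRAW_FACTOR = 2000  # bounded quota sampling: draws <= factor * quota


@dataclass
class PlantedEffect:
    """One planted SNP pair with main-effect and interaction log-odds."""

    snp_a_index: int
    snp_b_index: int
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0


@dataclass
class SimulationConfig:
    """Full generative specification of one synthetic cohort."""

    n_cases: int = 277
    n_controls: int = 285
    n_snps: int = 1000
    maf_low: float = 0.10
    maf_high: float = 0.50
    ld_blocks: list[tuple[int, int]] = field(default_factory=lambda: [(1, 0)])
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    intercept_beta0: float = 0.0
    missing_rate: float = 0.0
    effect_maf: Optional[float] = None  # force allele freq at effect SNPs
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.missing_rate < 0.5):
            raise ValueError("missing_rate must be in [0, 0.5)")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        for e in self.planted_effects:
            if not (0 <= e.snp_a_index < self.n_snps
                    and 0 <= e.snp_b_index < self.n_snps):
                raise ValueError("planted effect index out of range")
        for size, _nf in self.ld_blocks:
            if not (1 <= size <= 20):
                raise ValueError("block_size must be in [1, 20]")


#: cohort-size presets matching the two study stages
PRESETS = {
    "stage1": SimulationConfig(n_cases=277, n_controls=285, n_snps=480_365),
    "stage2": SimulationConfig(n_cases=181, n_controls=187, n_snps=620_901),
}


@dataclass
class TruthRecord:
    """Planted-effect ground truth echoed beside every simulated dataset."""

    config: SimulationConfig
    effect_allele_freqs: dict[int, float]
    realized_prevalence: float
    n_draws: int

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = payload["config"]
        cfg["ld_blocks"] = [tuple(b) for b in cfg["ld_blocks"]]
        cfg["planted_effects"] = [PlantedEffect(**e)
                                  for e in cfg["planted_effects"]]
        return cls(
            config=SimulationConfig(**cfg),
            effect_allele_freqs={int(k): v for k, v in
                                 payload["effect_allele_freqs"].items()},
            realized_prevalence=payload["realized_prevalence"],
            n_draws=payload["n_draws"],
        )


class _Population:
    """Founder haplotype pools shared by all individuals of a population."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        m = config.n_snps
        self.freqs = rng.uniform(config.maf_low, config.maf_high, size=m)
        if config.effect_maf is not None:
            for e in config.planted_effects:
                self.freqs[e.snp_a_index] = config.effect_maf
                self.freqs[e.snp_b_index] = config.effect_maf

        # tile the block pattern across the panel
        self.blocks: list[tuple[np.ndarray, Optional[np.ndarray]]] = []
        j = 0
        pat = 0
        while j < m:
            size, n_founders = config.ld_blocks[pat % len(config.ld_blocks)]
            idx = np.arange(j, min(j + size, m))
            founders = None
            if n_founders > 0:
                founders = (rng.random((n_founders, len(idx)))
                            < self.freqs[idx]).astype(np.int8)
            self.blocks.append((idx, founders))
            j += size
            pat += 1

        allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
        self.alleles = [_ALLELE_PAIRS[k] for k in allele_idx]

    def draw_haplotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n haplotypes over the whole panel (rows are gametes)."""
        m = self.config.n_snps
        hap = np.empty((n, m), dtype=np.int8)
        for idx, founders in self.blocks:
            if founders is None:
                hap[:, idx] = (rng.random((n, len(idx)))
                               < self.freqs[idx]).astype(np.int8)
            else:
                pick = rng.integers(0, founders.shape[0], size=n)
                hap[:, idx] = founders[pick, :]
        return hap

    def case_probability(self, dosage: np.ndarray) -> np.ndarray:
        cfg = self.config
        eta = np.full(dosage.shape[0], cfg.intercept_beta0, dtype=float)
        for e in cfg.planted_effects:
            a = dosage[:, e.snp_a_index].astype(float)
            b = dosage[:, e.snp_b_index].astype(float)
            eta += e.beta1 * a + e.beta2 * b + e.beta3 * a * b
        return expit(eta)


def _snp_frame_for(population: _Population, prefix: str = "rs"):
    cfg = population.config
    m = cfg.n_snps
    per_chrom = max(1, -(-m // 22))  # spread markers over 22 autosomes
    records = []
    for j in range(m):
        chrom = str(j // per_chrom + 1)
        pos = (j % per_chrom) * 5000 + 1
        a1, a2 = population.alleles[j]
        records.append((f"{prefix}{j + 1}", chrom, pos, a1, a2))
    return snp_frame(records)


def _sample_cohort(population: _Population, n_cases: int, n_controls: int,
                   rng: np.random.Generator, batch: int = 1024):
    """Retrospective quota sampling from the population's disease model."""
    quota = n_cases + n_controls
    max_draws = _MAX_DRAW_FACTOR * quota
    case_rows, ctrl_rows = [], []
    got_cases = got_ctrls = 0
    draws = 0
    case_draws = 0
    while got_cases < n_cases or got_ctrls < n_controls:
        if draws >= max_draws:
            raise RuntimeError(
                "case/control quotas unattainable within the draw bound; "
                "the disease model makes one class astronomically rare -- "
                "consider raising (or lowering) intercept_beta0")
        h1 = population.draw_haplotypes(batch, rng)
        h2 = population.draw_haplotypes(batch, rng)
        dos = h1 + h2
        pr = population.case_probability(dos)
        is_case = rng.random(batch) < pr
        draws += batch
        case_draws += int(is_case.sum())
        for i in range(batch):
            if is_case[i] and got_cases < n_cases:
                case_rows.append(dos[i])
                got_cases += 1
            elif not is_case[i] and got_ctrls < n_controls:
                ctrl_rows.append(dos[i])
                got_ctrls += 1
    dosage = np.vstack(case_rows + ctrl_rows)
    phenotype = np.array([1] * n_cases + [0] * n_controls, dtype=np.int8)
    prevalence = case_draws / draws
    return dosage, phenotype, prevalence, draws


def simulate_genotypes(config: SimulationConfig, id_prefix: str = "S"
                       ) -> tuple[GenotypeDataset, TruthRecord]:
    """Simulate one case-control cohort; fully reproducible from the seed."""
    rng = np.random.Generator(np.random.Philox(config.seed))
    population = _Population(config, rng)
    dosage, phenotype, prevalence, draws = _sample_cohort(
        population, config.n_cases, config.n_controls, rng)

    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage = np.where(miss, np.int8(-1), dosage)

    n = config.n_cases + config.n_controls
    ds = GenotypeDataset(
        snps=_snp_frame_for(population),
        sample_ids=np.array([f"{id_prefix}{i + 1}" for i in range(n)],
                            dtype=object),
        dosage=dosage.astype(np.int8),
        phenotype=phenotype,
        sex=rng.integers(1, 3, size=n).astype(np.int8),
    )
    truth = TruthRecord(
        config=config,
        effect_allele_freqs={
            int(j): float(population.freqs[j])
            for e in config.planted_effects
            for j in (e.snp_a_index, e.snp_b_index)
        },
        realized_prevalence=float(prevalence),
        n_draws=draws,
    )
    return ds, truth


def simulate_two_stage(config1: SimulationConfig, config2: SimulationConfig,
                       stage2_overlap: float = 1.0,
                       allow_effect_dropout: bool = False
                       ) -> tuple[GenotypeDataset, GenotypeDataset, TruthRecord]:
    """Two independent cohorts from one population, differing marker panels.

    Both cohorts share founder haplotype pools and planted effects (built
    from ``config1``); samples are drawn independently per cohort.  The
    stage-2 panel drops a fraction ``1 - stage2_overlap`` of markers
    uniformly at random (seeded by ``config2.seed``), never removing
    planted-effect SNPs unless ``allow_effect_dropout`` is set.
    """
    if not (0.0 < stage2_overlap <= 1.0):
        raise ValueError("stage2_overlap must be in (0, 1]")
    if config2.n_snps != config1.n_snps:
        raise ValueError("cohorts must share the panel before dropout")

    rng1 = np.random.Generator(np.random.Philox(config1.seed))
    population = _Population(config1, rng1)

    dosage1, ph1, prev1, draws1 = _sample_cohort(
        population, config1.n_cases, config1.n_controls, rng1)
    rng2 = np.random.Generator(np.random.Philox(config2.seed))
    dosage2, ph2, prev2, draws2 = _sample_cohort(
        population, config2.n_cases, config2.n_controls, rng2)

    snps = _snp_frame_for(population)
    m = config1.n_snps
    n_drop = round((1.0 - stage2_overlap) * m)
    protected = {j for e in config1.planted_effects
                 for j in (e.snp_a_index, e.snp_b_index)}
    droppable = (np.arange(m) if allow_effect_dropout else
                 np.array([j for j in range(m) if j not in protected]))
    drop = rng2.choice(droppable, size=min(n_drop, len(droppable)),
                       replace=False)
    keep2 = np.ones(m, dtype=bool)
    keep2[drop] = False

    def finish(dosage, ph, prefix, cfg, rng):
        if cfg.missing_rate > 0:
            miss = rng.random(dosage.shape) < cfg.missing_rate
            dosage = np.where(miss, np.int8(-1), dosage)
        n = cfg.n_cases + cfg.n_controls
        return GenotypeDataset(
            snps=snps.copy(),
            sample_ids=np.array([f"{prefix}{i + 1}" for i in range(n)],
                                dtype=object),
            dosage=dosage.astype(np.int8), phenotype=ph,
            sex=rng.integers(1, 3, size=n).astype(np.int8),
        )

    d1 = finish(dosage1, ph1, "S1_", config1, rng1)
    d2 = finish(dosage2, ph2, "S2_", config2, rng2).subset_markers(keep2)
    truth = TruthRecord(
        config=config1,
        effect_allele_freqs={int(j): float(population.freqs[j])
                             for j in sorted(protected)},
        realized_prevalence=float(prev1),
        n_draws=draws1 + draws2,
    )
    return d1, d2, truth


# ---------------------------------------------------------------------------
# QC benchmark panel
# ---------------------------------------------------------------------------

def qc_benchmark_panel(n_markers: int = 620_901, n_bad: int = 120_113,
                       n_cases: int = 80, n_controls: int = 120,
                       seed: int = 0) -> GenotypeDataset:
    """A marker panel in which exactly ``n_bad`` markers violate a QC rule.

    Clean markers carry Hardy-Weinberg-consistent genotype counts at common
    allele frequencies with no missingness; bad markers violate exactly one
    of the three marker filters (missing rate > 3%, MAF < 0.1, or control
    HWE p < 5e-5), split as evenly as possible across the three rules.
    Missing entries rotate across samples so that no sample's call rate
    drops below 99%.  Built column-pattern-wise so genome-scale panels fit
    in memory.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    n = n_cases + n_controls
    ctrl = np.arange(n_cases, n)

    def hwe_counts(p, size):
        """Integer genotype counts (hom_a1, het, hom_a2) near HWE."""
        h2 = round(size * p * p)
        h1 = round(size * 2 * p * (1 - p))
        return h2, h1, size - h2 - h1

    def pattern_from_counts(p):
        col = np.empty(n, dtype=np.int8)
        for rows in (np.arange(n_cases), ctrl):
            h2, h1, h0 = hwe_counts(p, len(rows))
            vals = np.array([2] * h2 + [1] * h1 + [0] * h0, dtype=np.int8)
            col[rows] = rng.permutation(vals)
        return col

    good_patterns = [pattern_from_counts(p)
                     for p in np.linspace(0.20, 0.45, 24)]

    # rule 1: 7% missing entries, rotating start so call rates stay high
    miss_k = max(int(np.ceil(0.07 * n)), int(0.03 * n) + 1)
    missing_patterns = []
    for start in range(n):
        col = pattern_from_counts(0.35).copy()
        idx = (start + np.arange(miss_k)) % n
        col[idx] = -1
        missing_patterns.append(col)

    # rule 2: MAF 0.05 < 0.10
    maf_patterns = [pattern_from_counts(0.05) for _ in range(8)]

    # rule 3: every control heterozygous (extreme HWE violation)
    hwe_patterns = []
    for _ in range(8):
        col = pattern_from_counts(0.35).copy()
        col[ctrl] = 1
        hwe_patterns.append(col)

    n_miss_bad = n_bad // 3
    n_maf_bad = n_bad // 3
    n_hwe_bad = n_bad - n_miss_bad - n_maf_bad
    n_good = n_markers - n_bad

    groups = [(good_patterns, n_good), (missing_patterns, n_miss_bad),
              (maf_patterns, n_maf_bad), (hwe_patterns, n_hwe_bad)]
    all_patterns = []
    assign = np.empty(n_markers, dtype=np.int32)
    pos = 0
    base = 0
    for patterns, count in groups:
        k = len(patterns)
        assign[pos:pos + count] = base + (np.arange(count) % k)
        all_patterns.extend(patterns)
        base += k
        pos += count
    rng.shuffle(assign)
    dosage = np.stack(all_patterns)[assign].T  # (n, n_markers)

    snps = snp_frame([
        (f"m{j + 1}", str(j % 22 + 1), j + 1, "A", "G")
        for j in range(n_markers)
    ])
    return GenotypeDataset(
        snps=snps,
        sample_ids=np.array([f"S{i + 1}" for i in range(n)], dtype=object),
        dosage=dosage,
        phenotype=np.array([1] * n_cases + [0] * n_controls, dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# recovery study
# ---------------------------------------------------------------------------

@dataclass
class RecoverySummary:
    n_replicates: int
    mean_beta3_hat: float
    mean_bias: float
    ci_coverage: float
    selection_power: float


def recovery_study(config: SimulationConfig, n_replicates: int,
                   replication_config: Optional[SimulationConfig] = None,
                   m_permutations: int = 99,
                   stage2_p: float = 0.01, combined_p: float = 5.0e-7,
                   perm_p: float = 0.01,
                   check_selection: bool = True) -> RecoverySummary:
    """Repeatedly simulate, re-estimate the planted interaction, and
    summarise bias, 95% CI coverage of the true beta3, and how often the
    two-stage filter chain selects the planted pair.

    ``config`` must plant exactly one interaction; per-replicate seeds are
    derived from ``config.seed``.  Selection uses the replication cohort
    described by ``replication_config`` (defaults to the same cohort sizes)
    and the published thresholds.
    """
    from .scan import interaction_test
    from .staged import combine_datasets, permutation_test

    if len(config.planted_effects) != 1:
        raise ValueError("recovery_study expects exactly one planted effect")
    effect = config.planted_effects[0]
    if replication_config is None:
        replication_config = config

    betas, covered, selected = [], [], []
    for r in range(n_replicates):
        cfg1 = SimulationConfig(**{**asdict(config),
                                   "seed": (config.seed + 7919 * r) % (2**31),
                                   "planted_effects": config.planted_effects})
        cfg2 = SimulationConfig(**{**asdict(replication_config),
                                   "seed": (config.seed + 7919 * r + 1) % (2**31),
                                   "planted_effects": config.planted_effects,
                                   "n_snps": config.n_snps})
        d1, d2, _truth = simulate_two_stage(cfg1, cfg2)
        aid = d1.snps["snp_id"].iloc[effect.snp_a_index]
        bid = d1.snps["snp_id"].iloc[effect.snp_b_index]
        pair = (aid, bid)
        r1 = interaction_test(d1.dosage_of(aid), d1.dosage_of(bid),
                              d1.phenotype, aid, bid)
        if r1.status != "ok":
            continue
        betas.append(r1.beta3)
        lo = r1.beta3 - 1.959963984540054 * r1.se_beta3
        hi = r1.beta3 + 1.959963984540054 * r1.se_beta3
        covered.append(lo <= effect.beta3 <= hi)

        if not check_selection:
            continue
        r2 = interaction_test(d2.dosage_of(aid), d2.dosage_of(bid),
                              d2.phenotype, aid, bid)
        dc = combine_datasets(d1, d2)
        rc = interaction_test(dc.dosage_of(aid), dc.dosage_of(bid),
                              dc.phenotype, aid, bid)
        sel = (r2.status == "ok" and r2.p_interaction < stage2_p
               and rc.status == "ok" and rc.p_interaction < combined_p)
        if sel and m_permutations > 0:
            for ds in (d1, d2, dc):
                summ = permutation_test(ds, [pair], m=m_permutations,
                                        seed=cfg1.seed + 13)[pair]
                if summ is None or summ.p_permutation >= perm_p:
                    sel = False
                    break
        selected.append(sel)

    betas_arr = np.array(betas)
    return RecoverySummary(
        n_replicates=len(betas),
        mean_beta3_hat=float(betas_arr.mean()) if len(betas) else np.nan,
        mean_bias=float(betas_arr.mean() - effect.beta3) if len(betas) else np.nan,
        ci_coverage=float(np.mean(covered)) if covered else np.nan,
        selection_power=float(np.mean(selected)) if selected else 0.0,
    )
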