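"""Two-stage replication: re-test top discovery pairs in an independent
cohort, pool the cohorts for a combined analysis, attach phenotype-
permutation p-values, and apply the selection filter chain
(stage-2 p < 0.01, combined p < 5e-7, all permutation p < 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset
from .scan import (
    STATUS_OK, InteractionResult, _interaction_batch, _make_result,
    batch_logistic_wald,
)

Pair = tuple[str, str]

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "0": "0"}


@dataclass
class PermutationSummary:
    """Permutation p-value bookkeeping for one pair: p = (b+1)/(m+1)."""

    m: int
    b: int
    seed: int

    def __post_init__(self):
        if not (0 <= self.b <= self.m):
            raise ValueError("b must be in [0, m]")

    @property
    def p_permutation(self) -> float:
        return (self.b + 1) / (self.m + 1)


@dataclass
class StagedCandidate:
    """One SNP pair tracked across the discovery/replication/combined stages."""

    pair: Pair
    p_stage1: Optional[float] = None
    p_stage2: Optional[float] = None
    p_combined: Optional[float] = None
    p_perm_stage1: Optional[float] = None
    p_perm_stage2: Optional[float] = None
    p_perm_combined: Optional[float] = None
    testable_in_stage2: bool = False
    passes_filters: bool = False


# ---------------------------------------------------------------------------
# allele harmonisation between cohorts
# ---------------------------------------------------------------------------

def harmonize_to_reference(dataset: GenotypeDataset,
                           reference_snps: pd.DataFrame) -> GenotypeDataset:
    """Re-orient shared markers so allele coding matches the reference map.

    For markers present in both panels: matching (A1, A2) are kept; swapped
    alleles flip the dosage d -> 2-d; a strand flip resolvable by base
    complement is relabelled; strand-ambiguous (A/T, C/G) or otherwise
    discordant allele sets are dropped with a warning rather than guessed.
    """
    ref = {r.snp_id: (r.allele_a1, r.allele_a2)
           for r in reference_snps.itertuples(index=False)}
    ds = dataset.copy()
    a1 = ds.snps["allele_a1"].to_numpy().copy()
    a2 = ds.snps["allele_a2"].to_numpy().copy()
    drop: list[int] = []
    for j, sid in enumerate(ds.snps["snp_id"]):
        if sid not in ref:
            continue
        ra1, ra2 = ref[sid]
        if (a1[j], a2[j]) == (ra1, ra2):
            continue
        if (a2[j], a1[j]) == (ra1, ra2):
            col = ds.dosage[:, j]
            ds.dosage[:, j] = np.where(col >= 0, 2 - col, MISSING)
            a1[j], a2[j] = ra1, ra2
            continue
        if {a1[j], a2[j]} in _AMBIGUOUS:
            drop.append(j)
            continue
        ca1, ca2 = _COMP.get(a1[j], "?"), _COMP.get(a2[j], "?")
        if (ca1, ca2) == (ra1, ra2):
            a1[j], a2[j] = ra1, ra2
        elif (ca2, ca1) == (ra1, ra2):
            col = ds.dosage[:, j]
            ds.dosage[:, j] = np.where(col >= 0, 2 - col, MISSING)
            a1[j], a2[j] = ra1, ra2
        else:
            drop.append(j)
    ds.snps["allele_a1"] = a1
    ds.snps["allele_a2"] = a2
    if drop:
        dropped_ids = ds.snps["snp_id"].iloc[drop].tolist()
        warnings.warn(
            f"dropping {len(drop)} markers with discordant/ambiguous alleles "
            f"vs reference: {dropped_ids[:5]}{'...' if len(drop) > 5 else ''}"
        )
        keep = np.ones(ds.n_snps, dtype=bool)
        keep[drop] = False
        ds = ds.subset_markers(keep)
    return ds


# ---------------------------------------------------------------------------
# batched pair testing
# ---------------------------------------------------------------------------

def test_pairs(dataset: GenotypeDataset, pairs: Sequence[Pair],
               chunk_size: int = 2048) -> list[InteractionResult]:
    """Interaction-test an explicit list of pairs (all must be present)."""
    index = dataset.snp_index()
    ia = np.array([index[a] for a, b in pairs], dtype=np.int64)
    ib = np.array([index[b] for a, b in pairs], dtype=np.int64)
    out: list[InteractionResult] = []
    for start in range(0, len(pairs), chunk_size):
        sa, sb = ia[start:start + chunk_size], ib[start:start + chunk_size]
        X, y, mask = _interaction_batch(
            dataset.dosage[:, sa].T, dataset.dosage[:, sb].T,
            dataset.phenotype)
        b, se, stat, p, n_used, status = batch_logistic_wald(
            X, y, mask, test_index=3)
        for k in range(len(sa)):
            a_id, b_id = pairs[start + k]
            out.append(_make_result(a_id, b_id, b[k], se[k], stat[k], p[k],
                                    int(n_used[k]), status[k]))
    return out


def replicate_pairs(pairs: Sequence[Pair], dataset2: GenotypeDataset,
                    reference_snps: pd.DataFrame | None = None
                    ) -> list[tuple[Pair, Optional[InteractionResult]]]:
    """Re-test discovery pairs in the replication cohort.

    A pair is untestable (result ``None``) iff either SNP is absent from the
    replication panel; untestability is data, not an error.  When the
    discovery marker map is supplied, allele coding is harmonised to it
    first (markers dropped by harmonisation become untestable).
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    ds2 = (harmonize_to_reference(dataset2, reference_snps)
           if reference_snps is not None else dataset2)
    present = set(ds2.snps["snp_id"])
    testable = [p for p in pairs if p[0] in present and p[1] in present]
    results = {(r.snp_a_id, r.snp_b_id): r for r in test_pairs(ds2, testable)}
    return [(p, results.get(p)) for p in pairs]


def untestable_fraction(
        replicated: Sequence[tuple[Pair, Optional[InteractionResult]]]
) -> float:
    return sum(1 for _, r in replicated if r is None) / len(replicated)


# ---------------------------------------------------------------------------
# combining cohorts
# ---------------------------------------------------------------------------

def combine_datasets(d1: GenotypeDataset, d2: GenotypeDataset
                     ) -> GenotypeDataset:
    """Pool two cohorts on the intersection of their marker panels.

    Marker order and allele orientation follow ``d1``; ``d2`` is
    harmonised first.  Colliding sample ids in ``d2`` gain a ``_2`` suffix
    with a warning.
    """
    d2h = harmonize_to_reference(d2, d1.snps)
    shared = [s for s in d1.snps["snp_id"] if s in set(d2h.snps["snp_id"])]
    if not shared:
        raise ValueError("empty marker intersection between cohorts")
    idx1 = d1.snp_index()
    idx2 = d2h.snp_index()
    k1 = np.array([idx1[s] for s in shared])
    k2 = np.array([idx2[s] for s in shared])

    ids1 = set(d1.sample_ids.tolist())
    new_ids = []
    n_collide = 0
    for sid in d2h.sample_ids:
        if sid in ids1:
            n_collide += 1
            sid = f"{sid}_2"
        new_ids.append(sid)
    if n_collide:
        warnings.warn(f"{n_collide} sample ids collide; suffixed with '_2'")

    return GenotypeDataset(
        snps=d1.snps.iloc[k1].copy(),
        sample_ids=np.concatenate([d1.sample_ids,
                                   np.array(new_ids, dtype=object)]),
        dosage=np.vstack([d1.dosage[:, k1], d2h.dosage[:, k2]]),
        phenotype=np.concatenate([d1.phenotype, d2h.phenotype]),
        sex=np.concatenate([d1.sex, d2h.sex]),
    )


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def make_permuted_phenotypes(phenotype: np.ndarray, m: int, seed: int
                             ) -> np.ndarray:
    """m dataset-level permutations of the phenotype vector (Philox stream)."""
    rng = np.random.Generator(np.random.Philox(seed))
    return np.array([rng.permutation(phenotype) for _ in range(m)],
                    dtype=np.int8)


def permutation_test(dataset: GenotypeDataset, pairs: Sequence[Pair],
                     m: int = 10_000, seed: int = 0,
                     perm_chunk: int = 1000
                     ) -> dict[Pair, Optional[PermutationSummary]]:
    """Phenotype-permutation p-values for each pair.

    One shared stream of ``m`` permuted phenotype vectors is used for all
    pairs (labels are permuted at the dataset level, genotypes fixed).  For
    each permutation the interaction p is recomputed; ``b`` counts
    permutations whose pseudo-p is <= the observed p (ties count as
    extreme; non-ok pseudo-fits count as non-extreme), and
    p_permutation = (b+1)/(m+1).  A pair whose observed fit is non-ok gets
    ``None``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    observed = {(r.snp_a_id, r.snp_b_id): r for r in test_pairs(dataset, list(pairs))}
    perms = make_permuted_phenotypes(dataset.phenotype, m, seed)

    index = dataset.snp_index()
    out: dict[Pair, Optional[PermutationSummary]] = {}
    for pair in pairs:
        obs = observed[pair]
        if obs.status != STATUS_OK:
            out[pair] = None
            continue
        da = dataset.dosage[:, index[pair[0]]]
        db = dataset.dosage[:, index[pair[1]]]
        b_count = 0
        for start in range(0, m, perm_chunk):
            ph_block = perms[start:start + perm_chunk]
            B = ph_block.shape[0]
            X, _, _ = _interaction_batch(da[None, :], db[None, :],
                                         dataset.phenotype)
            Xb = np.broadcast_to(X, (B,) + X.shape[1:])
            mask = ((da >= 0) & (db >= 0))[None, :] & (ph_block >= 0)
            y = (ph_block == 1).astype(np.float64)
            _, _, _, pv, _, status = batch_logistic_wald(
                Xb, y, mask, test_index=3)
            okp = status == STATUS_OK
            b_count += int((pv[okp] <= obs.p_interaction).sum())
        out[pair] = PermutationSummary(m=m, b=b_count, seed=seed)
    return out


# ---------------------------------------------------------------------------
# the filter chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionThresholds:
    max_p_stage2: float = 0.01
    max_p_combined: float = 5.0e-7
    max_p_permutation: float = 0.01


def filter_candidates(candidates: Sequence[StagedCandidate],
                      thresholds: SelectionThresholds = SelectionThresholds()
                      ) -> list[StagedCandidate]:
    """Apply the conjunction of selection rules; untestable pairs never pass.

    Passing candidates are returned sorted by combined p ascending, with
    ``passes_filters`` set on every input candidate.
    """
    t = thresholds
    passing = []
    for c in candidates:
        ok = (
            c.testable_in_stage2
            and c.p_stage2 is not None and c.p_stage2 < t.max_p_stage2
            and c.p_combined is not None and c.p_combined < t.max_p_combined
            and c.p_perm_stage1 is not None
            and c.p_perm_stage1 < t.max_p_permutation
            and c.p_perm_stage2 is not None
            and c.p_perm_stage2 < t.max_p_permutation
            and c.p_perm_combined is not None
            and c.p_perm_combined < t.max_p_permutation
        )
        c.passes_filters = ok
        if ok:
            passing.append(c)
    passing.sort(key=lambda c: (c.p_combined, c.pair))
    return passing


def candidates_to_frame(candidates: Sequence[StagedCandidate]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "SNP1": c.pair[0], "SNP2": c.pair[1],
            "P_STAGE1": c.p_stage1, "P_STAGE2": c.p_stage2,
            "P_COMBINED": c.p_combined,
            "P_PERM_S1": c.p_perm_stage1, "P_PERM_S2": c.p_perm_stage2,
            "P_PERM_COMB": c.p_perm_combined,
            "TESTABLE": c.testable_in_stage2, "PASS": c.passes_filters,
        }
        for c in candidates
    ])
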