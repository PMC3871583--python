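"""Replication, cohort combining, permutation p-values, filter chain."""

import numpy as np
import pytest

from epipair.scan import STATUS_OK, interaction_test
from epipair.staged import (
    PermutationSummary, SelectionThresholds, StagedCandidate,
    combine_datasets, filter_candidates, harmonize_to_reference,
    make_permuted_phenotypes, permutation_test, replicate_pairs,
    untestable_fraction,
)
from epipair.staged import test_pairs as fit_pairs

from conftest import make_dataset, random_dataset


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

def test_missing_marker_is_untestable(rng):
    d2 = random_dataset(rng, n=40, m=3)
    rep = replicate_pairs([("rs1", "rs2"), ("rs1", "rs99")], d2)
    assert rep[0][1] is not None
    assert rep[1][1] is None
    assert untestable_fraction(rep) == 0.5


def test_replication_on_same_dataset_is_identity(rng):
    ds = random_dataset(rng, n=80, m=6)
    pairs = [("rs1", "rs2"), ("rs3", "rs6")]
    rep = dict(replicate_pairs(pairs, ds, reference_snps=ds.snps))
    for a, b in pairs:
        direct = interaction_test(ds.dosage_of(a), ds.dosage_of(b),
                                  ds.phenotype, a, b)
        assert rep[(a, b)].p_interaction == pytest.approx(
            direct.p_interaction, abs=1e-12)


def test_constructed_untestable_fraction(rng):
    """A panel built to drop SNPs of 4.67% of pairs reports exactly that."""
    n_pairs = 300
    ids = [f"rs{k}" for k in range(2 * n_pairs)]
    pairs = [(ids[2 * k], ids[2 * k + 1]) for k in range(n_pairs)]
    n_drop = 14  # 14/300 = 4.67%
    dropped = {pairs[k][1] for k in range(n_drop)}
    keep_ids = [s for s in ids if s not in dropped]
    ds2 = make_dataset(
        rng.integers(0, 3, size=(30, len(keep_ids))).astype(np.int8),
        [1] * 15 + [0] * 15, ids=keep_ids,
        pos=list(range(1, len(keep_ids) + 1)))
    rep = replicate_pairs(pairs, ds2)
    assert untestable_fraction(rep) == pytest.approx(n_drop / n_pairs)


def test_allele_harmonization_flips_swapped_coding(rng):
    d1 = random_dataset(rng, n=50, m=2)
    d2 = d1.copy()
    # swap allele labels and dosage orientation at rs1
    d2.snps.loc[0, ["allele_a1", "allele_a2"]] = (
        d1.snps.loc[0, "allele_a2"], d1.snps.loc[0, "allele_a1"])
    col = d2.dosage[:, 0]
    d2.dosage[:, 0] = np.where(col >= 0, 2 - col, -1)
    h = harmonize_to_reference(d2, d1.snps)
    assert np.array_equal(h.dosage, d1.dosage)
    assert h.snps["allele_a1"].tolist() == d1.snps["allele_a1"].tolist()


def test_ambiguous_discordant_marker_dropped(rng):
    d1 = random_dataset(rng, n=30, m=2, maf=(0.3, 0.5))
    d1.snps.loc[0, ["allele_a1", "allele_a2"]] = ("A", "T")
    d2 = d1.copy()
    d2.snps.loc[0, ["allele_a1", "allele_a2"]] = ("A", "C")
    with pytest.warns(UserWarning, match="discordant"):
        h = harmonize_to_reference(d2, d1.snps)
    assert h.n_snps == 1


# ---------------------------------------------------------------------------
# combining cohorts
# ---------------------------------------------------------------------------

def test_combine_with_empty_cohort_is_identity(rng):
    d1 = random_dataset(rng, n=40, m=5)
    empty = d1.subset_samples(np.zeros(40, dtype=bool))
    dc = combine_datasets(d1, empty)
    assert dc.equals(d1)


def test_combine_conserves_samples(rng):
    d1 = random_dataset(rng, n=40, m=5)
    d2 = random_dataset(np.random.default_rng(7), n=25, m=5)
    d2.sample_ids = np.array([f"T{i}" for i in range(25)], dtype=object)
    dc = combine_datasets(d1, d2)
    assert dc.n_samples == 65
    assert dc.n_snps == 5


def test_combine_order_insensitive_for_association(rng):
    d1 = random_dataset(rng, n=60, m=4)
    d2 = random_dataset(np.random.default_rng(3), n=50, m=4)
    d2.sample_ids = np.array([f"T{i}" for i in range(50)], dtype=object)
    r12 = fit_pairs(combine_datasets(d1, d2), [("rs1", "rs3")])[0]
    r21 = fit_pairs(combine_datasets(d2, d1), [("rs1", "rs3")])[0]
    assert r12.beta3 == pytest.approx(r21.beta3, abs=1e-10)
    assert r12.p_interaction == pytest.approx(r21.p_interaction, abs=1e-10)


def test_combine_self_duplication_shrinks_se(rng):
    d = random_dataset(rng, n=100, m=3)
    with pytest.warns(UserWarning, match="collide"):
        dc = combine_datasets(d, d)
    r1 = fit_pairs(d, [("rs1", "rs2")])[0]
    r2 = fit_pairs(dc, [("rs1", "rs2")])[0]
    assert r2.beta3 == pytest.approx(r1.beta3, abs=1e-6)
    assert r2.se_beta3 == pytest.approx(r1.se_beta3 / np.sqrt(2), abs=1e-6)


def test_combine_empty_intersection_errors(rng):
    d1 = random_dataset(rng, n=10, m=2)
    d2 = random_dataset(rng, n=10, m=2)
    d2.snps["snp_id"] = ["other1", "other2"]
    with pytest.raises(ValueError, match="intersection"):
        combine_datasets(d1, d2)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def test_permutation_formula_bounds():
    assert PermutationSummary(m=10_000, b=0, seed=0).p_permutation == \
        pytest.approx(1 / 10_001)
    assert PermutationSummary(m=10_000, b=10_000, seed=0).p_permutation == 1.0
    with pytest.raises(ValueError):
        PermutationSummary(m=10, b=11, seed=0)


def test_permutation_monotone_in_b():
    ps = [PermutationSummary(m=99, b=b, seed=0).p_permutation
          for b in range(100)]
    assert all(x < y for x, y in zip(ps, ps[1:]))


def test_permutation_against_brute_force_recount(rng):
    """b equals an independent recount over the same permuted phenotypes."""
    ds = random_dataset(rng, n=60, m=4, missing=0.03)
    pair = ("rs1", "rs3")
    m = 200
    summary = permutation_test(ds, [pair], m=m, seed=42)[pair]

    obs = interaction_test(ds.dosage_of(pair[0]), ds.dosage_of(pair[1]),
                           ds.phenotype)
    perms = make_permuted_phenotypes(ds.phenotype, m, seed=42)
    b = 0
    for t in range(m):
        r = interaction_test(ds.dosage_of(pair[0]), ds.dosage_of(pair[1]),
                             perms[t])
        if r.status == STATUS_OK and r.p_interaction <= obs.p_interaction:
            b += 1
    assert summary.b == b
    assert summary.p_permutation == pytest.approx((b + 1) / (m + 1))


def test_permutation_reproducible_and_label_swap_invariant(rng):
    ds = random_dataset(rng, n=50, m=3)
    pair = ("rs1", "rs2")
    s1 = permutation_test(ds, [pair], m=60, seed=5)[pair]
    s2 = permutation_test(ds, [pair], m=60, seed=5)[pair]
    assert s1.b == s2.b
    flipped = ds.copy()
    flipped.phenotype = np.where(ds.phenotype >= 0, 1 - ds.phenotype,
                                 ds.phenotype).astype(np.int8)
    s3 = permutation_test(flipped, [pair], m=60, seed=5)[pair]
    assert s3.b == s1.b


def test_permutation_null_uniform_on_grid(rng):
    """Under the null the permutation p is uniform on {(b+1)/(m+1)}."""
    hits = 0
    n_rep = 200
    m = 99
    for k in range(n_rep):
        r = np.random.default_rng(900 + k)
        ds = random_dataset(r, n=40, m=2, balanced=False)
        s = permutation_test(ds, [("rs1", "rs2")], m=m, seed=1000 + k)
        summ = s[("rs1", "rs2")]
        if summ is not None and summ.p_permutation <= 0.05:
            hits += 1
    # binomial 99% band around 0.05 of 200
    assert 3 <= hits <= 18


def test_permutation_non_ok_observed_flagged(rng):
    ds = random_dataset(rng, n=40, m=2)
    ds.dosage[:, 1] = 0  # constant -> collinear
    out = permutation_test(ds, [("rs1", "rs2")], m=20, seed=0)
    assert out[("rs1", "rs2")] is None


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------

def _cand(pair, p2, pc, perms=(1e-3, 1e-3, 1e-3), testable=True, p1=1e-5):
    return StagedCandidate(
        pair=pair, p_stage1=p1, p_stage2=p2, p_combined=pc,
        p_perm_stage1=perms[0], p_perm_stage2=perms[1],
        p_perm_combined=perms[2], testable_in_stage2=testable)


def test_filter_strict_thresholds():
    c = _cand(("a", "b"), p2=0.011, pc=1e-9)
    assert filter_candidates([c]) == []
    c2 = _cand(("a", "b"), p2=0.009, pc=1e-9)
    assert filter_candidates([c2]) == [c2]
    assert c2.passes_filters


def test_filter_empty_input():
    assert filter_candidates([]) == []


def test_filter_untestable_never_passes():
    c = _cand(("a", "b"), p2=1e-4, pc=1e-9, testable=False)
    assert filter_candidates([c]) == []


def test_filter_against_mask_oracle(rng):
    """Passing set equals an explicit per-rule boolean mask."""
    cands = []
    for k in range(100):
        cands.append(StagedCandidate(
            pair=(f"a{k}", f"b{k}"),
            p_stage1=rng.random() * 1e-4,
            p_stage2=float(rng.choice([rng.random() * 0.02, np.nan])),
            p_combined=rng.random() * 1e-6,
            p_perm_stage1=rng.random() * 0.02,
            p_perm_stage2=rng.random() * 0.02,
            p_perm_combined=rng.random() * 0.02,
            testable_in_stage2=bool(rng.random() < 0.9)))
        if np.isnan(cands[-1].p_stage2):
            cands[-1].p_stage2 = None
    got = {c.pair for c in filter_candidates(cands)}
    expect = set()
    for c in cands:
        if (c.testable_in_stage2 and c.p_stage2 is not None
                and c.p_stage2 < 0.01 and c.p_combined < 5e-7
                and c.p_perm_stage1 < 0.01 and c.p_perm_stage2 < 0.01
                and c.p_perm_combined < 0.01):
            expect.add(c.pair)
    assert got == expect


def test_filter_output_sorted_by_combined_p():
    cs = [_cand(("x", "y"), 1e-3, 4e-7), _cand(("a", "b"), 1e-3, 1e-9),
          _cand(("m", "n"), 1e-3, 1e-8)]
    out = filter_candidates(cs)
    assert [c.pair for c in out] == [("a", "b"), ("m", "n"), ("x", "y")]
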