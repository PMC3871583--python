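"""EM haplotype frequencies, LD statistics, haplotype association."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from epipair.datatypes import GenotypeDataset
from epipair.ldhap import (
    _em_core, em_haplotypes, haplotype_association, ld_pair,
)

from conftest import make_dataset, random_dataset


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def test_no_phase_ambiguity_equals_direct_counting():
    """All-homozygote samples: frequencies are direct haplotype counts."""
    # 6 samples: 3x hom(A1,A1), 2x hom(A2,A2), 1x hom(A1,A2)
    dosage = np.array([[2, 2]] * 3 + [[0, 0]] * 2 + [[2, 0]], dtype=np.int8)
    ds = make_dataset(dosage, [1] * 3 + [0] * 3)
    tab = em_haplotypes(ds, ["rs1", "rs2"])
    freqs = dict(zip(tab.haplotypes, tab.frequencies))
    # allele_a1='A', allele_a2='G'; haplotype strings are over the loci
    assert freqs["AA"] == pytest.approx(6 / 12)
    assert freqs["GG"] == pytest.approx(4 / 12)
    assert freqs["AG"] == pytest.approx(2 / 12)


def test_complete_association_two_haplotypes():
    """Identical genotype vectors at MAF 0.5 give two 0.5 haplotypes."""
    g = np.array([0, 1, 2, 1, 0, 2, 1, 1, 0, 2], dtype=np.int8)
    ds = make_dataset(np.column_stack([g, g]), [1] * 5 + [0] * 5)
    tab = em_haplotypes(ds, ["rs1", "rs2"])
    top = sorted(zip(tab.frequencies, tab.haplotypes), reverse=True)[:2]
    assert top[0][0] == pytest.approx(0.5, abs=1e-6)
    assert top[1][0] == pytest.approx(0.5, abs=1e-6)
    assert {h for _, h in top} == {"AA", "GG"}
    st = ld_pair(g, g)
    assert st.d_prime == pytest.approx(1.0, abs=1e-9)
    assert st.r2 == pytest.approx(1.0, abs=1e-9)


def _loglik_oracle(genmat, freqs_by_hap):
    """Independent genotype log-likelihood by phase enumeration."""
    ll = 0.0
    for row in genmat:
        het = [i for i, g in enumerate(row) if g == 1]
        base = sum(1 << i for i, g in enumerate(row) if g == 2)
        prob = 0.0
        if not het:
            prob = freqs_by_hap.get(base, 0.0) ** 2
        else:
            for bits in itertools.product([0, 1], repeat=len(het)):
                h1, h2 = base, base
                for b, locus in zip(bits, het):
                    if b:
                        h1 |= 1 << locus
                    else:
                        h2 |= 1 << locus
                prob += freqs_by_hap.get(h1, 0.0) * freqs_by_hap.get(h2, 0.0)
        ll += np.log(max(prob, 1e-300))
    return ll


def test_em_matches_simplex_optimizer_oracle(rng):
    """EM log-likelihood and frequencies match direct simplex maximisation."""
    n, L = 30, 3
    p = rng.uniform(0.2, 0.5, L)
    h1 = (rng.random((n, L)) < p).astype(np.int8)
    h2 = (rng.random((n, L)) < p).astype(np.int8)
    genmat = (h1 + h2).astype(np.int64)
    hap_set, freqs, loglik, _, _, _ = _em_core(genmat, 1e-12, 5000)

    # independent oracle: maximise over the simplex via softmax params,
    # several random restarts, likelihood evaluated by phase enumeration
    def nll(theta):
        e = np.exp(theta - theta.max())
        f = e / e.sum()
        return -_loglik_oracle(genmat, dict(zip(hap_set, f)))

    best = None
    for k in range(6):
        r0 = np.random.default_rng(k).normal(size=len(hap_set))
        res = minimize(nll, r0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10,
                                "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    e = np.exp(best.x - best.x.max())
    f_oracle = e / e.sum()
    assert loglik == pytest.approx(-best.fun, abs=1e-6)
    np.testing.assert_allclose(freqs, f_oracle, atol=1e-4)


def test_em_loglik_monotone_and_frequencies_conserved(rng):
    ds = random_dataset(rng, n=50, m=4, missing=0.05)
    tab = em_haplotypes(ds, ["rs1", "rs2", "rs3", "rs4"])
    assert tab.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
    # monotonicity: re-run the core and check the recorded history
    sub = ds.dosage[:, :4]
    complete = (sub >= 0).all(axis=1)
    *_, history = _em_core(sub[complete].astype(np.int64), 1e-12, 1000)
    diffs = np.diff(history)
    assert (diffs >= -1e-9).all()


def test_em_locus_count_bounds(rng):
    ds = random_dataset(rng, n=20, m=10)
    with pytest.raises(ValueError):
        em_haplotypes(ds, ["rs1"])
    with pytest.raises(ValueError):
        em_haplotypes(ds, [f"rs{j}" for j in range(1, 10)])


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------

def test_ld_closed_forms():
    # complete LD fixture handled above; independence: a sample whose
    # genotype counts exactly factorise (both loci MAF 0.5, n = 64)
    counts = np.outer([16, 32, 16], [16, 32, 16]) // 64
    a, b = [], []
    for i in range(3):
        for j in range(3):
            a.extend([i] * counts[i, j])
            b.extend([j] * counts[i, j])
    st = ld_pair(np.array(a, np.int8), np.array(b, np.int8))
    assert st.d == pytest.approx(0.0, abs=1e-9)
    assert st.d_prime == pytest.approx(0.0, abs=1e-6)
    assert st.r2 == pytest.approx(0.0, abs=1e-9)


def test_ld_symmetry_and_label_flip(rng):
    ds = random_dataset(rng, n=100, m=2)
    a, b = ds.dosage[:, 0], ds.dosage[:, 1]
    s1, s2 = ld_pair(a, b), ld_pair(b, a)
    assert s1.d == pytest.approx(s2.d, abs=1e-9)
    assert s1.d_prime == pytest.approx(s2.d_prime, abs=1e-9)
    flipped = (2 - a).astype(np.int8)
    s3 = ld_pair(flipped, b)
    assert s3.d == pytest.approx(-s1.d, abs=1e-9)
    assert s3.d_prime == pytest.approx(s1.d_prime, abs=1e-9)
    assert s3.r2 == pytest.approx(s1.r2, abs=1e-9)


def test_ld_monomorphic_flagged():
    st = ld_pair(np.zeros(20, np.int8), np.ones(20, np.int8))
    assert not st.defined


def test_ld_matches_phased_counts(rng):
    """On unambiguously phased draws, EM recovers the phased frequencies."""
    n = 200
    hapfreq = {(1, 1): 0.4, (0, 0): 0.4, (1, 0): 0.1, (0, 1): 0.1}
    haps = list(hapfreq)
    idx = rng.choice(len(haps), size=2 * n, p=list(hapfreq.values()))
    drawn = np.array([haps[i] for i in idx])
    a = (drawn[:n, 0] + drawn[n:, 0]).astype(np.int8)
    b = (drawn[:n, 1] + drawn[n:, 1]).astype(np.int8)
    st = ld_pair(a, b)
    # phased-count oracle over the actual gametes
    pAB = (drawn[:, 0] & drawn[:, 1]).mean()
    pA, pB = drawn[:, 0].mean(), drawn[:, 1].mean()
    d_oracle = pAB - pA * pB
    assert st.d == pytest.approx(d_oracle, abs=0.02)


# ---------------------------------------------------------------------------
# haplotype association
# ---------------------------------------------------------------------------

def test_case_only_haplotype_scores_highest():
    """A haplotype carried only by cases gets the smallest p, positive z."""
    # unambiguous phase: homozygotes only
    dosage = np.array(
        [[2, 2]] * 10 + [[0, 0]] * 10 + [[2, 0]] * 4, dtype=np.int8)
    phen = np.array([1] * 10 + [0] * 10 + [0] * 4, dtype=np.int8)
    ds = make_dataset(dosage, phen)
    tab = em_haplotypes(ds, ["rs1", "rs2"])
    assoc = haplotype_association(tab, ds.phenotype, min_freq=0.01)
    k = assoc.haplotypes.index("AA")
    assert assoc.p_values[k] == min(assoc.p_values)
    assert assoc.scores[k] > 0


def test_unambiguous_phase_equals_counted_dosage_score(rng):
    """With only homozygous samples the score test equals one computed on
    directly counted haplotype dosages."""
    n = 80
    g = rng.choice([0, 2], size=(n, 2), p=[0.5, 0.5]).astype(np.int8)
    phen = (rng.random(n) < 0.5).astype(np.int8)
    if phen.sum() in (0, n):
        phen[0] = 1 - phen[0]
    ds = make_dataset(g, phen)
    tab = em_haplotypes(ds, ["rs1", "rs2"])
    assoc = haplotype_association(tab, ds.phenotype, min_freq=0.0)

    y = phen.astype(float)
    for k, hap in enumerate(assoc.haplotypes):
        counted = np.zeros(n)
        for i in range(n):
            alleles = "".join("A" if g[i, l] == 2 else "G" for l in range(2))
            if alleles == hap:
                counted[i] = 2.0
        U = counted @ (y - y.mean())
        V = y.mean() * (1 - y.mean()) * ((counted - counted.mean()) ** 2).sum()
        z = U / np.sqrt(V) if V > 0 else 0.0
        assert assoc.scores[k] == pytest.approx(z, abs=1e-8)


def test_rare_haplotypes_pooled(rng):
    ds = random_dataset(rng, n=150, m=3)
    tab = em_haplotypes(ds, ["rs1", "rs2", "rs3"])
    assoc = haplotype_association(tab, ds.phenotype, min_freq=0.05)
    rare_mass = tab.frequencies[tab.frequencies < 0.05].sum()
    if rare_mass > 0:
        assert assoc.haplotypes[-1] == "rare"
        assert assoc.frequencies[-1] == pytest.approx(rare_mass, abs=1e-9)


def test_single_common_haplotype_global_undefined():
    dosage = np.array([[2, 2]] * 19 + [[1, 1]], dtype=np.int8)
    ds = make_dataset(dosage, [1] * 10 + [0] * 10)
    tab = em_haplotypes(ds, ["rs1", "rs2"])
    assoc = haplotype_association(tab, ds.phenotype, min_freq=0.2)
    assert assoc.global_p is None


def test_null_haplotype_pvalues_uniform():
    """Permuted labels: per-haplotype p roughly uniform over replicates."""
    hits = total = 0
    for k in range(200):
        rng = np.random.default_rng(3000 + k)
        ds = random_dataset(rng, n=500, m=2, maf=(0.3, 0.5), balanced=False)
        tab = em_haplotypes(ds, ["rs1", "rs2"])
        assoc = haplotype_association(tab, ds.phenotype)
        # take the first common haplotype's p
        hits += assoc.p_values[0] < 0.05
        total += 1
    # binomial 99% band around 0.05 of 200 replicates
    assert 3 <= hits <= 18
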