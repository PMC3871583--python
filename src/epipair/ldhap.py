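"""EM haplotype-frequency estimation, pairwise LD, and haplotype association.

Haplotype frequencies over 2-8 loci are estimated from unphased genotypes
by expectation-maximisation over the diplotype configurations consistent
with each multilocus genotype; samples missing any genotype at the chosen
loci are excluded.  Pairwise D, D' and r^2 are derived from the two-locus
EM frequencies.  The case-control haplotype test scores each sample's
expected haplotype dosage (posterior diplotype expectation at the
converged frequencies) against disease status, pooling haplotypes rarer
than ``min_freq`` (default 0.01) into a single class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2

from .datatypes import GenotypeDataset

_DEFAULT_TOL = 1e-10
_DEFAULT_MAX_ITER = 1000
MIN_HAP_FREQ = 0.01


@dataclass
class HaplotypeTable:
    """EM-estimated haplotype frequencies over a small set of loci."""

    loci: list[str]  # SNP ids, order matches haplotype strings
    haplotypes: list[str]  # allele strings, e.g. "AGT"
    hap_codes: np.ndarray  # same haplotypes as bitmasks over loci (bit=A1)
    frequencies: np.ndarray
    log_likelihood: float
    n_iter: int
    expected_dosage: np.ndarray  # (n_used, n_haplotypes)
    sample_index: np.ndarray  # rows of the source dataset that were used

    def __post_init__(self):
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if (self.frequencies < -1e-12).any():
            raise ValueError("negative haplotype frequency")


def _compatible_pairs(pattern: tuple[int, ...]) -> list[tuple[int, int]]:
    """Unordered haplotype-code pairs consistent with a multilocus genotype."""
    het = [i for i, g in enumerate(pattern) if g == 1]
    base = 0
    for i, g in enumerate(pattern):
        if g == 2:
            base |= 1 << i
    if not het:
        return [(base, base)]
    pairs = []
    first, rest = het[0], het[1:]
    for assign in range(1 << len(rest)):
        h1 = base | (1 << first)
        h2 = base
        for k, locus in enumerate(rest):
            if (assign >> k) & 1:
                h1 |= 1 << locus
            else:
                h2 |= 1 << locus
        pairs.append((h1, h2))
    return pairs


def _em_core(genmat: np.ndarray, tol: float, max_iter: int):
    """Run EM on complete (n, L) genotype rows; returns the fitted pieces."""
    n, L = genmat.shape
    patterns: dict[tuple[int, ...], list[int]] = {}
    for i, row in enumerate(map(tuple, genmat.tolist())):
        patterns.setdefault(row, []).append(i)

    pair_lists = {pat: _compatible_pairs(pat) for pat in patterns}
    hap_set = sorted({h for pl in pair_lists.values() for hp in pl for h in hp})
    hap_pos = {h: k for k, h in enumerate(hap_set)}
    H = len(hap_set)

    # init: product of single-locus allele frequencies, plus a deterministic
    # jitter (1e-6 * rank) that breaks the double-heterozygote saddle
    p_a1 = genmat.mean(axis=0) / 2.0
    freqs = np.empty(H)
    for h, k in hap_pos.items():
        pr = 1.0
        for locus in range(L):
            pl = p_a1[locus]
            pr *= pl if (h >> locus) & 1 else (1.0 - pl)
        freqs[k] = pr + 1e-6 * (k + 1)
    freqs /= freqs.sum()

    loglik = -np.inf
    history = []
    for it in range(1, max_iter + 1):
        counts = np.zeros(H)
        ll = 0.0
        for pat, rows in patterns.items():
            w = len(rows)
            pl = pair_lists[pat]
            probs = np.array([
                (freqs[hap_pos[h1]] ** 2 if h1 == h2
                 else 2.0 * freqs[hap_pos[h1]] * freqs[hap_pos[h2]])
                for h1, h2 in pl
            ])
            tot = probs.sum()
            if tot <= 0:
                probs = np.full(len(pl), 1.0 / len(pl))
                tot = 1.0
                ll += w * np.log(1e-300)
            else:
                ll += w * np.log(tot)
            post = probs / tot
            for (h1, h2), q in zip(pl, post):
                counts[hap_pos[h1]] += w * q
                counts[hap_pos[h2]] += w * q
        new_freqs = counts / (2.0 * n)
        gain = ll - loglik
        loglik = ll
        history.append(ll)
        freqs = new_freqs
        if it > 1 and gain < tol:
            break

    # expected per-sample haplotype dosages at the converged frequencies
    expected = np.zeros((n, H))
    for pat, rows in patterns.items():
        pl = pair_lists[pat]
        probs = np.array([
            (freqs[hap_pos[h1]] ** 2 if h1 == h2
             else 2.0 * freqs[hap_pos[h1]] * freqs[hap_pos[h2]])
            for h1, h2 in pl
        ])
        tot = probs.sum()
        post = probs / tot if tot > 0 else np.full(len(pl), 1.0 / len(pl))
        dos = np.zeros(H)
        for (h1, h2), q in zip(pl, post):
            dos[hap_pos[h1]] += q
            dos[hap_pos[h2]] += q
        expected[rows, :] = dos
    return hap_set, freqs, loglik, it, expected, history


def em_haplotypes(dataset: GenotypeDataset, loci: Sequence[str],
                  tol: float = _DEFAULT_TOL,
                  max_iter: int = _DEFAULT_MAX_ITER) -> HaplotypeTable:
    """EM haplotype frequencies for 2-8 named loci of a dataset.

    Samples with a missing genotype at any locus are excluded.  The
    log-likelihood is non-decreasing across iterations; iteration stops on
    a gain below ``tol`` or at ``max_iter``.
    """
    if not (2 <= len(loci) <= 8):
        raise ValueError("em_haplotypes supports 2-8 loci")
    index = dataset.snp_index()
    cols = np.array([index[s] for s in loci])
    sub = dataset.dosage[:, cols]
    complete = (sub >= 0).all(axis=1)
    if not complete.any():
        raise ValueError("no samples with complete genotypes at the loci")
    genmat = sub[complete, :].astype(np.int64)
    hap_set, freqs, loglik, n_iter, expected, _ = _em_core(
        genmat, tol, max_iter)

    a1 = [dataset.snps["allele_a1"].iloc[c] for c in cols]
    a2 = [dataset.snps["allele_a2"].iloc[c] for c in cols]
    hap_strings = [
        "".join(a1[l] if (h >> l) & 1 else a2[l] for l in range(len(loci)))
        for h in hap_set
    ]
    return HaplotypeTable(
        loci=list(loci), haplotypes=hap_strings,
        hap_codes=np.array(hap_set), frequencies=freqs,
        log_likelihood=float(loglik), n_iter=n_iter,
        expected_dosage=expected,
        sample_index=np.flatnonzero(complete),
    )


# ---------------------------------------------------------------------------
# pairwise LD
# ---------------------------------------------------------------------------

@dataclass
class LDStats:
    d: float
    d_prime: float
    r2: float
    n_used: int
    defined: bool = True


def ld_pair(dosage_a: np.ndarray, dosage_b: np.ndarray) -> LDStats:
    """Pairwise D, D' and r^2 from EM-estimated haplotype frequencies.

    Computed on samples complete for both SNPs; to mirror LD heatmaps of
    control samples, pass control-subset dosage vectors.  Monomorphic
    input yields a flagged, undefined result.
    """
    da = np.asarray(dosage_a)
    db = np.asarray(dosage_b)
    complete = (da >= 0) & (db >= 0)
    a, b = da[complete].astype(np.int64), db[complete].astype(np.int64)
    n = len(a)
    if n == 0 or len(set(a.tolist())) < 2 or len(set(b.tolist())) < 2:
        return LDStats(np.nan, np.nan, np.nan, n, defined=False)
    hap_set, freqs, *_ = _em_core(np.column_stack([a, b]), _DEFAULT_TOL,
                                  _DEFAULT_MAX_ITER)
    f = dict(zip(hap_set, freqs))
    p_ab = f.get(0b11, 0.0)  # A1 at both loci
    p_a = f.get(0b01, 0.0) + p_ab
    p_b = f.get(0b10, 0.0) + p_ab
    qa, qb = 1.0 - p_a, 1.0 - p_b
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * qb, qa * p_b)
    else:
        d_max = min(p_a * p_b, qa * qb)
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    denom = p_a * qa * p_b * qb
    r2 = d * d / denom if denom > 0 else 0.0
    return LDStats(d=float(d), d_prime=float(min(d_prime, 1.0)),
                   r2=float(min(r2, 1.0)), n_used=n)


def ld_matrix(dataset: GenotypeDataset, loci: Sequence[str],
              controls_only: bool = True) -> np.ndarray:
    """Symmetric D' matrix over the given loci (NaN where undefined)."""
    index = dataset.snp_index()
    rows = dataset.is_control() if controls_only else np.ones(
        dataset.n_samples, dtype=bool)
    k = len(loci)
    out = np.full((k, k), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            st = ld_pair(dataset.dosage[rows, index[loci[i]]],
                         dataset.dosage[rows, index[loci[j]]])
            out[i, j] = out[j, i] = st.d_prime if st.defined else np.nan
    return out


# ---------------------------------------------------------------------------
# haplotype case-control association
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAssociation:
    haplotypes: list[str]  # tested classes, last may be "rare"
    frequencies: np.ndarray
    scores: np.ndarray  # signed z per class
    p_values: np.ndarray
    global_stat: Optional[float]
    global_df: Optional[int]
    global_p: Optional[float]


def haplotype_association(table: HaplotypeTable, phenotype: np.ndarray,
                          min_freq: float = MIN_HAP_FREQ
                          ) -> HaplotypeAssociation:
    """Score tests of expected haplotype dosage against case status.

    Haplotypes with EM frequency below ``min_freq`` are pooled into one
    "rare" class (keeping all samples in the test).  Each class gets a
    signed score z and 1-df p; the global test is the quadratic form of
    the non-rare score vector with df = n_non_rare - 1, undefined
    (flagged None) when fewer than two non-rare haplotypes exist.
    """
    ph = np.asarray(phenotype)[table.sample_index]
    use = ph >= 0
    y = (ph[use] == 1).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("haplotype association needs cases and controls")
    D = table.expected_dosage[use, :]

    common = table.frequencies >= min_freq
    labels = [h for h, c in zip(table.haplotypes, common) if c]
    cols = [D[:, k] for k in np.flatnonzero(common)]
    freqs = list(table.frequencies[common])
    if (~common).any():
        labels.append("rare")
        cols.append(D[:, ~common].sum(axis=1))
        freqs.append(table.frequencies[~common].sum())
    Dm = np.column_stack(cols)

    ybar = y.mean()
    resid = y - ybar
    U = Dm.T @ resid
    center = Dm - Dm.mean(axis=0)
    var = ybar * (1 - ybar) * (center ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, U / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    p = chi2.sf(z ** 2, df=1)

    k_common = int(common.sum())
    if k_common < 2:
        g_stat = g_df = g_p = None
    else:
        Dc = Dm[:, :k_common]
        Cc = Dc - Dc.mean(axis=0)
        V = ybar * (1 - ybar) * (Cc.T @ Cc)
        Uc = U[:k_common]
        g_stat = float(Uc @ np.linalg.pinv(V) @ Uc)
        g_df = k_common - 1
        g_p = float(chi2.sf(g_stat, df=g_df))

    return HaplotypeAssociation(
        haplotypes=labels, frequencies=np.array(freqs), scores=z,
        p_values=p, global_stat=g_stat, global_df=g_df, global_p=g_p)
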