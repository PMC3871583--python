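"""Marker statistics and quality-control filtering.

The Hardy-Weinberg test is the exact (Levene-Haldane) test: conditional on
the observed allele counts, the number of heterozygotes under random mating
follows the distribution

    P(n_het = h) ∝ 2^h * n! / ((n_hom1)! (n_het)! (n_hom2)!) * ...,

and the two-sided p-value sums the probabilities of all heterozygote counts
(of matching parity) no more probable than the observed one.  The exact
test is preferred over chi-square because the filtering threshold applied
here (5e-5) sits far in the tail, where chi-square is anti-conservative
for rare alleles.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

from .datatypes import CONTROL, MISSING, GenotypeDataset, QCReport, QCThresholds

_REL_TOL = 1.0 + 1e-9  # tie tolerance when summing probabilities <= observed


@lru_cache(maxsize=200_000)
def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact (Levene-Haldane) two-sided Hardy-Weinberg p-value.

    Parameters are genotype counts: heterozygotes and the two homozygote
    classes.  Returns 1.0 for monomorphic configurations.  Uses the
    numerically stable multiplicative recurrence over heterozygote counts
    of the parity fixed by the minor-allele total.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het  # minor allele count
    if rare == 0:
        return 1.0

    # unnormalised probabilities over attainable het counts (parity of rare)
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)  # mode neighbourhood start
    if (mid % 2) != (rare % 2):
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 * hom_r(h)+1)(hom_c(h)+1)
    h = mid
    hom_r = (rare - mid) // 2
    hom_c = n - mid - hom_r
    while h > 1:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        hom_r += 1
        hom_c += 1
    # upward recurrence
    h = mid
    hom_r = (rare - mid) // 2
    hom_c = n - mid - hom_r
    while h <= rare - 2:
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
        hom_r -= 1
        hom_c -= 1
    total = probs.sum()
    p = probs[probs <= probs[n_het] * _REL_TOL].sum() / total
    return float(min(p, 1.0))


def marker_stats(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-marker missing rate, minor allele frequency and control HWE p.

    MAF is computed over all samples with a called genotype (cases and
    controls); HWE is computed in controls only.  With zero controls the
    HWE column is NaN and flagged via the ``hwe_defined`` column.
    """
    if dataset.n_samples < 1:
        raise ValueError("marker_stats requires at least one sample")
    d = dataset.dosage
    called = d != MISSING
    n = dataset.n_samples
    missing_rate = 1.0 - called.sum(axis=0) / n

    a1 = np.where(called, d, 0).sum(axis=0).astype(float)
    alleles = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(alleles > 0, a1 / np.maximum(alleles, 1.0), 0.0)
    maf = np.minimum(f, 1.0 - f)
    maf[alleles == 0] = 0.0

    ctrl = dataset.phenotype == CONTROL
    hwe_defined = bool(ctrl.any())
    if hwe_defined:
        dc = d[ctrl, :]
        n_het = (dc == 1).sum(axis=0)
        n_hom1 = (dc == 2).sum(axis=0)
        n_hom2 = (dc == 0).sum(axis=0)
        hwe = np.fromiter(
            (hwe_exact_p(int(h), int(r), int(c))
             for h, r, c in zip(n_het, n_hom1, n_hom2)),
            dtype=float, count=dataset.n_snps,
        )
    else:
        hwe = np.full(dataset.n_snps, np.nan)

    return pd.DataFrame(
        {
            "snp_id": dataset.snp_ids,
            "missing_rate": missing_rate,
            "maf": maf,
            "hwe_p_controls": hwe,
            "hwe_defined": hwe_defined,
        }
    )


def apply_qc(dataset: GenotypeDataset,
             thresholds: QCThresholds = QCThresholds()
             ) -> tuple[GenotypeDataset, QCReport]:
    """Apply sample call-rate filtering, then marker filters.

    Samples with call rate below ``min_sample_call_rate`` are dropped
    first, so marker statistics reflect the retained samples.  Markers are
    then removed when missing rate exceeds ``max_marker_missing_rate``,
    MAF falls below ``min_maf`` (strict), or the exact HWE p-value in
    controls falls below ``min_hwe_p_controls`` (strict).
    """
    n_samples_in = dataset.n_samples
    n_markers_in = dataset.n_snps

    call_rate = (dataset.dosage != MISSING).sum(axis=1) / max(n_markers_in, 1)
    keep_samples = call_rate >= thresholds.min_sample_call_rate
    sample_reasons = {
        str(sid): ["low_call_rate"]
        for sid in dataset.sample_ids[~keep_samples]
    }
    if not keep_samples.any():
        raise ValueError("empty dataset after QC: all samples removed")
    ds = dataset.subset_samples(keep_samples) if (~keep_samples).any() else dataset

    stats = marker_stats(ds)
    bad_missing = stats["missing_rate"].to_numpy() > thresholds.max_marker_missing_rate
    bad_maf = stats["maf"].to_numpy() < thresholds.min_maf
    hwe = stats["hwe_p_controls"].to_numpy()
    bad_hwe = np.where(np.isnan(hwe), False, hwe < thresholds.min_hwe_p_controls)

    remove = bad_missing | bad_maf | bad_hwe
    marker_reasons: dict[str, list[str]] = {}
    for j in np.flatnonzero(remove):
        reasons = []
        if bad_missing[j]:
            reasons.append("missing_rate")
        if bad_maf[j]:
            reasons.append("maf")
        if bad_hwe[j]:
            reasons.append("hwe")
        marker_reasons[str(stats["snp_id"].iloc[j])] = reasons

    out = ds.subset_markers(~remove) if remove.any() else ds
    report = QCReport(
        n_markers_in=n_markers_in,
        n_markers_removed=int(remove.sum()),
        n_markers_out=out.n_snps,
        n_samples_in=n_samples_in,
        n_samples_removed=int((~keep_samples).sum()),
        n_samples_out=out.n_samples,
        marker_reasons=marker_reasons,
        sample_reasons=sample_reasons,
    )
    return out, report
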