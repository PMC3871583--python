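"""Allelic-dosage logistic-regression interaction test and pairwise scan.

For a SNP pair (A, B) with per-sample allele dosages a, b in {0,1,2} and
binary disease status y, the model

    logit P(y = 1) = b0 + b1*a + b2*b + b3*a*b

is fitted by maximum likelihood (Newton / iteratively reweighted least
squares) and the interaction is tested with the 1-df Wald chi-square on
b3.  Samples missing either dosage or the phenotype are excluded pairwise.

The genome-wide scan partitions markers into sets (one per chromosome by
default) and tests every unordered pair exactly once, streaming results
whose interaction p-value falls below a reporting threshold (1e-4 by
default, since an unfiltered genome-scale scan would emit billions of
rows).  Internally pairs are fitted in vectorised batches; the scalar
:func:`interaction_test` runs the same code path on a batch of one.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from .datatypes import GenotypeDataset, chrom_sort_key

STATUS_OK = "ok"
STATUS_COLLINEAR = "collinear"
STATUS_NOT_CONVERGED = "not_converged"
STATUS_INSUFFICIENT = "insufficient_data"

_MAX_ITER = 25
_TOL = 1e-8
_SEP_COEF = 15.0  # |coef| beyond this flags (quasi-)separation
_COND_EPS = 1e-9  # relative eigenvalue cut for rank deficiency


class InteractionResult(NamedTuple):
    """Outcome of one two-locus interaction test."""

    snp_a_id: str
    snp_b_id: str
    beta3: Optional[float]
    se_beta3: Optional[float]
    stat: Optional[float]
    p_interaction: Optional[float]
    or_interaction: Optional[float]
    n_used: int
    status: str


# ---------------------------------------------------------------------------
# batched logistic fits
# ---------------------------------------------------------------------------

def batch_logistic_wald(X: np.ndarray, y: np.ndarray, mask: np.ndarray,
                        test_index: int, max_iter: int = _MAX_ITER,
                        tol: float = _TOL):
    """Fit B logistic regressions and Wald-test one coefficient in each.

    Parameters
    ----------
    X : (B, n, p) design matrices (values where mask is 0 are ignored).
    y : (n,) or (B, n) binary response.
    mask : (B, n) boolean, sample inclusion per fit.
    test_index : column whose coefficient is Wald-tested.

    Returns
    -------
    beta, se, stat, p : (B,) arrays (NaN where status != ok)
    n_used : (B,) int
    status : (B,) array of status strings
    """
    X = np.asarray(X, dtype=np.float64)
    B, n, p = X.shape
    mask = np.asarray(mask, dtype=bool)
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 1:
        y = np.broadcast_to(y, (B, n))

    fmask = mask.astype(np.float64)
    n_used = mask.sum(axis=1)
    n_case = ((y == 1) & mask).sum(axis=1)
    n_ctrl = ((y == 0) & mask).sum(axis=1)

    status = np.full(B, STATUS_OK, dtype=object)
    status[(n_used < 4) | (n_case == 0) | (n_ctrl == 0)] = STATUS_INSUFFICIENT

    Xm = X * fmask[:, :, None]
    G = np.einsum("bni,bnj->bij", Xm, Xm, optimize=True)
    eig = np.linalg.eigvalsh(G)
    degenerate = eig[:, 0] < _COND_EPS * np.maximum(eig[:, -1], 1.0)
    status[degenerate & (status == STATUS_OK)] = STATUS_COLLINEAR

    active = status == STATUS_OK
    beta = np.zeros((B, p))
    converged = np.zeros(B, dtype=bool)
    # excluded fits iterate on an identity system so the batched solve stays
    # well posed; their outputs are discarded
    dead = ~active

    for _ in range(max_iter):
        todo = active & ~converged
        if not todo.any():
            break
        eta = np.einsum("bnp,bp->bn", X, beta, optimize=True)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None) * fmask
        H = np.einsum("bni,bn,bnj->bij", X, w, X, optimize=True)
        score = np.einsum("bni,bn->bi", X, (y - mu) * fmask, optimize=True)
        H[dead] = np.eye(p)
        score[dead] = 0.0
        try:
            delta = np.linalg.solve(H, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # a fit went singular mid-iteration: regularise minimally
            H = H + 1e-10 * np.eye(p)
            delta = np.linalg.solve(H, score[..., None])[..., 0]
        delta[~todo] = 0.0
        beta = beta + delta
        converged = converged | (np.abs(delta).max(axis=1) < tol)

    bmax = np.abs(beta).max(axis=1)
    separated = active & (~np.isfinite(bmax) | (bmax > _SEP_COEF))
    status[separated] = STATUS_INSUFFICIENT
    not_conv = active & ~converged & ~separated
    status[not_conv] = STATUS_NOT_CONVERGED

    ok = status == STATUS_OK
    b_out = np.full(B, np.nan)
    se_out = np.full(B, np.nan)
    if ok.any():
        eta = np.einsum("bnp,bp->bn", X[ok], beta[ok], optimize=True)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None) * fmask[ok]
        H = np.einsum("bni,bn,bnj->bij", X[ok], w, X[ok], optimize=True)
        cov = np.linalg.inv(H)
        b_out[ok] = beta[ok, test_index]
        se_out[ok] = np.sqrt(cov[:, test_index, test_index])
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = (b_out / se_out) ** 2
    pval = chi2.sf(stat, df=1)
    return b_out, se_out, stat, pval, n_used.astype(int), status


def _interaction_batch(dosage_a: np.ndarray, dosage_b: np.ndarray,
                       phenotype: np.ndarray):
    """Build pairwise-complete interaction designs for stacked dosage rows.

    ``dosage_a``/``dosage_b`` are (B, n) int arrays with -1 for missing.
    """
    B, n = dosage_a.shape
    mask = (dosage_a >= 0) & (dosage_b >= 0) & (phenotype[None, :] >= 0)
    a = np.where(dosage_a >= 0, dosage_a, 0).astype(np.float64)
    b = np.where(dosage_b >= 0, dosage_b, 0).astype(np.float64)
    X = np.empty((B, n, 4))
    X[:, :, 0] = 1.0
    X[:, :, 1] = a
    X[:, :, 2] = b
    X[:, :, 3] = a * b
    y = (phenotype == 1).astype(np.float64)
    return X, y, mask


def interaction_test(dosage_a: np.ndarray, dosage_b: np.ndarray,
                     phenotype: np.ndarray, snp_a_id: str = "A",
                     snp_b_id: str = "B") -> InteractionResult:
    """Test one SNP pair for allelic interaction.

    Returns an :class:`InteractionResult`; non-estimable configurations are
    reported through ``status`` (collinear / not_converged /
    insufficient_data) with numeric fields set to None.
    """
    da = np.asarray(dosage_a, dtype=np.int8)[None, :]
    db = np.asarray(dosage_b, dtype=np.int8)[None, :]
    ph = np.asarray(phenotype, dtype=np.int8)
    X, y, mask = _interaction_batch(da, db, ph)
    b, se, stat, p, n_used, status = batch_logistic_wald(X, y, mask, test_index=3)
    return _make_result(snp_a_id, snp_b_id, b[0], se[0], stat[0], p[0],
                        int(n_used[0]), status[0])


def _make_result(aid, bid, b, se, stat, p, n_used, status) -> InteractionResult:
    if status == STATUS_OK:
        return InteractionResult(aid, bid, float(b), float(se), float(stat),
                                 float(p), float(np.exp(b)), n_used, status)
    return InteractionResult(aid, bid, None, None, None, None, None,
                             n_used, status)


# ---------------------------------------------------------------------------
# scan planning
# ---------------------------------------------------------------------------

@dataclass
class ScanPlan:
    """Partition of markers into labelled sets plus the reporting gate.

    ``sets`` maps a label to the marker column indices it contains; the scan
    runs a within-set task for every set and a between-sets task for every
    unordered pair of sets, so each unordered marker pair is tested exactly
    once.
    """

    sets: dict[str, np.ndarray]
    report_threshold: float = 1.0e-4
    set_order: list[str] = field(default=None)

    def __post_init__(self):
        if self.set_order is None:
            self.set_order = list(self.sets)
        seen: set[int] = set()
        for label in self.set_order:
            idx = np.asarray(self.sets[label], dtype=np.int64)
            if idx.size == 0:
                raise ValueError(f"scan set {label!r} is empty")
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ValueError(f"marker index {overlap.pop()} in two sets")
            seen.update(idx.tolist())
            self.sets[label] = idx

    @classmethod
    def by_chromosome(cls, dataset: GenotypeDataset,
                      report_threshold: float = 1.0e-4) -> "ScanPlan":
        """One set per chromosome, ordered 1..22, X, Y, XY, MT."""
        chroms = dataset.snps["chromosome"].astype(str)
        labels = sorted(chroms.unique(), key=chrom_sort_key)
        sets = {c: np.flatnonzero((chroms == c).to_numpy()) for c in labels}
        return cls(sets=sets, report_threshold=report_threshold,
                   set_order=labels)

    @classmethod
    def single_set(cls, dataset: GenotypeDataset,
                   report_threshold: float = 1.0e-4) -> "ScanPlan":
        return cls(sets={"ALL": np.arange(dataset.n_snps)},
                   report_threshold=report_threshold, set_order=["ALL"])

    def tasks(self) -> list[tuple[str, str, str]]:
        """Deterministic (label_a, label_b, mode) task list."""
        out = []
        for i, la in enumerate(self.set_order):
            out.append((la, la, "within_set"))
            for lb in self.set_order[i + 1:]:
                out.append((la, lb, "between_sets"))
        return out


def _task_pair_indices(plan: ScanPlan, task) -> tuple[np.ndarray, np.ndarray]:
    la, lb, mode = task
    ia = plan.sets[la]
    if mode == "within_set":
        k = len(ia)
        iu, ju = np.triu_indices(k, k=1)
        return ia[iu], ia[ju]
    ib = plan.sets[lb]
    gi, gj = np.meshgrid(ia, ib, indexing="ij")
    return gi.ravel(), gj.ravel()


def scan_task(dataset: GenotypeDataset, plan: ScanPlan,
              task: tuple[str, str, str],
              chunk_size: int = 2048) -> list[InteractionResult]:
    """Run one (set-pair, mode) task; returns the gated result list."""
    idx_a, idx_b = _task_pair_indices(plan, task)
    snp_ids = dataset.snp_ids
    ph = dataset.phenotype
    out: list[InteractionResult] = []
    for start in range(0, len(idx_a), chunk_size):
        ia = idx_a[start:start + chunk_size]
        ib = idx_b[start:start + chunk_size]
        da = dataset.dosage[:, ia].T
        db = dataset.dosage[:, ib].T
        X, y, mask = _interaction_batch(da, db, ph)
        b, se, stat, p, n_used, status = batch_logistic_wald(
            X, y, mask, test_index=3)
        for k in range(len(ia)):
            if status[k] == STATUS_OK and not (p[k] < plan.report_threshold):
                continue
            out.append(_make_result(
                str(snp_ids[ia[k]]), str(snp_ids[ib[k]]), b[k], se[k],
                stat[k], p[k], int(n_used[k]), status[k]))
    return out


def pairwise_scan(dataset: GenotypeDataset, plan: ScanPlan | None = None,
                  chunk_size: int = 2048) -> Iterator[InteractionResult]:
    """Exhaustive pairwise interaction scan over the plan's partition.

    Yields results in deterministic (task, pair) order.  Only pairs with
    ``p_interaction < plan.report_threshold`` are emitted, plus every pair
    with a non-ok status (flagged, so failures are never silent).
    """
    if plan is None:
        plan = ScanPlan.by_chromosome(dataset)
    for task in plan.tasks():
        yield from scan_task(dataset, plan, task, chunk_size=chunk_size)


# ---------------------------------------------------------------------------
# ranking and arithmetic helpers
# ---------------------------------------------------------------------------

def _rank_key(r: InteractionResult):
    return (r.p_interaction, r.snp_a_id, r.snp_b_id)


def top_k(results: Iterable[InteractionResult], k: int) -> list[InteractionResult]:
    """The k status-ok results with smallest interaction p-value.

    Ties break on (p, snp_a_id, snp_b_id) lexicographically so the ranking
    is deterministic across platforms; if fewer than k ok results exist,
    all are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ok = (r for r in results if r.status == STATUS_OK)
    return heapq.nsmallest(k, ok, key=_rank_key)


def count_tests(n_snps: int) -> int:
    """Number of unordered SNP pairs, n(n-1)/2, in exact integer arithmetic."""
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    return n_snps * (n_snps - 1) // 2


def genome_wide_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance level alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0,1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def results_to_rows(results: Iterable[InteractionResult],
                    chrom_of: dict[str, str] | None = None) -> list[dict]:
    """Flatten results for TSV export (CHR1 SNP1 CHR2 SNP2 N BETA_INT ...)."""
    rows = []
    for r in results:
        rows.append({
            "CHR1": (chrom_of or {}).get(r.snp_a_id, "."),
            "SNP1": r.snp_a_id,
            "CHR2": (chrom_of or {}).get(r.snp_b_id, "."),
            "SNP2": r.snp_b_id,
            "N": r.n_used,
            "BETA_INT": r.beta3,
            "SE": r.se_beta3,
            "OR_INT": r.or_interaction,
            "STAT": r.stat,
            "P": r.p_interaction,
            "STATUS": r.status,
        })
    return rows
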