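"""Effect-size reporting: two-locus genotype odds-ratio grids and
single-locus association tests.

The 3x3 odds-ratio grid compares every two-locus genotype combination with
the double homozygote of the major alleles (minor-allele dosage (0, 0)),
whose odds ratio is 1 by construction.  Confidence intervals are Woolf
(log-normal) intervals, exp(ln OR +- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d));
cells where any of the four counts is zero are flagged undefined unless
the Haldane-Anscombe 0.5 correction is explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import warnings

from .scan import (
    STATUS_OK, batch_logistic_wald,
)

_Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass
class ORCell:
    genotype_a: int
    genotype_b: int
    n_cases: int
    n_controls: int
    odds_ratio: Optional[float]
    ci95: Optional[tuple[float, float]]

    @property
    def defined(self) -> bool:
        return self.odds_ratio is not None


def genotype_or_table(dosage_a: np.ndarray, dosage_b: np.ndarray,
                      phenotype: np.ndarray,
                      haldane: bool = False) -> list[list[ORCell]]:
    """3x3 grid of odds ratios relative to the (0, 0) dosage baseline.

    ``grid[i][j]`` holds the cell with dosage_a = i, dosage_b = j.  With
    ``haldane=True`` a 0.5 continuity correction is added to all four
    counts of a comparison whenever any of them is zero.
    """
    da = np.asarray(dosage_a)
    db = np.asarray(dosage_b)
    ph = np.asarray(phenotype)
    use = (da >= 0) & (db >= 0) & (ph >= 0)
    da, db, ph = da[use], db[use], ph[use]

    cases = np.zeros((3, 3), dtype=int)
    ctrls = np.zeros((3, 3), dtype=int)
    for i in range(3):
        for j in range(3):
            cell = (da == i) & (db == j)
            cases[i, j] = int((cell & (ph == 1)).sum())
            ctrls[i, j] = int((cell & (ph == 0)).sum())

    base_ca, base_co = cases[0, 0], ctrls[0, 0]
    if base_ca == 0 or base_co == 0:
        warnings.warn("empty baseline cell: odds ratios undefined")

    grid: list[list[ORCell]] = []
    for i in range(3):
        row = []
        for j in range(3):
            ca, co = cases[i, j], ctrls[i, j]
            if (i, j) == (0, 0):
                orr: Optional[float] = 1.0 if (ca > 0 and co > 0) else None
                ci = (1.0, 1.0) if orr else None
            else:
                counts = np.array([ca, co, base_ca, base_co], dtype=float)
                if (counts == 0).any():
                    if haldane:
                        counts = counts + 0.5
                    else:
                        row.append(ORCell(i, j, ca, co, None, None))
                        continue
                a, b, c, d = counts
                orr = (a * d) / (b * c)
                se = np.sqrt((1 / counts).sum())
                ci = (float(np.exp(np.log(orr) - _Z95 * se)),
                      float(np.exp(np.log(orr) + _Z95 * se)))
                orr = float(orr)
            row.append(ORCell(i, j, ca, co, orr, ci))
        grid.append(row)
    return grid


def or_table_frame(grid: list[list[ORCell]]) -> pd.DataFrame:
    rows = []
    for row in grid:
        for c in row:
            rows.append({
                "GENO_A": c.genotype_a, "GENO_B": c.genotype_b,
                "N_CASE": c.n_cases, "N_CTRL": c.n_controls,
                "OR": c.odds_ratio if c.defined else np.nan,
                "CI_L": c.ci95[0] if c.defined else np.nan,
                "CI_U": c.ci95[1] if c.defined else np.nan,
                "FLAG": "ok" if c.defined else "undefined",
            })
    return pd.DataFrame(rows)


@dataclass
class SingleLocusResult:
    beta: Optional[float]
    se: Optional[float]
    odds_ratio: Optional[float]
    p_value: Optional[float]
    n_used: int
    status: str


def single_locus_test(dosage: np.ndarray, phenotype: np.ndarray
                      ) -> SingleLocusResult:
    """Logistic regression of case status on allele dosage; Wald p.

    Monomorphic or separated inputs are flagged through ``status`` rather
    than returning numbers.
    """
    d = np.asarray(dosage)
    ph = np.asarray(phenotype)
    mask = (d >= 0) & (ph >= 0)
    X = np.empty((1, len(d), 2))
    X[0, :, 0] = 1.0
    X[0, :, 1] = np.where(d >= 0, d, 0)
    y = (ph == 1).astype(float)
    b, se, stat, p, n_used, status = batch_logistic_wald(
        X, y, mask[None, :], test_index=1)
    if status[0] != STATUS_OK:
        return SingleLocusResult(None, None, None, None, int(n_used[0]),
                                 status[0])
    return SingleLocusResult(float(b[0]), float(se[0]),
                             float(np.exp(b[0])), float(p[0]),
                             int(n_used[0]), STATUS_OK)
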