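"""Core containers: marker map, genotype dosage matrix, QC thresholds/report.

Dosage is stored as ``int8`` with values {0, 1, 2} counting copies of the
A1 allele (by convention the minor allele in controls) and ``-1`` for a
missing genotype.  Phenotype is ``int8`` with 1 = case, 0 = control,
-1 = missing; sex uses the PLINK codes 1 = male, 2 = female, 0 = unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

MISSING = np.int8(-1)
CASE = np.int8(1)
CONTROL = np.int8(0)

#: canonical ordering of chromosome labels for sorting and set partitioning
_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "XY": 25, "MT": 26})

VALID_ALLELES = frozenset("ACGT0")


def chrom_sort_key(label: str) -> tuple[int, str]:
    """Sort key placing 1..22, X, Y, XY, MT in the usual order."""
    return (_CHROM_ORDER.get(str(label), 99), str(label))


class SNPRecord(NamedTuple):
    """One marker: identifier, map position, and allele labels.

    ``allele_a1`` is the counted (dosage) allele; ``allele_a2`` the
    reference allele.  A monomorphic marker may carry the sentinel ``0``
    as ``allele_a1``.
    """

    snp_id: str
    chromosome: str
    position_bp: int
    allele_a1: str
    allele_a2: str


SNP_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele_a1", "allele_a2"]


def snp_frame(records: Iterable[SNPRecord | tuple]) -> pd.DataFrame:
    df = pd.DataFrame(list(records), columns=SNP_COLUMNS)
    df["position_bp"] = df["position_bp"].astype(np.int64)
    return df


@dataclass
class GenotypeDataset:
    """A samples x SNPs dosage matrix with marker map and binary phenotype."""

    snps: pd.DataFrame  # columns SNP_COLUMNS, row order == dosage columns
    sample_ids: np.ndarray  # dtype object/str, length n_samples
    dosage: np.ndarray  # int8 (n_samples, n_snps); -1 missing
    phenotype: np.ndarray  # int8; 1 case, 0 control, -1 missing
    sex: np.ndarray = field(default=None)  # int8; 1 male, 2 female, 0 unknown

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.sex is None:
            self.sex = np.zeros(len(self.sample_ids), dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.snps = self.snps.reset_index(drop=True)
        self.validate()

    # -- basic facts -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    def snp_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snps["snp_id"])}

    def validate(self) -> None:
        n, m = self.dosage.shape
        if n != self.n_samples or m != self.n_snps:
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{self.n_samples} samples x {self.n_snps} snps"
            )
        if len(self.phenotype) != n or len(self.sex) != n:
            raise ValueError("phenotype/sex length mismatch")
        bad = ~np.isin(self.dosage, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2} or -1 (missing)")
        ids = self.snps["snp_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")
        if (ids == "").any():
            raise ValueError("empty snp_id")
        if (self.snps["position_bp"] < 1).any():
            raise ValueError("position_bp must be >= 1")

    # -- accessors -------------------------------------------------------
    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self.snp_index()[snp_id]]

    def snp_record(self, snp_id: str) -> SNPRecord:
        row = self.snps.iloc[self.snp_index()[snp_id]]
        return SNPRecord(
            row.snp_id, str(row.chromosome), int(row.position_bp),
            row.allele_a1, row.allele_a2,
        )

    def is_case(self) -> np.ndarray:
        return self.phenotype == CASE

    def is_control(self) -> np.ndarray:
        return self.phenotype == CONTROL

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        return GenotypeDataset(
            snps=self.snps.copy(),
            sample_ids=self.sample_ids[keep],
            dosage=self.dosage[keep, :],
            phenotype=self.phenotype[keep],
            sex=self.sex[keep],
        )

    def subset_markers(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        return GenotypeDataset(
            snps=self.snps.iloc[keep],
            sample_ids=self.sample_ids.copy(),
            dosage=self.dosage[:, keep],
            phenotype=self.phenotype.copy(),
            sex=self.sex.copy(),
        )

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            snps=self.snps.copy(),
            sample_ids=self.sample_ids.copy(),
            dosage=self.dosage.copy(),
            phenotype=self.phenotype.copy(),
            sex=self.sex.copy(),
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.snps.reset_index(drop=True).equals(other.snps.reset_index(drop=True))
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.dosage, other.dosage)
            and np.array_equal(self.phenotype, other.phenotype)
            and np.array_equal(self.sex, other.sex)
        )


@dataclass(frozen=True)
class QCThresholds:
    """Marker- and sample-level quality-control cut-offs."""

    max_marker_missing_rate: float = 0.03
    min_maf: float = 0.10
    min_hwe_p_controls: float = 5.0e-5
    min_sample_call_rate: float = 0.99

    def __post_init__(self):
        for name in (
            "max_marker_missing_rate", "min_maf",
            "min_hwe_p_controls", "min_sample_call_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class QCReport:
    """Bookkeeping of a QC pass; in = removed + out always holds."""

    n_markers_in: int
    n_markers_removed: int
    n_markers_out: int
    n_samples_in: int
    n_samples_removed: int
    n_samples_out: int
    marker_reasons: dict[str, list[str]] = field(default_factory=dict)
    sample_reasons: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_markers_in - self.n_markers_removed != self.n_markers_out:
            raise ValueError("marker accounting violated")
        if self.n_samples_in - self.n_samples_removed != self.n_samples_out:
            raise ValueError("sample accounting violated")
        for tag, reasons in list(self.marker_reasons.items()) + list(
            self.sample_reasons.items()
        ):
            if not reasons:
                raise ValueError(f"removed item {tag!r} has no reason tag")

    def to_dict(self) -> dict:
        return {
            "n_markers_in": self.n_markers_in,
            "n_markers_removed": self.n_markers_removed,
            "n_markers_out": self.n_markers_out,
            "n_samples_in": self.n_samples_in,
            "n_samples_removed": self.n_samples_removed,
            "n_samples_out": self.n_samples_out,
            "marker_reasons": self.marker_reasons,
            "sample_reasons": self.sample_reasons,
        }
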