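"""Read and write genotype panels in the PLINK PED/MAP and BED/BIM/FAM formats.

Text (PED/MAP) genotypes are pairs of allele characters per marker; the
binary BED format packs four samples per byte with the 2-bit codes

    00 homozygous A1     10 heterozygous
    01 missing           11 homozygous A2

in SNP-major order (one block of ceil(n/4) bytes per marker).  Phenotype
follows the PLINK convention 1 = control, 2 = case, 0/-9 = missing.

At load time the counted allele A1 is re-oriented to the minor allele in
controls (ties broken lexicographically) so that dosage counts minor-allele
copies; pass ``orient_minor=False`` to keep the file's own A1.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CASE, CONTROL, MISSING, SNP_COLUMNS, VALID_ALLELES, GenotypeDataset,
)

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# 2-bit BED code -> dosage of A1 (missing = -1)
_BED_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0, -1: 1, 1: 2, 0: 3}


class PlinkFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_genotypes(path_prefix: str | Path, format: str = "ped_map",
                   orient_minor: bool = True) -> GenotypeDataset:
    """Read ``PREFIX.ped/.map`` or ``PREFIX.bed/.bim/.fam`` into a dataset.

    Parameters
    ----------
    path_prefix
        Filesystem prefix shared by the component files.
    format
        ``"ped_map"`` (text) or ``"bed_bim_fam"`` (binary, SNP-major).
    orient_minor
        Re-orient A1 to the minor allele in controls (the default used by
        every downstream analysis).
    """
    prefix = Path(path_prefix)
    if format == "ped_map":
        ds = _read_ped_map(prefix)
    elif format == "bed_bim_fam":
        ds = _read_bed(prefix)
    else:
        raise ValueError(f"unknown format {format!r}")
    if orient_minor:
        orient_to_minor_allele(ds)
    return ds


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PlinkFormatError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(parts)}"
                )
            chrom, snp_id, _cm, pos = parts
            rows.append((snp_id, chrom, int(pos), "0", "0"))
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def _read_ped_map(prefix: Path) -> GenotypeDataset:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    snps = _read_map(map_path)
    m = len(snps)

    sample_ids, phen, sex = [], [], []
    allele_rows = []  # per sample: 2m allele chars
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields "
                    f"for {m} markers, got {len(parts)}"
                )
            _fid, iid, _pat, _mat, sx, ph = parts[:6]
            alleles = parts[6:]
            for a in alleles:
                if a not in VALID_ALLELES:
                    raise PlinkFormatError(
                        f"{ped_path}: line {lineno}: invalid allele {a!r}"
                    )
            sample_ids.append(iid)
            sex.append(int(sx) if sx in ("1", "2") else 0)
            phen.append(_decode_phenotype(ph, ped_path, lineno))
            allele_rows.append(alleles)

    n = len(sample_ids)
    alleles = np.array(allele_rows, dtype="U1").reshape(n, m, 2) if n else \
        np.empty((0, m, 2), dtype="U1")

    # determine the two allele labels per marker from the data
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    a1s, a2s = [], []
    for j in range(m):
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise PlinkFormatError(
                f"{ped_path}: marker {snps['snp_id'][j]!r} has >2 alleles "
                f"{observed}"
            )
        if len(observed) == 2:
            a1, a2 = observed  # provisional; re-oriented later
        elif len(observed) == 1:
            a1, a2 = "0", observed[0]  # monomorphic: sentinel as counted allele
        else:
            a1, a2 = "0", "0"
        a1s.append(a1)
        a2s.append(a2)
        miss = (col == "0").any(axis=1)
        dosage[:, j] = np.where(miss, MISSING, (col == a1).sum(axis=1))
    snps["allele_a1"] = a1s
    snps["allele_a2"] = a2s

    return GenotypeDataset(
        snps=snps,
        sample_ids=np.array(sample_ids, dtype=object),
        dosage=dosage,
        phenotype=np.array(phen, dtype=np.int8),
        sex=np.array(sex, dtype=np.int8),
    )


def _decode_phenotype(code: str, path, lineno) -> int:
    if code == "2":
        return int(CASE)
    if code == "1":
        return int(CONTROL)
    if code in ("0", "-9"):
        return int(MISSING)
    raise PlinkFormatError(f"{path}: line {lineno}: bad phenotype code {code!r}")


def _read_bim(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise PlinkFormatError(
                    f"{path}: line {lineno}: expected 6 fields, got {len(parts)}"
                )
            chrom, snp_id, _cm, pos, a1, a2 = parts
            rows.append((snp_id, chrom, int(pos), a1, a2))
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def _read_fam(path: Path):
    sample_ids, phen, sex = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise PlinkFormatError(
                    f"{path}: line {lineno}: expected 6 fields, got {len(parts)}"
                )
            _fid, iid, _pat, _mat, sx, ph = parts
            sample_ids.append(iid)
            sex.append(int(sx) if sx in ("1", "2") else 0)
            phen.append(_decode_phenotype(ph, path, lineno))
    return (
        np.array(sample_ids, dtype=object),
        np.array(phen, dtype=np.int8),
        np.array(sex, dtype=np.int8),
    )


def _read_bed(prefix: Path) -> GenotypeDataset:
    snps = _read_bim(prefix.with_suffix(".bim"))
    sample_ids, phen, sex = _read_fam(prefix.with_suffix(".fam"))
    n, m = len(sample_ids), len(snps)
    bed_path = prefix.with_suffix(".bed")
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:2].tobytes() != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic number")
    if raw[2:3].tobytes() != _BED_SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: not in SNP-major mode")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed_path}: expected {bytes_per_snp * m} data bytes for "
            f"{n} samples x {m} markers, found {len(body)}"
        )
    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, sample s sits in byte s//4 at bit offset 2*(s%4)
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    dosage = _BED_CODE_TO_DOSAGE[codes].T.copy()  # (n, m)
    return GenotypeDataset(snps=snps, sample_ids=sample_ids,
                           dosage=dosage, phenotype=phen, sex=sex)


# ---------------------------------------------------------------------------
# allele orientation
# ---------------------------------------------------------------------------

def orient_to_minor_allele(ds: GenotypeDataset) -> None:
    """Flip markers in place so A1 is the minor allele in controls.

    Allele counts are taken among controls (all samples if there are no
    controls); frequency ties break to the lexicographically smaller label.
    Markers with a sentinel allele are left alone.
    """
    ctrl = ds.phenotype == CONTROL
    rows = ctrl if ctrl.any() else np.ones(ds.n_samples, dtype=bool)
    d = ds.dosage[rows, :]
    ok = d >= 0
    a1_count = np.where(ok, d, 0).sum(axis=0).astype(float)
    total = 2.0 * ok.sum(axis=0)
    a1 = ds.snps["allele_a1"].to_numpy().copy()
    a2 = ds.snps["allele_a2"].to_numpy().copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, a1_count / np.maximum(total, 1), np.nan)
    for j in range(ds.n_snps):
        if a1[j] == "0" or a2[j] == "0":
            continue
        f = freq[j]
        flip = False
        if np.isnan(f):
            flip = a2[j] < a1[j]
        elif f > 0.5:
            flip = True
        elif f == 0.5:
            flip = a2[j] < a1[j]
        if flip:
            col = ds.dosage[:, j]
            ds.dosage[:, j] = np.where(col >= 0, 2 - col, MISSING)
            a1[j], a2[j] = a2[j], a1[j]
    ds.snps["allele_a1"] = a1
    ds.snps["allele_a2"] = a2


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_genotypes(dataset: GenotypeDataset, path_prefix: str | Path,
                    format: str = "ped_map") -> list[Path]:
    """Write the dataset; output is readable by :func:`read_genotypes`.

    Text output is canonical: single-space separated, FID = IID, genotypes
    rendered as ``a1 a1`` / ``a1 a2`` / ``a2 a2`` / ``0 0``, so writing a
    dataset read from a canonical file reproduces it byte for byte.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    dataset.validate()
    if format == "ped_map":
        return _write_ped_map(dataset, prefix)
    if format == "bed_bim_fam":
        return _write_bed(dataset, prefix)
    raise ValueError(f"unknown format {format!r}")


def _phenotype_code(v: int) -> str:
    return {1: "2", 0: "1"}.get(int(v), "0")


def _write_map(ds: GenotypeDataset, path: Path) -> None:
    with open(path, "w") as fh:
        for row in ds.snps.itertuples(index=False):
            fh.write(f"{row.chromosome} {row.snp_id} 0 {row.position_bp}\n")


def _write_ped_map(ds: GenotypeDataset, prefix: Path) -> list[Path]:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    _write_map(ds, map_path)
    a1 = ds.snps["allele_a1"].to_numpy()
    a2 = ds.snps["allele_a2"].to_numpy()
    geno_strings = [
        [f"{x2} {x2}", f"{x1} {x2}", f"{x1} {x1}", "0 0"]
        for x1, x2 in zip(a1, a2)
    ]
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(ds.sample_ids):
            fields = [str(sid), str(sid), "0", "0", str(int(ds.sex[i])),
                      _phenotype_code(ds.phenotype[i])]
            row = ds.dosage[i]
            fields.extend(
                geno_strings[j][row[j] if row[j] >= 0 else 3]
                for j in range(ds.n_snps)
            )
            fh.write(" ".join(fields) + "\n")
    return [ped_path, map_path]


def _write_bed(ds: GenotypeDataset, prefix: Path) -> list[Path]:
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    bed_path = prefix.with_suffix(".bed")
    with open(bim_path, "w") as fh:
        for row in ds.snps.itertuples(index=False):
            fh.write(
                f"{row.chromosome} {row.snp_id} 0 {row.position_bp} "
                f"{row.allele_a1} {row.allele_a2}\n"
            )
    with open(fam_path, "w") as fh:
        for i, sid in enumerate(ds.sample_ids):
            fh.write(
                f"{sid} {sid} 0 0 {int(ds.sex[i])} "
                f"{_phenotype_code(ds.phenotype[i])}\n"
            )
    n, m = ds.n_samples, ds.n_snps
    bytes_per_snp = (n + 3) // 4
    code = np.empty(ds.dosage.shape, dtype=np.uint8)
    for dos, c in _DOSAGE_TO_BED_CODE.items():
        code[ds.dosage == dos] = c
    # trailing pad bits in the last byte are zero by convention
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = code.T
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (padded.reshape(m, bytes_per_snp, 4) << shifts).sum(
        axis=2, dtype=np.uint16
    ).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())
    return [bed_path, bim_path, fam_path]
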