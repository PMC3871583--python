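"""Group candidate SNP pairs into interaction regions and annotate them.

Two pairs are linked when, after orienting each pair so its lower
(chromosome, position) endpoint comes first, both A-endpoints are within a
window (default 100 kb) on the same chromosome and likewise both
B-endpoints.  Clusters are the connected components of that relation; each
cluster reports its region bounds, member count ("suggestive interaction
number"), and best pair by combined p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import SNPRecord, chrom_sort_key
from .staged import StagedCandidate


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive coordinates."""

    genes: pd.DataFrame  # columns: name, chromosome, start_bp, end_bp, strand

    def __post_init__(self):
        g = self.genes
        if (g["start_bp"] > g["end_bp"]).any():
            raise ValueError("gene interval with start_bp > end_bp")
        g["chromosome"] = g["chromosome"].astype(str)

    @classmethod
    def from_bed(cls, path) -> "GeneAnnotation":
        """Load from BED (0-based half-open; converted to 1-based inclusive)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        out = pd.DataFrame({
            "name": df[3] if df.shape[1] > 3 else [
                f"feature_{i}" for i in range(len(df))],
            "chromosome": df[0].astype(str).str.replace("^chr", "", regex=True),
            "start_bp": df[1].astype(int) + 1,
            "end_bp": df[2].astype(int),
            "strand": df[5] if df.shape[1] > 5 else "+",
        })
        return cls(out)

    @classmethod
    def from_gff3(cls, path, feature_type: str = "gene") -> "GeneAnnotation":
        """Load gene features from GFF3 (already 1-based inclusive)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["seqid", "source", "type", "start", "end",
                                "score", "strand", "phase", "attributes"])
        df = df[df["type"] == feature_type]

        def name_of(attrs: str) -> str:
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            return fields.get("Name", fields.get("gene_name",
                                                 fields.get("ID", ".")))

        out = pd.DataFrame({
            "name": df["attributes"].map(name_of),
            "chromosome": df["seqid"].astype(str).str.replace(
                "^chr", "", regex=True),
            "start_bp": df["start"].astype(int),
            "end_bp": df["end"].astype(int),
            "strand": df["strand"],
        })
        return cls(out.reset_index(drop=True))


@dataclass
class InteractionCluster:
    members: list[StagedCandidate]
    region_a: tuple[str, int, int]  # (chromosome, min_bp, max_bp)
    region_b: tuple[str, int, int]
    best_pair: StagedCandidate

    @property
    def n_suggestive(self) -> int:
        return len(self.members)


def _orient(cand: StagedCandidate, snp_map: dict[str, tuple[str, int]]):
    """Canonical endpoint order: lower (chromosome, position) first."""
    a, b = cand.pair
    for s in (a, b):
        if s not in snp_map:
            raise KeyError(f"unknown SNP id {s!r} in candidate pair")
    ka = (chrom_sort_key(snp_map[a][0]), snp_map[a][1])
    kb = (chrom_sort_key(snp_map[b][0]), snp_map[b][1])
    return (a, b) if ka <= kb else (b, a)


def cluster_pairs(candidates: Sequence[StagedCandidate],
                  snp_map: dict[str, tuple[str, int]],
                  window_bp: int = 100_000) -> list[InteractionCluster]:
    """Connected-component clustering of pairs under the dual-endpoint window.

    ``snp_map`` maps snp_id -> (chromosome, position_bp).  Output clusters
    are sorted by their best pair's combined p (None last), and the result
    is invariant to input order and within-pair endpoint order.
    """
    n = len(candidates)
    oriented = [_orient(c, snp_map) for c in candidates]
    ends = [
        (snp_map[a], snp_map[b]) for a, b in oriented
    ]

    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        (ca1, pa1), (cb1, pb1) = ends[i]
        for j in range(i + 1, n):
            (ca2, pa2), (cb2, pb2) = ends[j]
            if (ca1 == ca2 and cb1 == cb2
                    and abs(pa1 - pa2) <= window_bp
                    and abs(pb1 - pb2) <= window_bp):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    def sort_key(c: StagedCandidate):
        return (c.p_combined is None, c.p_combined, c.pair)

    clusters = []
    for idx in groups.values():
        members = [candidates[i] for i in idx]
        pa = [ends[i][0] for i in idx]
        pb = [ends[i][1] for i in idx]
        region_a = (pa[0][0], min(p for _, p in pa), max(p for _, p in pa))
        region_b = (pb[0][0], min(p for _, p in pb), max(p for _, p in pb))
        best = min(members, key=sort_key)
        clusters.append(InteractionCluster(
            members=sorted(members, key=sort_key),
            region_a=region_a, region_b=region_b, best_pair=best))
    clusters.sort(key=lambda cl: sort_key(cl.best_pair))
    return clusters


def nearest_gene(snp: SNPRecord, annotation: GeneAnnotation
                 ) -> Optional[tuple[str, int, str]]:
    """Nearest gene to a SNP: (name, distance_bp, relation).

    Distance is 0 with relation ``within`` when the position lies inside a
    gene interval; otherwise the minimal gap to the closest interval end on
    that chromosome, with ``upstream``/``downstream`` taken relative to the
    gene's strand.  Ties break toward the smaller start coordinate.
    Returns None when the chromosome has no annotated gene.
    """
    g = annotation.genes
    on_chrom = g[g["chromosome"] == str(snp.chromosome)]
    if on_chrom.empty:
        return None
    pos = snp.position_bp
    best = None
    for row in on_chrom.sort_values(["start_bp", "end_bp", "name"]).itertuples():
        if row.start_bp <= pos <= row.end_bp:
            dist, side = 0, "within"
        elif pos < row.start_bp:
            dist = row.start_bp - pos
            side = "upstream" if row.strand != "-" else "downstream"
        else:
            dist = pos - row.end_bp
            side = "downstream" if row.strand != "-" else "upstream"
        if best is None or dist < best[1]:
            best = (row.name, dist, side)
    return best


_TABLE_COLUMNS = [
    "REGION_A", "REGION_B", "SNP1", "SNP2", "GENE_A", "DIST_A",
    "GENE_B", "DIST_B", "P_STAGE1", "P_STAGE2", "P_COMBINED", "N_SUGGESTIVE",
]


def _sci(p: Optional[float]) -> str:
    return "." if p is None else f"{p:.2E}"


def region_table(clusters: Sequence[InteractionCluster],
                 annotation: GeneAnnotation | None = None,
                 snp_records: dict[str, SNPRecord] | None = None
                 ) -> pd.DataFrame:
    """One row per cluster: best pair, nearest genes, stagewise p-values.

    The column schema is fixed whether or not annotation is available;
    p-values are rendered in 2-decimal scientific notation (e.g. 9.86E-11).
    """
    if not clusters:
        raise ValueError("no clusters to tabulate")
    rows = []
    for cl in clusters:
        best = cl.best_pair
        genes = {"A": (".", "."), "B": (".", ".")}
        if annotation is not None and snp_records is not None:
            for side, sid in (("A", best.pair[0]), ("B", best.pair[1])):
                rec = snp_records.get(sid)
                hit = nearest_gene(rec, annotation) if rec else None
                if hit:
                    genes[side] = (hit[0], hit[1])
        rows.append({
            "REGION_A": f"{cl.region_a[0]}:{cl.region_a[1]}-{cl.region_a[2]}",
            "REGION_B": f"{cl.region_b[0]}:{cl.region_b[1]}-{cl.region_b[2]}",
            "SNP1": best.pair[0], "SNP2": best.pair[1],
            "GENE_A": genes["A"][0], "DIST_A": genes["A"][1],
            "GENE_B": genes["B"][0], "DIST_B": genes["B"][1],
            "P_STAGE1": _sci(best.p_stage1),
            "P_STAGE2": _sci(best.p_stage2),
            "P_COMBINED": _sci(best.p_combined),
            "N_SUGGESTIVE": cl.n_suggestive,
        })
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
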