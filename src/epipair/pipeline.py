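"""End-to-end two-stage workflow: QC -> scan -> top-K -> replicate ->
combine -> permute -> select -> cluster -> report, with a run manifest and
stage-level resumability.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datatypes import GenotypeDataset, QCThresholds
from .io_plink import read_genotypes
from .qc import apply_qc
from .scan import (
    STATUS_OK, InteractionResult, ScanPlan, results_to_rows, scan_task, top_k,
)
from .staged import (
    SelectionThresholds, StagedCandidate, combine_datasets, filter_candidates,
    permutation_test, replicate_pairs, candidates_to_frame,
)
from .clustering import GeneAnnotation, cluster_pairs, region_table

log = logging.getLogger("epipair")


@dataclass
class PipelineConfig:
    """Thresholds, inputs and seed for one end-to-end run."""

    in1_prefix: str
    in2_prefix: str
    out_dir: str
    in1_format: str = "ped_map"
    in2_format: str = "ped_map"
    report_threshold: float = 1.0e-4
    top_k: int = 10_000
    stage2_p: float = 0.01
    combined_p: float = 5.0e-7
    perm_m: int = 10_000
    perm_p: float = 0.01
    cluster_window_bp: int = 100_000
    seed: int = 0
    workers: int = 1
    qc: QCThresholds = field(default_factory=QCThresholds)
    annotation_bed: Optional[str] = None

    def __post_init__(self):
        for name in ("report_threshold", "stage2_p", "combined_p", "perm_p"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0,1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def scan_parallel(dataset: GenotypeDataset, plan: ScanPlan,
                  workers: int = 1) -> list[InteractionResult]:
    """Run all scan tasks, optionally in parallel, with deterministic merge.

    Results are concatenated in plan task order regardless of worker
    scheduling, so output is identical for any worker count.
    """
    tasks = plan.tasks()
    if workers <= 1:
        chunks = [scan_task(dataset, plan, t) for t in tasks]
    else:
        chunks = Parallel(n_jobs=workers)(
            delayed(scan_task)(dataset, plan, t) for t in tasks)
    return [r for chunk in chunks for r in chunk]


class PipelineRun:
    """Stage-by-stage execution with a manifest for resumability."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = self._load_manifest()

    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                manifest = json.load(fh)
            if manifest.get("config_digest") != self.config.digest():
                raise RuntimeError(
                    "manifest in output directory was produced by a "
                    "different configuration; refusing to resume")
            return manifest
        return {"config_digest": self.config.digest(),
                "seed": self.config.seed, "stages": {}}

    def _save_manifest(self) -> None:
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2)

    def _stage_done(self, name: str, outputs: list[Path]) -> bool:
        return (name in self.manifest["stages"]
                and all(p.exists() for p in outputs))

    def _mark_done(self, name: str, t0: float, **info) -> None:
        self.manifest["stages"][name] = {
            "seconds": round(time.time() - t0, 3), **info}
        self._save_manifest()
        log.info("stage %s done (%.1fs) %s", name,
                 time.time() - t0, info)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns paths of the produced tables."""
    run = PipelineRun(config)
    out = run.out

    candidate_path = out / "candidates.tsv"
    cluster_path = out / "clusters.tsv"
    scan_path = out / "scan_stage1.tsv.gz"
    top_path = out / "top_pairs.tsv"

    # --- load + QC ------------------------------------------------------
    d1, rep1 = apply_qc(read_genotypes(config.in1_prefix, config.in1_format),
                        config.qc)
    d2, rep2 = apply_qc(read_genotypes(config.in2_prefix, config.in2_format),
                        config.qc)
    (out / "qc_stage1.json").write_text(json.dumps(rep1.to_dict()))
    (out / "qc_stage2.json").write_text(json.dumps(rep2.to_dict()))

    chrom_of = dict(zip(d1.snps["snp_id"], d1.snps["chromosome"].astype(str)))

    # --- stage-1 scan ---------------------------------------------------
    if not run._stage_done("scan", [scan_path]):
        t0 = time.time()
        plan = ScanPlan.by_chromosome(d1, config.report_threshold)
        results = scan_parallel(d1, plan, config.workers)
        pd.DataFrame(results_to_rows(results, chrom_of)).to_csv(
            scan_path, sep="\t", index=False)
        run._mark_done("scan", t0, pairs_emitted=len(results))

    scan_df = pd.read_csv(scan_path, sep="\t")
    ok_df = scan_df[scan_df["STATUS"] == STATUS_OK]

    # --- top-K ----------------------------------------------------------
    if not run._stage_done("top", [top_path]):
        t0 = time.time()
        ranked = ok_df.sort_values(["P", "SNP1", "SNP2"]).head(config.top_k)
        ranked.to_csv(top_path, sep="\t", index=False)
        run._mark_done("top", t0, k=len(ranked))
    top_df = pd.read_csv(top_path, sep="\t")
    pairs = list(zip(top_df["SNP1"], top_df["SNP2"]))
    p1 = dict(zip(pairs, top_df["P"]))

    # --- replication, combined, permutations ---------------------------
    if not run._stage_done("candidates", [candidate_path]):
        t0 = time.time()
        replicated = replicate_pairs(pairs, d2, reference_snps=d1.snps)
        testable = [p for p, r in replicated if r is not None]
        p2 = {p: (r.p_interaction if r.status == STATUS_OK else None)
              for p, r in replicated if r is not None}

        dc = combine_datasets(d1, d2)
        from .staged import test_pairs
        in_dc = set(dc.snps["snp_id"])
        testable_c = [p for p in testable if p[0] in in_dc and p[1] in in_dc]
        pc = {(r.snp_a_id, r.snp_b_id):
              (r.p_interaction if r.status == STATUS_OK else None)
              for r in test_pairs(dc, testable_c)}

        # permutation p-values only for pairs still alive after the
        # stage-2 and combined thresholds (the expensive step)
        alive = [p for p in testable_c
                 if p2.get(p) is not None and p2[p] < config.stage2_p
                 and pc.get(p) is not None and pc[p] < config.combined_p]
        perm1 = permutation_test(d1, alive, config.perm_m, config.seed)
        perm2 = permutation_test(d2, alive, config.perm_m, config.seed + 1)
        permc = permutation_test(dc, alive, config.perm_m, config.seed + 2)

        candidates = []
        for p in pairs:
            c = StagedCandidate(
                pair=p, p_stage1=p1.get(p), p_stage2=p2.get(p),
                p_combined=pc.get(p),
                testable_in_stage2=p in set(testable))
            if p in set(alive):
                for attr, perms in (("p_perm_stage1", perm1),
                                    ("p_perm_stage2", perm2),
                                    ("p_perm_combined", permc)):
                    s = perms.get(p)
                    setattr(c, attr, s.p_permutation if s else None)
            candidates.append(c)
        thresholds = SelectionThresholds(config.stage2_p, config.combined_p,
                                         config.perm_p)
        filter_candidates(candidates, thresholds)
        candidates_to_frame(candidates).to_csv(candidate_path, sep="\t",
                                               index=False)
        run._mark_done("candidates", t0,
                       untestable=len(pairs) - len(testable),
                       passing=sum(c.passes_filters for c in candidates))

    cand_df = pd.read_csv(candidate_path, sep="\t")

    # --- clustering + region table -------------------------------------
    if not run._stage_done("clusters", [cluster_path]):
        t0 = time.time()
        passing = cand_df[cand_df["PASS"] == True]  # noqa: E712
        if len(passing):
            cands = [
                StagedCandidate(
                    pair=(r.SNP1, r.SNP2), p_stage1=r.P_STAGE1,
                    p_stage2=r.P_STAGE2, p_combined=r.P_COMBINED,
                    testable_in_stage2=True, passes_filters=True)
                for r in passing.itertuples()
            ]
            snp_map = {
                r.snp_id: (str(r.chromosome), int(r.position_bp))
                for r in d1.snps.itertuples(index=False)
            }
            clusters = cluster_pairs(cands, snp_map,
                                     config.cluster_window_bp)
            annotation = (GeneAnnotation.from_bed(config.annotation_bed)
                          if config.annotation_bed else None)
            snp_records = {s: d1.snp_record(s) for c in cands for s in c.pair}
            table = region_table(clusters, annotation, snp_records)
        else:
            table = pd.DataFrame()
        table.to_csv(cluster_path, sep="\t", index=False)
        run._mark_done("clusters", t0, n_clusters=len(table))

    return {
        "scan": str(scan_path), "top": str(top_path),
        "candidates": str(candidate_path), "clusters": str(cluster_path),
        "manifest": str(run.manifest_path),
    }
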