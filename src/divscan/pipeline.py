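"""End-to-end driver: QC -> structure -> FST scan -> iHS/XP-EHH -> regions.

The pipeline takes phased haplotypes (in memory or from a phased VCF plus
a sample-to-line TSV), runs every stage with explicit seeds, and writes
per-SNP tables, per-window tables, region/consensus BEDs and a
machine-readable JSON summary. Reruns with an identical config produce
byte-identical summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .data import HaplotypeMatrix, LineAssignment, SnpMap
from .fst import FstScanConfig, fst_scan, snp_fst_table
from .haplo import HaploScanConfig, ihs_scan, window_flag_haplo, xpehh_scan
from .qc import QcConfig, run_qc
from .regions import (annotate_regions, cross_test_consensus, merge_windows,
                      read_bed, regions_to_bed)
from .structure import classical_mds, ibs_distance_matrix

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    # inputs: either in-memory objects or file paths
    vcf_path: str | None = None
    lines_path: str | None = None
    control_label: str = "NeC"
    selected_labels: list = field(default_factory=list)
    features_bed: str | None = None
    out_dir: str | None = None
    run_qc_stage: bool = True
    qc: QcConfig = field(default_factory=QcConfig)
    fst: FstScanConfig = field(default_factory=FstScanConfig)
    haplo: HaploScanConfig = field(default_factory=HaploScanConfig)
    mds_axes: int = 2


@dataclass
class PipelineResult:
    summary: dict
    snp_map: SnpMap
    qc_report: pd.DataFrame
    mds_coordinates: pd.DataFrame
    fst_tables: dict
    fst_windows: pd.DataFrame
    ihs_scores: pd.DataFrame
    ihs_windows: pd.DataFrame
    xpehh_scores: dict
    xpehh_windows: pd.DataFrame
    regions_by_test: dict
    consensus: list
    annotation: list


def _round6(x):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), 6)


def run_pipeline(cfg: PipelineConfig,
                 H: HaplotypeMatrix | None = None,
                 snp_map: SnpMap | None = None,
                 lines: LineAssignment | None = None) -> PipelineResult:
    """Execute the full scan; see module docstring for the stage order.

    Any stage failure raises with the stage name prepended.
    """
    stage = "input"
    try:
        if H is None:
            H, snp_map, _ = dio.read_phased_vcf(cfg.vcf_path)
            lines = dio.read_line_assignment(cfg.lines_path, cfg.control_label,
                                             cfg.selected_labels)
        lines.check_covers(H.samples)
        if len(lines.selected) < 2:
            raise ValueError("pipeline needs a control line and >= 2 selected lines")
        sel1, sel2 = lines.selected[0], lines.selected[1]

        stage = "qc"
        G = H.to_genotypes()
        if cfg.run_qc_stage:
            G2, map2, report = run_qc(G, snp_map, lines, cfg.qc)
            keep_snps = np.nonzero(np.isin(snp_map.snp_id, map2.snp_id))[0]
            keep_samples = H.sample_index(G2.samples)
            H = H.subset_samples(keep_samples).subset_snps(keep_snps)
            snp_map = map2
            G = G2
            qc_df = report.to_dataframe()
        else:
            qc_df = pd.DataFrame(columns=["id", "type", "reason", "iteration", "flags"])

        stage = "structure"
        D = ibs_distance_matrix(G)
        mds = classical_mds(D, k=cfg.mds_axes)
        mds_df = pd.DataFrame(
            mds.coordinates,
            columns=[f"pco{i + 1}" for i in range(mds.n_axes)])
        mds_df.insert(0, "sample_id", G.samples)
        mds_df["line"] = [lines.mapping[s] for s in G.samples]

        stage = "fst_scan"
        fst_tables, fst_windows = fst_scan(G, snp_map, lines, cfg.fst)
        # genome-wide per-SNP means for every pairwise line comparison
        fst_means = {}
        pairs = [(lines.control, sel1), (lines.control, sel2), (sel1, sel2)]
        for a, b in pairs:
            t = snp_fst_table(G, snp_map, lines, a, b, cfg.fst)
            fst_means[f"{a}_vs_{b}"] = float(np.nanmean(t["theta"].to_numpy()))

        stage = "ihs_scan"
        pooled = [s for s in G.samples if lines.mapping[s] != lines.control]
        H_pooled = H.subset_samples(H.sample_index(pooled))
        ihs = ihs_scan(H_pooled, snp_map, cfg.haplo)
        ihs_w = window_flag_haplo(ihs, snp_map, cfg.haplo, mode="ihs")

        stage = "xpehh_scan"
        H_con = H.subset_samples(H.sample_index(
            [s for s in G.samples if lines.mapping[s] == lines.control]))
        xp = {}
        for sel in (sel1, sel2):
            H_sel = H.subset_samples(H.sample_index(
                [s for s in G.samples if lines.mapping[s] == sel]))
            xp[sel] = xpehh_scan(H_sel, H_con, snp_map, cfg.haplo)
        xp_w = window_flag_haplo(xp[sel1], snp_map, cfg.haplo, mode="xpehh",
                                 scores2=xp[sel2])

        stage = "regions"
        fst_flag = fst_windows.rename(columns={"candidate": "flagged"})
        regions_by_test = {
            "FST": merge_windows(fst_flag, "FST"),
            "XPEHH": merge_windows(xp_w, "XPEHH"),
            "IHS": merge_windows(ihs_w, "IHS"),
        }
        consensus = cross_test_consensus(regions_by_test)

        stage = "annotation"
        annotation = []
        if cfg.features_bed:
            feats = read_bed(cfg.features_bed)
            annotation = annotate_regions(consensus, feats)

        stage = "summary"
        summary = {
            "n_samples": int(G.n_samples),
            "n_snps_retained": int(len(snp_map)),
            "qc_removed_samples": int((qc_df["type"] == "sample").sum()),
            "qc_removed_snps": int((qc_df["type"] == "snp").sum()),
            "mds_explained_pct": [_round6(100 * e) for e in mds.explained],
            "mean_fst": {k: _round6(v) for k, v in fst_means.items()},
            "n_windows_flagged": {
                "FST": int(fst_windows["candidate"].sum()),
                "XPEHH": int(xp_w["flagged"].sum()),
                "IHS": int(ihs_w["flagged"].sum()),
            },
            "n_windows_eligible": {
                "FST": int((fst_windows["eligible_1"]
                            & fst_windows["eligible_2"]).sum()),
                "XPEHH": int(((xp_w["n_snps_1"] >= cfg.haplo.min_snps)
                              & (xp_w["n_snps_2"] >= cfg.haplo.min_snps)).sum()),
                "IHS": int((ihs_w["n_snps"] >= cfg.haplo.min_snps).sum()),
            },
            "n_regions": {t: len(r) for t, r in regions_by_test.items()},
            "n_consensus_regions": len(consensus),
            "consensus_regions": [
                {"chrom": r.chrom, "start": r.start, "end": r.end,
                 "tests": sorted(r.tests)}
                for r in sorted(consensus, key=lambda r: (r.chrom, r.start))
            ],
            "config": {
                "qc": vars(cfg.qc) | {"autosomes": sorted(cfg.qc.autosomes)},
                "fst": vars(cfg.fst),
                "haplo": vars(cfg.haplo),
            },
        }

        result = PipelineResult(
            summary=summary, snp_map=snp_map, qc_report=qc_df,
            mds_coordinates=mds_df, fst_tables=fst_tables,
            fst_windows=fst_windows, ihs_scores=ihs, ihs_windows=ihs_w,
            xpehh_scores=xp, xpehh_windows=xp_w,
            regions_by_test=regions_by_test, consensus=consensus,
            annotation=annotation)
        if cfg.out_dir:
            _write_outputs(cfg, result)
        return result
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e


def _write_outputs(cfg: PipelineConfig, res: PipelineResult) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    res.mds_coordinates.to_csv(out / "mds_coordinates.tsv", sep="\t", index=False)
    for name, t in res.fst_tables.items():
        t.to_csv(out / f"fst_snp_{name}.tsv", sep="\t", index=False)
    res.fst_windows.to_csv(out / "fst_windows.tsv", sep="\t", index=False)
    res.ihs_scores.to_csv(out / "ihs_snp.tsv", sep="\t", index=False)
    res.ihs_windows.to_csv(out / "ihs_windows.tsv", sep="\t", index=False)
    for sel, t in res.xpehh_scores.items():
        t.to_csv(out / f"xpehh_snp_{sel}.tsv", sep="\t", index=False)
    res.xpehh_windows.to_csv(out / "xpehh_windows.tsv", sep="\t", index=False)
    for test, regs in res.regions_by_test.items():
        regions_to_bed(regs, out / f"regions_{test.lower()}.bed")
    regions_to_bed(res.consensus, out / "regions_consensus.bed")
    if res.annotation:
        pd.DataFrame(
            [{"chrom": h.region.chrom, "region_start": h.region.start,
              "region_end": h.region.end, "feature": h.feature,
              "feature_start": h.feature_start, "feature_end": h.feature_end,
              "overlap_bp": h.overlap_bp} for h in res.annotation]
        ).to_csv(out / "annotation.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(res.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_log.txt", "w") as fh:
        fh.write("divscan pipeline run\n")
        fh.write(f"samples: {res.summary['n_samples']}  "
                 f"snps_retained: {res.summary['n_snps_retained']}\n")
        fh.write("stages: qc -> structure -> fst_scan -> ihs_scan -> "
                 "xpehh_scan -> regions -> consensus -> annotation\n")
        for name, c in (("qc", cfg.qc), ("fst", cfg.fst), ("haplo", cfg.haplo)):
            for k, v in sorted(vars(c).items()):
                if k == "autosomes":
                    v = f"{min(v)}..{max(v)}"
                fh.write(f"{name}.{k} = {v}\n")
        fh.write(f"inputs: vcf={cfg.vcf_path} lines={cfg.lines_path} "
                 f"features={cfg.features_bed}\n")
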