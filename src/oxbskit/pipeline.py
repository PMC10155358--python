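"""End-to-end orchestration: simulate/ingest -> estimate -> DMR -> annotate
-> screen -> compare.

Every stage reads its inputs from, and serialises its outputs to, the run
directory, so any stage can be re-run in isolation from the previous
stage's files.  A structured log records per-stage record counts and a
manifest ties the outputs to a hash of the fully-merged configuration.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import biomarker_screen, dmr_calling, hmc_estimation, meth_io, synthetic_cohort
from .config import config_hash, load_config
from .genomic_annotation import GeneModel, annotate_dmrs, category_counts

logger = logging.getLogger("oxbskit.pipeline")

STAGES = ("simulate", "estimate", "dmr", "annotate", "screen", "compare")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunPaths:
    outdir: str

    def __post_init__(self):
        os.makedirs(self.outdir, exist_ok=True)

    def sub(self, name: str) -> str:
        path = os.path.join(self.outdir, name)
        os.makedirs(path, exist_ok=True)
        return path

    @property
    def sample_sheet(self) -> str:
        return os.path.join(self.outdir, "sim", "sample_sheet.csv")

    @property
    def gene_model(self) -> str:
        return os.path.join(self.outdir, "sim", "genes.bed12")

    def paired(self, sample: str) -> str:
        return os.path.join(self.outdir, "paired", f"{sample}.tsv")

    def dmr_bed(self, contrast: str, mark: str) -> str:
        return os.path.join(self.outdir, "dmr", f"{contrast}_{mark}.bed")


def _planted_regions(cfg: Mapping, cpg_map: pd.DataFrame) -> list:
    """Lay out the configured effect regions over the simulated CpG map.

    Effects are planted over whole CpG runs (maximal stretches with
    inter-CpG gaps <= the segmentation max_gap) holding between
    ``region_cpgs`` and 3x that many CpGs — DMR-like effects live in CpG
    clusters.  5mC effects are laid out first, then 5hmC, never sharing a
    run; signs alternate.
    """
    eff = cfg["simulate"]["effects"]
    n_total = eff["n_5mc_regions"] + eff["n_5hmc_regions"]
    if n_total == 0:
        return []
    rc = eff["region_cpgs"]
    max_gap = cfg["segmentation"]["max_gap"]
    slots = []
    for chrom, sub in cpg_map.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        edges = np.concatenate(
            [[0], np.flatnonzero(np.diff(pos) > max_gap) + 1, [len(pos)]]
        )
        for a, b in zip(edges[:-1], edges[1:]):
            if rc <= b - a <= 3 * rc:
                slots.append((chrom, int(pos[a]), int(pos[b - 1]) + 2))
    if len(slots) < n_total:
        raise StageError("simulate", "CpG map too small for requested effect regions")
    pick = np.linspace(0, len(slots) - 1, n_total).astype(int)
    regions = []
    for j, sl in enumerate(pick):
        chrom, start, end = slots[sl]
        if j < eff["n_5mc_regions"]:
            mark, delta = "5mC", eff["delta_5mc"] * (1 if j % 2 == 0 else -1)
        else:
            mark, delta = "5hmC", eff["delta_5hmc"] * (1 if j % 2 == 0 else -1)
        coupling = eff["coupling"] * -np.sign(delta) * abs(delta) if eff["coupling"] else 0.0
        regions.append(
            synthetic_cohort.RegionEffect(chrom, start, end, mark, delta, coupling)
        )
    return regions


def stage_simulate(cfg: Mapping, paths: RunPaths) -> None:
    sim = cfg["simulate"]
    sim_dir = paths.sub("sim")
    cpg_map, gene_model = synthetic_cohort.simulate_reference(
        sim["n_chromosomes"], sim["cpgs_per_chromosome"],
        spacing=sim["spacing"], seed=cfg["seed"],
    )
    regions = _planted_regions(cfg, cpg_map)
    chem = synthetic_cohort.ChemistryParams(**sim["chemistry"])
    truth = synthetic_cohort.make_cohort_truth(
        sim["n_per_group"], cpg_map, regions,
        coverage=synthetic_cohort.CoverageModel(
            sim["coverage_mean"], sim["coverage_dispersion"]
        ),
        chemistry=chem,
        sample_effect_sd=(
            sim["sample_effect_sd"] if sim["per_sample_heterogeneity"] else 0.0
        ),
        seed=cfg["seed"],
    )
    tables = synthetic_cohort.simulate_counts(truth)
    rows = []
    for sample, labelled in zip(truth.sample_ids, truth.group_labels):
        bs_path = os.path.join(sim_dir, f"{sample}_bs.tsv")
        ox_path = os.path.join(sim_dir, f"{sample}_ox.tsv")
        meth_io.write_methratio(tables[sample]["bs"], bs_path)
        meth_io.write_methratio(tables[sample]["ox"], ox_path)
        rows.append(
            {"sample_id": sample, "path_bs": bs_path, "path_ox": ox_path,
             "group": labelled}
        )
    pd.DataFrame(rows).to_csv(paths.sample_sheet, index=False)
    gene_model.to_bed12(paths.gene_model)
    synthetic_cohort.truth_regions_to_bed(
        regions, os.path.join(sim_dir, "truth_regions.bed")
    )
    logger.info("simulate: %d samples, %d CpGs, %d planted regions",
                len(rows), len(cpg_map), len(regions))


def _load_sheet(cfg: Mapping, paths: RunPaths) -> pd.DataFrame:
    sheet_path = (
        paths.sample_sheet if cfg["mode"] == "simulate"
        else cfg["ingest"]["sample_sheet"]
    )
    if not os.path.exists(sheet_path):
        raise StageError("estimate", f"sample sheet not found: {sheet_path}")
    return meth_io.read_sample_sheet(sheet_path)


def stage_estimate(cfg: Mapping, paths: RunPaths) -> None:
    sheet = _load_sheet(cfg, paths)
    paths.sub("paired")
    est = cfg["estimation"]
    n_sites = 0
    for row in sheet.itertuples():
        bs = meth_io.read_methratio(row.path_bs)
        ox = meth_io.read_methratio(row.path_ox)
        paired = hmc_estimation.merge_paired(bs, ox, min_cov=est["min_cov"])
        paired = hmc_estimation.estimate_hmc(paired, mode=est["hmc_mode"])
        hmc_estimation.write_paired_table(paired, paths.paired(row.sample_id))
        n_sites += len(paired)
    logger.info("estimate: %d samples, %d paired sites total", len(sheet), n_sites)


def load_cohort(cfg: Mapping, paths: RunPaths) -> dict[str, pd.DataFrame]:
    sheet = _load_sheet(cfg, paths)
    cohort = {}
    for sample in sheet["sample_id"]:
        p = paths.paired(sample)
        if not os.path.exists(p):
            raise StageError("dmr", f"paired table missing for {sample}: {p}")
        cohort[sample] = hmc_estimation.read_paired_table(p)
    return cohort


def resolve_design(cfg: Mapping, paths: RunPaths) -> meth_io.ContrastDesign:
    sheet = _load_sheet(cfg, paths)
    con = cfg["contrast"]
    if con.get("expression_column"):
        col = con["expression_column"]
        if col not in sheet.columns:
            raise StageError("dmr", f"expression column {col!r} not in sheet")
        expr = dict(zip(sheet["sample_id"], sheet[col]))
        return meth_io.median_split(expr, name=con["name"])
    col = con["group_column"]
    if col not in sheet.columns:
        raise StageError("dmr", f"group column {col!r} not in sample sheet")
    groups = dict(zip(sheet["sample_id"], sheet[col]))
    return meth_io.ContrastDesign(name=con["name"], groups=groups)


def _thresholds(cfg: Mapping) -> dmr_calling.Thresholds:
    th = cfg["thresholds"]
    return dmr_calling.Thresholds(
        diff={"5mC": th["diff_5mc"], "5hmC": th["diff_5hmc"], "BS": th["diff_bs"]},
        q=th["q"],
    )


def _segmentation(cfg: Mapping) -> dmr_calling.SegmentationParams:
    return dmr_calling.SegmentationParams(**cfg["segmentation"])


def stage_dmr(cfg: Mapping, paths: RunPaths) -> None:
    cohort = load_cohort(cfg, paths)
    design = resolve_design(cfg, paths)
    paths.sub("dmr")
    for mark in cfg["marks"]:
        dmrs = dmr_calling.call_dmrs(
            cohort, design, mark,
            thresholds=_thresholds(cfg), seg=_segmentation(cfg),
            hmc_mode=cfg["estimation"]["hmc_mode"] if mark == "5hmC" else "raw",
        )
        sig = dmr_calling.significant_dmrs(dmrs)
        hyper = sum(d.direction == "hyper" for d in sig)
        meth_io.write_dmr_bed(dmrs, paths.dmr_bed(design.name, mark))
        logger.info(
            "dmr[%s/%s]: %d candidates, %d significant (%d hyper / %d hypo)",
            design.name, mark, len(dmrs), len(sig), hyper, len(sig) - hyper,
        )


def _gene_model(cfg: Mapping, paths: RunPaths) -> GeneModel:
    ann = cfg["annotation"]
    path = (
        paths.gene_model if cfg["mode"] == "simulate"
        else cfg["ingest"]["gene_model"]
    )
    kwargs = dict(
        promoter_window=(ann["promoter_upstream"], ann["promoter_downstream"]),
        tts_window=(ann["tts_upstream"], ann["tts_downstream"]),
    )
    if path and os.path.exists(path):
        return GeneModel.from_bed12(path, **kwargs)
    return GeneModel(transcripts=[], **kwargs)


def stage_annotate(cfg: Mapping, paths: RunPaths) -> None:
    design = resolve_design(cfg, paths)
    model = _gene_model(cfg, paths)
    out_dir = paths.sub("annotation")
    for mark in cfg["marks"]:
        bed = paths.dmr_bed(design.name, mark)
        if not os.path.exists(bed):
            raise StageError("annotate", f"missing DMR bed {bed}")
        sig = dmr_calling.significant_dmrs(meth_io.read_dmr_bed(bed))
        cats = annotate_dmrs(sig, model)
        table = category_counts(sig, cats)
        table.to_csv(os.path.join(out_dir, f"{mark}_category_counts.tsv"), sep="\t")
        logger.info("annotate[%s]: %d significant DMRs tabulated", mark, len(sig))


def stage_screen(cfg: Mapping, paths: RunPaths) -> None:
    cohort = load_cohort(cfg, paths)
    design = resolve_design(cfg, paths)
    out_dir = paths.sub("screen")
    scr = cfg["screen"]
    for mark in cfg["marks"]:
        dmrs = meth_io.read_dmr_bed(paths.dmr_bed(design.name, mark))
        evals = biomarker_screen.screen_biomarkers(
            dmr_calling.significant_dmrs(dmrs), cohort, design, mark,
            auc_cutoff=scr["auc_cutoff"], min_sample_frac=scr["min_sample_frac"],
        )
        frame = biomarker_screen.evals_to_frame(evals)
        frame.to_csv(
            os.path.join(out_dir, f"{mark}_biomarkers.tsv"), sep="\t", index=False
        )
        n_pass = int(frame["passes_screen"].sum()) if len(frame) else 0
        logger.info("screen[%s]: %d evaluated, %d pass AUC>%.2f",
                    mark, len(frame), n_pass, scr["auc_cutoff"])


def stage_compare(cfg: Mapping, paths: RunPaths) -> None:
    cohort = load_cohort(cfg, paths)
    design = resolve_design(cfg, paths)
    out_dir = paths.sub("compare")
    dmrs_m = meth_io.read_dmr_bed(paths.dmr_bed(design.name, "5mC"))
    sig_m = dmr_calling.significant_dmrs(dmrs_m)
    if sig_m:
        # three-signal comparison for the strongest 5mC DMR
        top = max(sig_m, key=lambda d: abs(d.mean_diff))
        comparison = biomarker_screen.compare_signals(top, cohort, design)
        comparison.insert(0, "region", f"{top.chrom}:{top.start}-{top.end}")
        comparison.to_csv(os.path.join(out_dir, "signal_comparison.tsv"), sep="\t")
        logger.info("compare: top 5mC DMR %s:%d-%d AUCs %s",
                    top.chrom, top.start, top.end,
                    np.round(comparison["auc"].to_numpy(), 3).tolist())
    # global delta-5mC vs delta-5hmC correlation over 5mC candidate regions
    regions = [d.interval for d in dmrs_m]
    if len(regions) >= 3:
        prof = {}
        for signal in ("5mC", "5hmC"):
            means = biomarker_screen.region_sample_means(regions, cohort, signal)
            case = means[design.case_samples].mean(axis=1)
            control = means[design.control_samples].mean(axis=1)
            prof[signal] = case - control
        r, p = biomarker_screen.profile_correlation(prof["5mC"], prof["5hmC"])
        pd.DataFrame(
            [{"comparison": "delta5mC_vs_delta5hmC", "pearson_r": r, "p": p,
              "n_regions": len(regions)}]
        ).to_csv(os.path.join(out_dir, "profile_correlation.tsv"), sep="\t", index=False)
        logger.info("compare: delta5mC vs delta5hmC r=%.3f (p=%.2g)", r, p)


def run_pipeline(config, outdir: str) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    cfg = load_config(config)
    paths = RunPaths(outdir)
    handler = logging.FileHandler(os.path.join(outdir, "run_log.txt"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("oxbskit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if cfg["mode"] == "simulate":
            stage_simulate(cfg, paths)
        stage_estimate(cfg, paths)
        stage_dmr(cfg, paths)
        stage_annotate(cfg, paths)
        stage_screen(cfg, paths)
        stage_compare(cfg, paths)
    finally:
        root.removeHandler(handler)
        handler.close()
    manifest = {
        "config_hash": config_hash(cfg),
        "config": cfg,
        "outputs": sorted(
            os.path.relpath(os.path.join(dp, f), outdir)
            for dp, _, files in os.walk(outdir)
            for f in files
            if f != "manifest.json"
        ),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
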