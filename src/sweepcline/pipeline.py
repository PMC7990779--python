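"""Four-stage candidate pipeline: iHS screen -> F_ST filter -> climate
association -> case-control replication.

Stage 1 scores iHS per scan group and screens |iHS| > threshold.  Stage 2
computes pairwise F_ST for the screened SNPs and retains those reaching the
retention threshold in at least one group pair (the differentiation screen
has no canonical significance test, so the rule is a configurable cutoff
plus an empirical percentile against all SNPs in the input).  Stages 3 and 4
annotate the surviving SNPs with climate-cline statistics and case-control
association; they do not filter.  Every SNP is accounted for (passed,
failed or flagged) at every stage, and a fixed config + seed reproduces the
report byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as scio
from .assoc import AllelicAssociation
from .climate import ClineAssociation
from .core import HaplotypeMatrix, PopulationPanel
from .ehh import BinTable, IhsScan, DEFAULT_EHH_CUTOFF, DEFAULT_IHS_THRESHOLD, DEFAULT_MIN_DAF
from .fst import FstScan

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    haplotypes: str
    panel: str
    climate: str | None = None
    genotypes: str | None = None
    genetic_map: str | None = None
    bin_table: str | None = None
    output_dir: str = "pipeline_out"
    ihs_threshold: float = DEFAULT_IHS_THRESHOLD
    ehh_cutoff: float = DEFAULT_EHH_CUTOFF
    maf_min: float = DEFAULT_MIN_DAF
    fst_threshold: float = 0.15
    fst_estimator: str = "hudson"
    scan_groups: list[str] | None = None
    risk_allele: str = "coded"
    n_bins: int = 20
    min_bin_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ehh_cutoff < 1):
            raise ValueError("ehh_cutoff must be in (0, 1)")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.ihs_threshold <= 0:
            raise ValueError("ihs_threshold must be positive")
        for name in ("haplotypes", "panel"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunReport:
    """Joined pipeline output plus per-stage bookkeeping."""

    config: dict
    counts: dict = field(default_factory=dict)
    ihs: pd.DataFrame | None = None
    fst: pd.DataFrame | None = None
    climate: pd.DataFrame | None = None
    association: pd.DataFrame | None = None
    final: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (("ihs", self.ihs), ("fst", self.fst),
                         ("climate", self.climate), ("association", self.association),
                         ("candidates", self.final)):
            if df is not None:
                scio.write_results_tsv(df, out / f"{name}.tsv")
        summary = {
            "config": self.config,
            "counts": self.counts,
            "notes": self.notes,
            "final_snps": ([] if self.final is None else
                           sorted(self.final["snp_id"].unique().tolist())),
        }
        scio.write_run_summary(summary, out / "report.json")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the four stages and write report.json + per-stage TSVs."""
    matrix = scio.read_haplotype_tsv(config.haplotypes)
    panel = scio.read_panel_tsv(config.panel)
    bin_table = BinTable.from_tsv(config.bin_table) if config.bin_table else None
    gmap = scio.read_genetic_map(config.genetic_map) if config.genetic_map else None

    report = RunReport(config=asdict(config))
    counts = report.counts

    # restrict the scan to the configured groups
    groups = [panel.group_of_sample(s) for s in matrix.haplotype_samples()]
    scan_groups = config.scan_groups or sorted(set(groups))
    rows = np.flatnonzero(np.isin(groups, scan_groups))
    if rows.size == 0:
        raise ValueError(f"no haplotypes in scan groups {scan_groups}")
    scan_matrix = matrix.subset_haplotypes(rows)

    # ---- stage 1: iHS screen ---------------------------------------------
    scan = IhsScan(scan_matrix, panel, min_daf=config.maf_min,
                   ehh_cutoff=config.ehh_cutoff, n_bins=config.n_bins,
                   min_bin_size=config.min_bin_size, bin_table=bin_table,
                   genetic_map=gmap)
    ihs_res = scan.fit()
    report.ihs = ihs_res.frame
    hits = ihs_res.candidates(config.ihs_threshold)
    stage1_snps = sorted(hits["snp_id"].unique().tolist())
    counts["stage1"] = {
        "snps_in": matrix.n_snps,
        "snp_population_pairs_evaluated": len(report.ihs),
        "snp_population_pairs_scored": int(np.isfinite(report.ihs["ihs"]).sum()),
        "snps_passing": len(stage1_snps),
    }
    logger.info("stage 1 (iHS): %d candidate SNP(s) of %d", len(stage1_snps), matrix.n_snps)

    # ---- stage 2: F_ST filter --------------------------------------------
    survivors: list[str] = []
    fst_frame = pd.DataFrame(columns=["snp_id", "pop1", "pop2", "estimator",
                                      "p1", "p2", "n1", "n2", "fst", "flags"])
    if stage1_snps:
        fst_all = FstScan(scan_matrix, panel, estimator=config.fst_estimator).fit()
        background = fst_all.frame
        fst_frame = background[background["snp_id"].isin(stage1_snps)].copy()
        pct = []
        for _, row in fst_frame.iterrows():
            pair_bg = background[(background["pop1"] == row["pop1"])
                                 & (background["pop2"] == row["pop2"])]["fst"].dropna()
            pct.append(float((pair_bg <= row["fst"]).mean() * 100) if len(pair_bg) else np.nan)
        fst_frame["percentile"] = pct
        best = fst_frame.groupby("snp_id")["fst"].max()
        survivors = sorted(best.index[best >= config.fst_threshold].tolist())
    else:
        report.notes.append("stage 2 skipped: no iHS candidates")
    report.fst = fst_frame
    counts["stage2"] = {"snps_in": len(stage1_snps), "snps_passing": len(survivors)}
    logger.info("stage 2 (F_ST >= %.3g): %d of %d retained",
                config.fst_threshold, len(survivors), len(stage1_snps))

    # ---- stage 3: climate association (annotation) -----------------------
    climate_rows = []
    n_climate = 0
    if survivors and config.climate:
        climate = scio.read_climate_csv(config.climate)
        for sid in survivors:
            try:
                cline = ClineAssociation.from_matrix(matrix, sid, climate).fit()
            except ValueError as exc:
                report.notes.append(f"stage 3: {sid}: {exc}")
                continue
            climate_rows.append(cline.frame)
            n_climate += 1
    elif survivors:
        report.notes.append("stage 3 skipped: no climate table configured")
    elif config.climate:
        report.notes.append("stage 3 skipped: no surviving SNPs")
    report.climate = (pd.concat(climate_rows, ignore_index=True) if climate_rows
                      else pd.DataFrame(columns=["snp_id", "covariate", "n", "r", "p",
                                                 "p_adjusted", "flags"]))
    counts["stage3"] = {"snps_in": len(survivors), "snps_annotated": n_climate}

    # ---- stage 4: case-control association (annotation) ------------------
    assoc_rows = []
    if survivors and config.genotypes:
        geno = scio.read_genotype_tsv(config.genotypes)
        typed = set(geno["snp_id"].unique())
        for sid in survivors:
            if sid not in typed:
                report.notes.append(f"stage 4: {sid} absent from genotype table")
                continue
            res = AllelicAssociation.from_frame(geno, snp_id=sid,
                                                risk_allele=config.risk_allele).fit()
            frame = res.frame
            frame["snp_id"] = sid
            assoc_rows.append(frame)
    elif survivors:
        report.notes.append("stage 4 skipped: no genotype table configured")
    report.association = (pd.concat(assoc_rows, ignore_index=True) if assoc_rows
                          else pd.DataFrame(columns=["snp_id", "a", "b", "c", "d",
                                                     "odds_ratio", "ci_low", "ci_high",
                                                     "chi2", "p", "flags"]))
    counts["stage4"] = {"snps_in": len(survivors), "snps_tested": len(assoc_rows)}

    # ---- final joined table ----------------------------------------------
    rows_out = []
    for sid in survivors:
        ihs_snp = report.ihs[(report.ihs["snp_id"] == sid)
                             & np.isfinite(report.ihs["ihs"])]
        top = ihs_snp.loc[ihs_snp["ihs"].abs().idxmax()] if len(ihs_snp) else None
        fst_snp = report.fst[report.fst["snp_id"] == sid]
        clim_snp = report.climate[report.climate["snp_id"] == sid]
        best_cov = (clim_snp.loc[clim_snp["p"].idxmin()] if len(clim_snp)
                    and clim_snp["p"].notna().any() else None)
        asc = report.association[report.association["snp_id"] == sid]
        rows_out.append({
            "snp_id": sid,
            "top_population": top["population"] if top is not None else "NA",
            "ihs": top["ihs"] if top is not None else np.nan,
            "fst_max": fst_snp["fst"].max() if len(fst_snp) else np.nan,
            "best_covariate": best_cov["covariate"] if best_cov is not None else "NA",
            "climate_r": best_cov["r"] if best_cov is not None else np.nan,
            "climate_p": best_cov["p"] if best_cov is not None else np.nan,
            "odds_ratio": asc["odds_ratio"].iloc[0] if len(asc) else np.nan,
            "or_ci_low": asc["ci_low"].iloc[0] if len(asc) else np.nan,
            "or_ci_high": asc["ci_high"].iloc[0] if len(asc) else np.nan,
            "assoc_p": asc["p"].iloc[0] if len(asc) else np.nan,
        })
    report.final = pd.DataFrame(rows_out, columns=[
        "snp_id", "top_population", "ihs", "fst_max", "best_covariate",
        "climate_r", "climate_p", "odds_ratio", "or_ci_low", "or_ci_high", "assoc_p"])

    report.write(config.output_dir)
    return report
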