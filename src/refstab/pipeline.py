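"""Orchestration: the full stability analysis per sample set.

Runs, for each requested sample set: conversion of mean Cq to
efficiency-corrected relative quantities (the calibrator is recomputed within
the set so each set is self-contained), the four stability algorithms
(geNorm, NormFinder, BestKeeper, comparative delta-Ct), the consensus
geometric-mean ranking, and the geNorm V-curve with the optimal number of
reference genes.  Every stage logs counts (genes in, samples excluded, QC
flags) and all outputs are deterministic for a fixed configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import calibration, consensus, genorm, normfinder, pairwise_methods, qpcr_data

log = logging.getLogger("refstab")


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    cq_path: str
    sheet_path: str
    efficiency_path: str | None = None  # CSV gene,efficiency
    dilution_path: str | None = None  # CSV gene,dilution_factor,cq (fit if no efficiency CSV)
    sample_sets: tuple[str, ...] = ("genotypes", "stress", "tissues", "all")
    output_dir: str | None = None
    sd_flag_threshold: float = 0.5
    v_cutoff: float = genorm.DEFAULT_V_CUTOFF
    tied_final_pair: bool = True
    normfinder_grouped_sets: tuple[str, ...] = ()  # sets analyzed with grouped NormFinder
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.cq_path, self.sheet_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.efficiency_path is None and self.dilution_path is None:
            raise ValueError("need either an efficiency CSV or a dilution-series CSV")


@dataclass
class SampleSetReport:
    sample_set: str
    samples: list[str]
    stability: consensus.StabilityTable
    genorm_result: genorm.GenormResult
    normfinder_result: normfinder.NormfinderResult
    bestkeeper_result: pairwise_methods.BestKeeperResult
    deltact_result: pairwise_methods.DeltaCtResult

    def consensus_frame(self) -> pd.DataFrame:
        return self.stability.to_frame()

    def v_curve_frame(self) -> pd.DataFrame:
        rows = [{"n": n, "v": v} for n, v in sorted(self.genorm_result.v_curve.items())]
        frame = pd.DataFrame(rows)
        frame["below_cutoff"] = frame["v"] < self.genorm_result.cutoff
        return frame


def analyze_sample_set(
    matrix: qpcr_data.CqMatrix,
    eff: dict[str, float],
    sample_set: str = "all",
    groups: dict[str, str] | None = None,
    v_cutoff: float = genorm.DEFAULT_V_CUTOFF,
    tied_final_pair: bool = True,
) -> SampleSetReport:
    """All four stability methods + consensus on one aggregated Cq matrix."""
    try:
        rq = calibration.to_relative_quantities(matrix, eff)
    except ValueError as exc:
        raise PipelineError(f"[{sample_set}] relative-quantity conversion: {exc}") from exc

    try:
        gen = genorm.genorm_full(rq, cutoff=v_cutoff)
    except ValueError as exc:
        raise PipelineError(f"[{sample_set}] genorm: {exc}") from exc
    try:
        nf = normfinder.normfinder_stability(rq, groups=groups)
    except ValueError as exc:
        raise PipelineError(f"[{sample_set}] normfinder: {exc}") from exc
    cq_complete = matrix.subset(samples=rq.samples)
    try:
        bk = pairwise_methods.bestkeeper(cq_complete)
        dct = pairwise_methods.delta_ct_stability(cq_complete)
    except ValueError as exc:
        raise PipelineError(f"[{sample_set}] bestkeeper/deltact: {exc}") from exc

    ranks = pd.DataFrame(
        {
            "genorm": pd.Series(gen.ranks(tied_final_pair=tied_final_pair)),
            "normfinder": pd.Series(consensus.rank_scores(nf.stability)),
            "bestkeeper": pd.Series(consensus.rank_scores(bk.sd_cq)),
            "deltact": pd.Series(consensus.rank_scores(dct.mean_pairwise_sd)),
        }
    )
    table = consensus.comprehensive_rank(ranks)
    log.info(
        "[%s] %d genes, %d samples analyzed; geNorm final pair %s; optimal n = %s",
        sample_set, len(rq.genes), len(rq.samples), gen.final_pair, gen.optimal_n,
    )
    return SampleSetReport(
        sample_set=sample_set,
        samples=list(rq.samples),
        stability=table,
        genorm_result=gen,
        normfinder_result=nf,
        bestkeeper_result=bk,
        deltact_result=dct,
    )


def load_efficiencies(cfg: PipelineConfig) -> dict[str, float]:
    if cfg.efficiency_path is not None:
        return calibration.read_efficiency_csv(cfg.efficiency_path)
    eff: dict[str, float] = {}
    for series in calibration.read_dilution_csv(cfg.dilution_path):
        curve = calibration.fit_standard_curve(series)
        if not curve.valid:
            raise PipelineError(f"[calibration] gene {series.gene}: invalid standard curve")
        eff[series.gene] = curve.efficiency
    return eff


def run_full_analysis(cfg: PipelineConfig) -> dict[str, SampleSetReport]:
    """Read inputs, aggregate replicates, analyze every configured sample set.

    When ``cfg.output_dir`` is set, writes per-set ``consensus_<set>.csv`` and
    ``vcurve_<set>.csv``, plus ``gene_stats.csv``, ``qc_flags.csv`` and the
    aggregated matrix.
    """
    try:
        dataset = qpcr_data.read_cq_table(cfg.cq_path, cfg.sheet_path)
    except Exception as exc:
        raise PipelineError(f"[read] {exc}") from exc
    matrix, flags = qpcr_data.aggregate_replicates(dataset, cfg.sd_flag_threshold)
    log.info("[aggregate] %d genes x %d samples; %d QC flags", len(matrix.genes), len(matrix.samples), len(flags))
    eff = load_efficiencies(cfg)
    missing = [g for g in matrix.genes if g not in eff]
    if missing:
        raise PipelineError(f"[calibration] no efficiency for genes: {missing}")

    group_map = dataset.group_labels()
    reports: dict[str, SampleSetReport] = {}
    for set_name in cfg.sample_sets:
        samples = dataset.samples_in_set(set_name)
        sub = matrix.subset(samples=samples)
        groups = {s: group_map[s] for s in samples} if set_name in cfg.normfinder_grouped_sets else None
        reports[set_name] = analyze_sample_set(
            sub, eff, sample_set=set_name, groups=groups,
            v_cutoff=cfg.v_cutoff, tied_final_pair=cfg.tied_final_pair,
        )

    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        matrix.to_frame().to_csv(out / "cq_matrix.csv")
        pd.DataFrame(
            [{"gene": f.gene, "observation": f.observation, "sd": f.sd, "mean": f.mean} for f in flags],
            columns=["gene", "observation", "sd", "mean"],
        ).to_csv(out / "qc_flags.csv", index=False)
        qpcr_data.stats_to_frame(qpcr_data.descriptive_stats(matrix)).to_csv(out / "gene_stats.csv")
        for set_name, rep in reports.items():
            rep.consensus_frame().to_csv(out / f"consensus_{set_name}.csv")
            rep.v_curve_frame().to_csv(out / f"vcurve_{set_name}.csv", index=False)
    return reports
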