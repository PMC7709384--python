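"""End-to-end orchestration: unite -> DMC -> DMR -> annotate -> enrich -> elements.

Every stage is a pure function of (inputs, config, seed); ``run_pipeline``
wires them together, writes each stage's TSV/BED outputs, and logs a run
record with the configuration echo and seed so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotate import Annotator
from .core import ElementInstance, GeneModel, SiteCounts
from .diffmeth import (call_dmcs, call_dmrs, dmc_chromosome_summary,
                       dmc_test_all)
from .enrich import category_distribution, enrichment_table
from .methcall import (GroupDesign, MethylMatrix, chromosome_mean_test,
                       mean_methylation, unite_sites)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis thresholds; the defaults are the study's stated values."""

    min_coverage: int = 10
    q_threshold: float = 0.01
    dmc_diff: float = 10.0
    dmr_diff: float = 10.0
    dmr_min_cpg: int = 3
    dmr_max_gap: int = 100
    fisher_alpha: float = 0.001
    chrom_alpha: float = 0.01
    promoter_upstream: int = -1000
    promoter_downstream: int = 100
    tss_window: int = 2000
    pwm_rel_threshold: float = 0.90
    hot_spot_min: int = 3
    full_length_min_length: int = 6000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.q_threshold <= 1 and 0 < self.fisher_alpha <= 1
                and 0 < self.chrom_alpha <= 1):
            raise ValueError("significance thresholds must lie in (0, 1]")
        if self.min_coverage < 1 or self.dmr_min_cpg < 1 or self.dmr_max_gap < 1:
            raise ValueError("count thresholds must be positive")
        if self.dmc_diff < 0 or self.dmr_diff < 0:
            raise ValueError("difference thresholds must be non-negative")
        if not 0 < self.pwm_rel_threshold <= 1:
            raise ValueError("pwm_rel_threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    matrix: MethylMatrix
    dmc_table: pd.DataFrame
    dmr_table: pd.DataFrame
    chrom_summary: pd.DataFrame
    chrom_means: pd.DataFrame
    annotated_sites: pd.DataFrame
    annotated_dmrs: pd.DataFrame
    basic_distribution: pd.DataFrame
    group_enrichment: pd.DataFrame
    outputs: dict[str, Path] = field(default_factory=dict)


def run_pipeline(
    per_sample_sites: Mapping[str, Sequence[SiteCounts]],
    design: GroupDesign,
    gene_models: Sequence[GeneModel],
    repeats: Sequence[ElementInstance],
    config: PipelineConfig = PipelineConfig(),
    outdir=None,
) -> PipelineResult:
    """Run all analysis stages; write stage outputs when ``outdir`` given."""

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("unite")
        matrix = unite_sites(per_sample_sites, design, config.min_coverage)

        stage("dmc")
        dmc = call_dmcs(dmc_test_all(matrix), config.q_threshold,
                        config.dmc_diff)

        stage("dmr")
        dmr = call_dmrs(matrix, dmc, max_gap=config.dmr_max_gap,
                        min_cpg=config.dmr_min_cpg,
                        diff_threshold=config.dmr_diff,
                        q_threshold=config.q_threshold)

        stage("summaries")
        chrom_summary = dmc_chromosome_summary(dmc, matrix)
        chrom_means = chromosome_mean_test(matrix)

        stage("annotate")
        annotator = Annotator(
            gene_models, repeats,
            promoter_window=(config.promoter_upstream,
                             config.promoter_downstream))
        annotated = annotator.annotate_sites(dmc)
        annotated_dmrs = annotator.annotate_intervals(dmr)

        stage("enrich")
        dmcs_only = annotated[annotated["call"] != "none"]
        basic_dist = category_distribution(annotated, annotated, "basic")
        if len(dmcs_only):
            group_enr = enrichment_table(annotated, dmcs_only, "group",
                                         alpha=config.fisher_alpha)
        else:
            group_enr = pd.DataFrame()
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    result = PipelineResult(matrix, dmc, dmr, chrom_summary, chrom_means,
                            annotated, annotated_dmrs, basic_dist, group_enr)
    if outdir is not None:
        result.outputs = _write_outputs(result, config, outdir)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig,
                   outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[name] = p

    emit("dmc", result.annotated_sites)
    emit("dmr", result.annotated_dmrs)
    emit("chromosome_summary", result.chrom_summary)
    emit("chromosome_means", result.chrom_means)
    emit("basic_distribution", result.basic_distribution)
    if len(result.group_enrichment):
        emit("group_enrichment", result.group_enrichment)

    dmr_bed = outdir / "dmr.bed"
    with open(dmr_bed, "w") as fh:
        for _, r in result.dmr_table.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                     f"{r['call']}DMR\t0\t.\n")
    paths["dmr_bed"] = dmr_bed

    cfg = config.to_dict()
    cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    (outdir / "config.yaml").write_text(cfg_text)
    run_log = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "n_united_cpgs": len(result.matrix),
        "n_hypo_dmcs": int((result.dmc_table["call"] == "hypo").sum()),
        "n_hyper_dmcs": int((result.dmc_table["call"] == "hyper").sum()),
        "n_dmrs": len(result.dmr_table),
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")
    paths["config"] = outdir / "config.yaml"
    paths["run_log"] = outdir / "run_log.json"
    return paths
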