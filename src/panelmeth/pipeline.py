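"""End-to-end pipeline: reads -> CpG calls -> matrix -> differential -> clusters.

The pipeline either consumes existing inputs (panel BED, reference FASTA,
one coordinate-sorted SAM per sample) or generates a synthetic cohort first,
then runs calling, QC, aggregation, differential-methylation assessment and
clustering, writing per-stage artifacts and a machine-readable summary JSON.
All randomness funnels through the single seed recorded in the summary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, cluster, differential, simulate
from .aggregate import build_matrix
from .panel import CapturePanel, generate_panel, read_fasta, write_fasta


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Validated parameters for a full pipeline run."""

    out_dir: str = "panelmeth_out"
    # inputs (file mode); leave None to simulate
    panel_bed: str | None = None
    reference_fasta: str | None = None
    reads_dir: str | None = None  # one <sample>.sam per sample
    # synthetic mode
    n_genes: int = 10
    regions_per_gene: tuple[int, int] = (1, 3)
    region_length: tuple[int, int] = (300, 900)
    n_samples: int = 8
    mean_depth: float = 190.0
    conversion_eff: float = 0.995
    seq_error: float = 0.001
    dup_rate: float = 0.05
    n_diff_regions: int = 2
    minority_size: int = 2
    effect_pp: float = 30.0
    direction_mix: str | float = "hyper"
    # analysis parameters
    flank: int = 250
    min_depth: int = 10
    confidence: float = 0.99
    minority_max: int | None = None
    pp_cuts: tuple[float, ...] = (5, 10, 20)
    fold_cut: float = 2.0
    k_impute: int = 10
    contrast: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.flank < 0 or self.min_depth < 1:
            raise PipelineError("flank must be >= 0 and min_depth >= 1")
        if not (0 < self.confidence < 1):
            raise PipelineError("confidence must be in (0, 1)")
        if not (0 < self.conversion_eff <= 1):
            raise PipelineError("conversion_eff must be in (0, 1]")
        if self.mean_depth <= 0:
            raise PipelineError("mean_depth must be positive")
        file_mode = self.panel_bed is not None
        if file_mode and (self.reference_fasta is None or self.reads_dir is None):
            raise PipelineError(
                "file mode needs panel_bed, reference_fasta and reads_dir together"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    # ---- stage: inputs ---------------------------------------------------
    truth = None
    if config.panel_bed is not None:
        panel = CapturePanel.from_bed(config.panel_bed)
        reference = read_fasta(config.reference_fasta)
        reads = {
            p.stem: simulate.read_sam(p)
            for p in sorted(Path(config.reads_dir).glob("*.sam"))
        }
        if not reads:
            raise PipelineError(f"stage 'inputs' failed: no SAM files in {config.reads_dir}")
    else:
        panel, reference = generate_panel(
            config.n_genes,
            config.regions_per_gene,
            config.region_length,
            seed=config.seed,
            flank=config.flank,
        )
        diff_spec = (
            (config.n_diff_regions, config.minority_size, config.effect_pp,
             config.direction_mix)
            if config.n_diff_regions
            else None
        )
        truth = simulate.generate_cohort_truth(
            panel,
            n_samples=config.n_samples,
            differential_spec=diff_spec,
            conversion_eff=config.conversion_eff,
            seq_error=config.seq_error,
            dup_rate=config.dup_rate,
            seed=config.seed + 1,
        )
        reads = simulate.generate_reads(
            truth, panel, reference,
            mean_depth=config.mean_depth, flank=config.flank,
            seed=config.seed + 2,
        )
        panel.to_bed(out / "panel.bed")
        write_fasta(reference, out / "reference.fa")
        truth.to_tsv(out / "truth.tsv")
    summary["stages"]["inputs"] = {
        "n_capture_regions": len(panel.capture_regions),
        "n_genes": len(panel.genes),
        "n_samples": len(reads),
        "synthetic": truth is not None,
    }

    # ---- stage: call -----------------------------------------------------
    sites_by_sample: dict[str, pd.DataFrame] = {}
    qc: dict[str, dict] = {}
    for sample, pairs in reads.items():
        filtered = calling.preprocess_reads(pairs)
        target = [p for p in filtered if p.chrom != panel.lambda_contig]
        sites = calling.call_methylation(target, reference, panel, flank=config.flank)
        sites_by_sample[sample] = sites
        calling.write_methratio_tsv(sites, out / f"{sample}.methratio.tsv")
        conv = calling.conversion_efficiency(
            filtered, reference[panel.lambda_contig], panel.lambda_contig
        )
        cov = calling.coverage_report(pairs, panel)
        n_total, n_strict = calling.count_informative_cpgs(sites)
        qc[sample] = {
            "conversion_pct": conv.efficiency_pct,
            "coverage": cov.to_dict(),
            "sensitivity_pct": calling.sensitivity(cov.mean_cov_primary),
            "informative_cpgs": n_total,
            "strict_cpgs": n_strict,
        }
    mean_primary = float(np.mean([q["coverage"]["mean_cov_primary"] for q in qc.values()]))
    summary["stages"]["call"] = {
        "per_sample": qc,
        "mean_cov_primary": mean_primary,
        "mean_conversion_pct": float(np.mean([q["conversion_pct"] for q in qc.values()])),
        "cohort_sensitivity_pct": calling.sensitivity(mean_primary),
    }
    (out / "qc.json").write_text(json.dumps(summary["stages"]["call"], indent=2))

    # ---- stage: aggregate ------------------------------------------------
    try:
        matrix = build_matrix(
            sites_by_sample, panel, min_depth=config.min_depth, flank=config.flank
        )
    except Exception as exc:
        raise PipelineError(f"stage 'aggregate' failed: {exc}") from exc
    matrix.to_csv(out / "methylation_matrix.csv")
    summary["stages"]["aggregate"] = {
        "shape": list(matrix.values.shape),
        "n_missing": int(matrix.values.isna().sum().sum()),
    }

    # ---- stage: differential --------------------------------------------
    caller = differential.MinorityZScoreCaller(
        confidence=config.confidence, minority_max=config.minority_max
    ).fit(matrix)
    calls = caller.calls_
    ranking = differential.rank_and_threshold(
        calls, pp_cuts=config.pp_cuts, fold_cut=config.fold_cut
    )
    hyper = differential.hypermethylated_subset(calls, fold_cut=config.fold_cut)
    differential.differential_table(calls).to_csv(
        out / "differential_regions.tsv", sep="\t", index=False
    )
    summary["stages"]["differential"] = {
        "n_called": len(calls),
        "minority_max": caller.minority_max_,
        "z_crit": caller.z_crit_,
        "pp_counts": ranking["pp_counts"],
        "n_hyper": len(hyper["positive"]),
        "hyper_above_20pp": [r.region_id for r in hyper["above_pp"]],
        "hyper_high_fold": [r.region_id for r in hyper["high_fold_low_pp"]],
    }

    # ---- stage: cluster --------------------------------------------------
    try:
        complete = cluster.impute_missing(matrix, k=config.k_impute)
        zmat = differential.zscore(complete)
        assessable = zmat.dropna(how="all")
        result = cluster.hierarchical_cluster(assessable, contrast=config.contrast)
        outliers = cluster.overall_sample_outliers(matrix)
    except Exception as exc:
        raise PipelineError(f"stage 'cluster' failed: {exc}") from exc
    result.sample_labels.to_csv(out / "cluster_labels.tsv", sep="\t")
    (out / "samples.nwk").write_text(result.newick("samples") + "\n")
    (out / "regions.nwk").write_text(result.newick("regions") + "\n")
    summary["stages"]["cluster"] = {
        "sample_labels": {str(k): int(v) for k, v in result.sample_labels.items()},
        "group_a": result.group_a,
        "group_b": result.group_b,
        "overall_outliers": {
            str(s): str(f)
            for s, f in outliers["flag"].items()
            if f
        },
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
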