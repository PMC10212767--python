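"""Orchestration: scan -> ChIP filter -> RNA-seq confirmation on files.

Intermediate TSV/BED/JSON files are the contract between stages, so any
stage can be re-run independently; a machine-readable run report records
the parameters, the seed and the per-stage funnel counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

import iris
from iris import chip as chip_mod
from iris import confirm as confirm_mod
from iris import scan as scan_mod
from iris.genomic_io import (
    read_alignments,
    read_narrowpeak,
    read_reference_features,
    read_transcript_models,
    select_representative_isoforms,
    write_bed,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed."""


class InputError(PipelineError):
    """An input file is missing or malformed."""


@dataclass
class PipelineConfig:
    annotation: str
    groseq: str
    rnaseq: str
    peaks: Sequence[str] = ()
    reference: str | None = None
    out: str = "iris_out"
    width: int = 500
    step: int = 250
    pseudocount: float = 0.5
    logasr_min: float = 0.5
    fdr: float = 0.01
    final_logasr_min: float = 1.0
    final_fdr: float = 1e-5
    upstream_bp: int = 2000
    n_background: int | None = None
    seed: int = 0
    warnings: list[str] = field(default_factory=list)

    def params(self) -> dict:
        return {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("warnings",)
        }


def _require(path: str | None, stage: str) -> Path:
    if path is None:
        raise InputError(f"{stage}: required input not configured")
    p = Path(path)
    if not p.exists():
        raise InputError(f"{stage}: input file not found: {p}")
    return p


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Run all stages, persisting intermediates under ``config.out``.

    Returns ``(final annotation frame, run report)``.  The report is also
    written as ``report.json``.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "iris",
        "version": iris.__version__,
        "parameters": config.params(),
        "seed": config.seed,
        "warnings": [],
        "counts": {},
    }

    # inputs checked up front so a bad config aborts before any computation
    annotation = _require(config.annotation, "scan")
    groseq_path = _require(config.groseq, "scan")
    rnaseq_path = _require(config.rnaseq, "confirm")
    peak_paths = [_require(p, "chip") for p in config.peaks]
    if not peak_paths:
        raise InputError("chip: no narrowPeak files configured")

    try:
        models_all = read_transcript_models(annotation)
        models = select_representative_isoforms(models_all.values())
        models = {m.transcript_id: m for m in models.values()}
        reads, summary = read_alignments(groseq_path, models)
        report["warnings"] += [
            f"groseq: {k}={v}" for k, v in summary.items() if v
        ]

        windows = scan_mod.scan_windows(
            reads, models, config.width, config.step, config.pseudocount
        )
        windows.to_csv(out / "windows.tsv", sep="\t", index=False)
        significant = scan_mod.call_significant_windows(
            windows, config.logasr_min, config.fdr
        )
        merged = (
            scan_mod.merge_windows(significant)
            if len(significant)
            else pd.DataFrame(columns=["transcript_id", "start", "end"])
        )
        refined = scan_mod.rescore_loci(
            merged, reads, models, config.pseudocount, config.logasr_min, config.fdr
        )
        loci = refined.loc[refined["groseq_pass"]].reset_index(drop=True)
        loci = scan_mod.attach_genomic_blocks(loci, models)
        loci.to_csv(out / "loci.tsv", sep="\t", index=False)
        if len(loci):
            write_bed(loci, out / "loci.bed")
        background = scan_mod.select_background_loci(
            windows, n=config.n_background, seed=config.seed
        )
        background = scan_mod.attach_genomic_blocks(background, models)
        background.to_csv(out / "background.tsv", sep="\t", index=False)
        report["counts"].update(
            windows_tested=int(len(windows)),
            significant_windows=int(len(significant)),
            merged_loci=int(len(merged)),
            refined_loci=int(len(loci)),
            background_loci=int(len(background)),
        )
    except InputError:
        raise
    except Exception as exc:
        _write_report(report, out)
        raise PipelineError(f"scan stage failed: {exc}") from exc

    try:
        peak_sets = [read_narrowpeak(p) for p in peak_paths]
        null = chip_mod.build_null(background, peak_sets, config.upstream_bp)
        if null.iqr == 0:
            report["warnings"].append("chip: degenerate null (IQR = 0)")
        counted = chip_mod.count_all_loci(loci, peak_sets, config.upstream_bp)
        chipped = chip_mod.filter_by_chip(counted, null)
        chipped.to_csv(out / "chip.tsv", sep="\t", index=False)
        with open(out / "chip_null.json", "w") as handle:
            json.dump(null.to_dict(), handle, indent=2)
        chip_pass = chipped.loc[chipped["chip_pass"]].reset_index(drop=True)
        report["counts"]["chip_pass"] = int(len(chip_pass))
    except Exception as exc:
        _write_report(report, out)
        raise PipelineError(f"chip stage failed: {exc}") from exc

    try:
        rnaseq, summary = read_alignments(rnaseq_path, models)
        report["warnings"] += [
            f"rnaseq: {k}={v}" for k, v in summary.items() if v
        ]
        scored = confirm_mod.score_rnaseq(chip_pass, rnaseq, models, config.pseudocount)
        scored = confirm_mod.finalize(scored, config.final_logasr_min, config.final_fdr)
        final = scored.loc[scored["rnaseq_pass"]].reset_index(drop=True)
        if config.reference is not None:
            reference = read_reference_features(_require(config.reference, "confirm"))
            final = confirm_mod.classify_overlap(final, reference)
            final.groupby("category").size().rename("n_loci").to_csv(
                out / "categories.tsv", sep="\t"
            )
        final.to_csv(out / "final.tsv", sep="\t", index=False)
        if len(final):
            write_bed(final, out / "final.bed")
        report["counts"]["final"] = int(len(final))
    except InputError:
        raise
    except Exception as exc:
        _write_report(report, out)
        raise PipelineError(f"confirm stage failed: {exc}") from exc

    _write_report(report, out)
    return final, report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, default=str)
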