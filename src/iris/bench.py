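"""End-to-end benchmark of the pipeline on a fully simulated study.

Generates a transcriptome with declared antisense units, stranded GRO-seq
and RNA-seq libraries, and multi-sample ChIP peaks (true promoters at the
declared units, spurious presence at the scan's own background loci), runs
the three pipeline stages in memory, and evaluates the final annotation
against the declared truth: sensitivity, false-discovery proportion and
refined-boundary error.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from iris import chip as chip_mod
from iris import confirm as confirm_mod
from iris import scan as scan_mod
from iris import synth


def run_simulated_study(
    config: synth.SimConfig,
    logasr_min: float = 0.5,
    q_max: float = 0.01,
    final_logasr_min: float = 1.0,
    final_q_max: float = 1e-5,
    upstream_bp: int = 2000,
    pseudocount: float = 0.5,
) -> dict:
    """One replicate: simulate, run all three stages, evaluate against truth.

    Returns a dict with the stage outputs, funnel counts and the evaluation
    (sensitivity, fdp, per-unit boundary errors of recovered units).
    """
    models = synth.simulate_transcriptome(config)
    units = synth.place_antisense_units(models, config)
    truth = synth._unit_loci_frame(models, units)
    groseq = synth.simulate_stranded_reads(models, config, "groseq", units)
    rnaseq = synth.simulate_stranded_reads(models, config, "rnaseq", units)

    windows = scan_mod.scan_windows(groseq, models, pseudocount=pseudocount)
    significant = scan_mod.call_significant_windows(windows, logasr_min, q_max)
    merged = scan_mod.merge_windows(significant) if len(significant) else pd.DataFrame(
        columns=["transcript_id", "start", "end"]
    )
    refined = scan_mod.rescore_loci(
        merged, groseq, models, pseudocount, logasr_min, q_max
    )
    scan_pass = refined.loc[refined["groseq_pass"]].reset_index(drop=True)

    background = scan_mod.select_background_loci(windows, seed=config.seed)
    background = scan_mod.attach_genomic_blocks(background, models)
    scan_pass = scan_mod.attach_genomic_blocks(scan_pass, models)

    peak_sets = synth.simulate_chip_samples(truth, background, config)
    null = chip_mod.build_null(background, peak_sets, upstream_bp)
    counted = chip_mod.count_all_loci(scan_pass, peak_sets, upstream_bp)
    chipped = chip_mod.filter_by_chip(counted, null)
    chip_pass = chipped.loc[chipped["chip_pass"]].reset_index(drop=True)

    scored = confirm_mod.score_rnaseq(chip_pass, rnaseq, models, pseudocount)
    scored = confirm_mod.finalize(scored, final_logasr_min, final_q_max)
    final = scored.loc[scored["rnaseq_pass"]].reset_index(drop=True)

    evaluation = evaluate_against_truth(final, units)
    evaluation["background_chip_counts"] = null.background_counts
    evaluation["chip_threshold"] = null.threshold
    return {
        "models": models,
        "units": units,
        "truth": truth,
        "windows": windows,
        "scan_pass": scan_pass,
        "background": background,
        "peak_sets": peak_sets,
        "null": null,
        "chip_pass": chip_pass,
        "final": final,
        "funnel": {
            "windows_tested": int(len(windows)),
            "significant_windows": int(len(significant)),
            "merged_loci": int(len(merged)),
            "refined_loci": int(len(scan_pass)),
            "chip_pass": int(len(chip_pass)),
            "final": int(len(final)),
        },
        "evaluation": evaluation,
    }


def evaluate_against_truth(
    final: pd.DataFrame, units: Sequence[tuple[str, int, int, float]]
) -> dict:
    """Sensitivity, false-discovery proportion and boundary errors.

    A unit is recovered when a final locus on its transcript overlaps it by
    >= 1 nt; a final locus is a false discovery when it overlaps no unit on
    its transcript.  Boundary error of a recovered unit is the larger of
    the start and end deviations of the overlapping locus.
    """
    unit_map: dict[str, list[tuple[int, int]]] = {}
    for tid, s, e, _ in units:
        unit_map.setdefault(tid, []).append((s, e))

    false_pos = 0
    for _, row in final.iterrows():
        tid = str(row["transcript_id"])
        s, e = int(row["start"]), int(row["end"])
        if not any(min(e, ue) > max(s, us) for us, ue in unit_map.get(tid, [])):
            false_pos += 1

    recovered = 0
    bound_errors: list[float] = []
    for tid, us, ue, _ in units:
        hits = final.loc[final["transcript_id"] == tid]
        overlap = hits.loc[
            (hits["start"] < ue) & (hits["end"] > us)
        ]
        if len(overlap):
            recovered += 1
            row = overlap.iloc[0]
            bound_errors.append(
                max(abs(int(row["start"]) - us), abs(int(row["end"]) - ue))
            )
    n_units = len(units)
    n_final = len(final)
    return {
        "sensitivity": recovered / n_units if n_units else float("nan"),
        "fdp": false_pos / n_final if n_final else 0.0,
        "bound_errors": np.array(bound_errors, dtype=float),
        "n_final": n_final,
        "n_units": n_units,
    }


def run_replicates(base_config: synth.SimConfig, n_replicates: int, **kwargs) -> dict:
    """Average the end-to-end evaluation over seeded replicates.

    Replicate r uses seed ``base_config.seed + r``; reports mean sensitivity
    and FDP, pooled boundary errors and the funnel of the last replicate.
    """
    sens, fdp, errors = [], [], []
    funnel = None
    for r in range(n_replicates):
        cfg = synth.SimConfig(**{**base_config.to_dict(), "seed": base_config.seed + r})
        result = run_simulated_study(cfg, **kwargs)
        sens.append(result["evaluation"]["sensitivity"])
        fdp.append(result["evaluation"]["fdp"])
        errors.append(result["evaluation"]["bound_errors"])
        funnel = result["funnel"]
    all_errors = np.concatenate(errors) if errors else np.array([])
    return {
        "sensitivity": float(np.mean(sens)),
        "fdp": float(np.mean(fdp)),
        "mean_bound_error": float(all_errors.mean()) if all_errors.size else float("nan"),
        "bound_errors": all_errors,
        "per_replicate_sensitivity": sens,
        "per_replicate_fdp": fdp,
        "last_funnel": funnel,
    }
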