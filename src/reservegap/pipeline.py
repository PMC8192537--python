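"""End-to-end analysis: QC -> screening -> SDM -> gap analysis -> prioritization.

The pipeline is a pure function of (inputs, configuration, seed): rerunning
with the same scenario and seed reproduces every output file bit-exactly.
Each stage logs its in/out counts so data losses are attributable.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .grid import BinaryMask, Layer
from .prioritize import (
    EfficiencyReport,
    Solution,
    build_problem,
    completeness_metric,
    solve_exact,
    solve_greedy,
    specificity_metric,
)
from .qc import QCReport, clean_records, filter_min_occurrences, subset_records
from .raster import write_raster
from .representation import (
    RepresentationRecord,
    class_fractions,
    extrinsic_representativeness,
    gap_analysis,
    records_to_frame,
)
from .sdm import SpeciesSDM, fit_species_sdm, sample_background
from .synthetic import Scenario
from .vif import VIFTable, prune_predictors

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    qc_report: QCReport
    minocc_report: QCReport
    vif_table: VIFTable
    sdms: dict[str, SpeciesSDM]
    dropped_low_tss: list[str]
    ranges: dict[str, BinaryMask]
    gap_records: list[RepresentationRecord]
    completeness_solution: Solution
    specificity_solution: Solution
    efficiency: dict[str, float]
    completeness_report: EfficiencyReport = None  # type: ignore[assignment]
    specificity_report: EfficiencyReport = None  # type: ignore[assignment]
    problems: dict = field(default_factory=dict)


def run_on_scenario(
    scenario: Scenario,
    config: RunConfig | None = None,
    solver: str = "exact",
    known_institutions=(),
    run_prioritization: bool = True,
) -> PipelineResult:
    """Run the full analysis on an in-memory scenario.

    With ``run_prioritization=False`` the pipeline stops after the gap
    analysis (useful when only representation results are needed)."""
    cfg = config or RunConfig()
    grid = scenario.grid

    def stage(name):
        logger.info("stage: %s", name)
        return name

    name = stage("clean")
    try:
        cleaned, qc_report = clean_records(
            scenario.occurrences,
            grid,
            known_centroids=scenario.centroids,
            known_institutions=known_institutions,
            uncertainty_max_m=cfg.uncertainty_max_m,
        )
        retained_species, minocc_report = filter_min_occurrences(
            cleaned, grid, cfg.min_occurrences
        )
        cleaned = subset_records(cleaned, retained_species)
    except Exception as exc:
        raise StageError(f"stage '{name}' failed: {exc}") from exc

    name = stage("screen")
    try:
        named = {f"var{i:02d}": p for i, p in enumerate(scenario.predictors)}
        predictors_kept, vif_table = prune_predictors(named, cfg.vif_threshold)
        predictors = list(predictors_kept.values())
    except Exception as exc:
        raise StageError(f"stage '{name}' failed: {exc}") from exc

    name = stage("sdm")
    try:
        sdms: dict[str, SpeciesSDM] = {}
        dropped: list[str] = []
        for sp in retained_species:
            cells = sorted(
                {grid.cell_of(r.x, r.y) for r in cleaned if r.species_id == sp}
                - {None}
            )
            presence_cells = np.array(cells, dtype=int)
            background_cells = sample_background(
                sp, cleaned, cfg.n_background, grid, seed=cfg.seed
            )
            result = fit_species_sdm(
                sp, presence_cells, background_cells, predictors, cfg, seed=cfg.seed
            )
            if result.binary_range is None or result.binary_range.count() == 0:
                dropped.append(sp)
                logger.info("%s: ensemble TSS <= %.2f, species dropped", sp, cfg.tss_keep)
            else:
                sdms[sp] = result
        if not sdms:
            raise ValueError("no species passed the ensemble TSS cutoff")
        ranges = {sp: s.binary_range for sp, s in sdms.items()}
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage '{name}' failed: {exc}") from exc

    name = stage("gaps")
    try:
        gap_records = gap_analysis(ranges, scenario.pa_mask, cfg)
    except Exception as exc:
        raise StageError(f"stage '{name}' failed: {exc}") from exc

    if not run_prioritization:
        return PipelineResult(
            qc_report=qc_report,
            minocc_report=minocc_report,
            vif_table=vif_table,
            sdms=sdms,
            dropped_low_tss=dropped,
            ranges=ranges,
            gap_records=gap_records,
            completeness_solution=None,  # type: ignore[arg-type]
            specificity_solution=None,  # type: ignore[arg-type]
            efficiency={
                "extrinsic_representativeness_pct": extrinsic_representativeness(gap_records),
                **{f"class_{k}_pct": v for k, v in class_fractions(gap_records).items()},
                "n_species_analyzed": len(gap_records),
            },
        )

    name = stage("prioritize")
    try:
        target_fractions = {r.species_id: r.target_fraction for r in gap_records}
        solve = solve_exact if solver == "exact" else solve_greedy
        prob_lock = build_problem(
            ranges,
            scenario.pa_mask,
            mode="completeness",
            exclusion_mask=scenario.exclusion_mask,
            target_fractions=target_fractions,
            config=cfg,
        )
        sol_lock = solve(prob_lock)
        comp = completeness_metric(prob_lock, sol_lock)
        prob_free = build_problem(
            ranges,
            scenario.pa_mask,
            mode="specificity",
            exclusion_mask=scenario.exclusion_mask,
            target_fractions=target_fractions,
            config=cfg,
        )
        sol_free = solve(prob_free)
        spec = specificity_metric(prob_free, scenario.pa_mask, sol_free)
    except Exception as exc:
        raise StageError(f"stage '{name}' failed: {exc}") from exc

    efficiency = {
        "extrinsic_representativeness_pct": extrinsic_representativeness(gap_records),
        **{f"class_{k}_pct": v for k, v in class_fractions(gap_records).items()},
        "pa_area_km2": comp.pa_area_km2,
        "added_area_km2": comp.added_area_km2,
        "completeness_pct": comp.completeness_pct,
        "expansion_pct": comp.expansion_pct,
        "expansion_of_current_pa_pct": comp.expansion_of_current_pa_pct,
        "completeness_alt_pct": comp.completeness_alt_pct,
        "free_solution_area_km2": spec.free_solution_area_km2,
        "overlap_area_km2": spec.overlap_area_km2,
        "specificity_pct": spec.specificity_pct,
        "n_species_analyzed": len(gap_records),
    }
    return PipelineResult(
        qc_report=qc_report,
        minocc_report=minocc_report,
        vif_table=vif_table,
        sdms=sdms,
        dropped_low_tss=dropped,
        ranges=ranges,
        gap_records=gap_records,
        completeness_solution=sol_lock,
        specificity_solution=sol_free,
        efficiency=efficiency,
        completeness_report=comp,
        specificity_report=spec,
        problems={"completeness": prob_lock, "specificity": prob_free},
    )


def write_results(result: PipelineResult, scenario: Scenario, out_dir: str) -> None:
    """Write the report files: gap CSV, both solution masks, efficiency JSON."""
    os.makedirs(out_dir, exist_ok=True)
    records_to_frame(result.gap_records).to_csv(
        os.path.join(out_dir, "gap_report.csv"), index=False
    )
    write_raster(
        result.completeness_solution.selected_mask(result.problems["completeness"]),
        os.path.join(out_dir, "solution_completeness.tif"),
    )
    write_raster(
        result.specificity_solution.selected_mask(result.problems["specificity"]),
        os.path.join(out_dir, "solution_specificity.tif"),
    )
    with open(os.path.join(out_dir, "efficiency.json"), "w") as fh:
        json.dump(result.efficiency, fh, indent=2)


def run_pipeline(
    scenario: Scenario, out_dir: str, config: RunConfig | None = None, solver: str = "exact"
) -> PipelineResult:
    """Run the analysis on a scenario and write all report files."""
    result = run_on_scenario(scenario, config=config, solver=solver)
    write_results(result, scenario, out_dir)
    return result
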