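"""Per-case and cohort orchestration.

A case run executes the whole measurement chain on one simulation/scan
pair: basic alignment -> RPS landmark alignment (with the acceptance
rule) -> signed distance map -> artifact trim -> aesthetic-unit
segmentation -> congruence metrics.  A study run stacks per-case
reports, tests each region's IO% for normality and screens the five
patient factors with the GLM, producing the p-value grid.

Every run writes a JSON manifest capturing the configuration, package
version and input checksums; outputs contain no timestamps, so a rerun
with identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distance import DistanceMap, signed_distance_map, trim_artifacts, export_colour_map
from .mesh_io import (
    LandmarkSet,
    TriangleMesh,
    read_landmarks,
    read_stl,
    validate_mesh,
)
from .metrics import CongruenceReport, case_report
from .regions import REGION_NAMES, RegionMasks, assign_regions, build_fences
from .registration import (
    AlignmentResult,
    apply_transform,
    basic_alignment,
    rps_alignment,
    transform_landmarks,
)
from .stats import FactorPGrid, cohort_report, glm_factor_screen, shapiro_wilk

logger = logging.getLogger(__name__)


class AlignmentRejectedError(RuntimeError):
    """RPS alignment exceeded the acceptance threshold in strict mode."""


@dataclass(frozen=True)
class RunConfig:
    """Knobs of a pipeline run (defaults follow the measurement protocol)."""

    tau: float = 2.0  # congruence tolerance, mm
    epsilon: float = 0.1  # RPS acceptance threshold, mm (strict <)
    trim_method: str = "robust"  # robust | absolute | none
    trim_param: float = 6.0  # k (robust) or cut in mm (absolute)
    direction: str = "sim_to_scan"  # where the distance map lives
    area_weighted: bool = False
    strict_alignment: bool = False
    save_error_map: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if self.trim_method not in ("robust", "absolute", "none"):
            raise ValueError(f"unknown trim method {self.trim_method!r}")
        if self.direction not in ("sim_to_scan", "scan_to_sim"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class CaseResult:
    report: CongruenceReport
    alignment: AlignmentResult
    dmap: DistanceMap
    masks: RegionMasks
    manifest: dict = field(default_factory=dict)


def analyze_case(
    sim: TriangleMesh,
    scan: TriangleMesh,
    sim_landmarks: LandmarkSet,
    scan_landmarks: LandmarkSet,
    config: RunConfig = RunConfig(),
) -> CaseResult:
    """Run the measurement chain on in-memory inputs."""
    # landmark bookkeeping fails fast, before any geometry
    scan_landmarks.rps_subset().check_paired(sim_landmarks.rps_subset())

    _, sim = validate_mesh(sim, clean=True)
    _, scan = validate_mesh(scan, clean=True)
    logger.info("stage basic_alignment")
    t0 = basic_alignment(scan, sim)
    logger.info("stage rps_alignment")
    lm0 = transform_landmarks(scan_landmarks, t0)
    align = rps_alignment(lm0, sim_landmarks, epsilon=config.epsilon)
    total = align.transform.compose(t0)
    align = AlignmentResult(total, align.residuals, align.names, align.epsilon)
    if not align.accepted:
        msg = (
            f"RPS alignment rejected: max residual {align.max_residual:.4f} mm "
            f">= {align.epsilon} mm"
        )
        if config.strict_alignment:
            raise AlignmentRejectedError(msg)
        warnings.warn(msg)
    scan_aligned = apply_transform(scan, total)
    scan_lm_aligned = transform_landmarks(scan_landmarks, total)

    logger.info("stage distance_map (%s)", config.direction)
    if config.direction == "sim_to_scan":
        dmap = signed_distance_map(sim, scan_aligned, flip_sign=True)
        host_mesh, host_lm = sim, sim_landmarks
    else:
        dmap = signed_distance_map(scan_aligned, sim, flip_sign=False)
        host_mesh, host_lm = scan_aligned, scan_lm_aligned

    if config.trim_method != "none":
        logger.info("stage trim_artifacts (%s)", config.trim_method)
        dmap = trim_artifacts(dmap, config.trim_method, config.trim_param)

    logger.info("stage segmentation")
    masks = assign_regions(host_mesh, build_fences(host_lm))
    logger.info("stage metrics")
    report = case_report(dmap, masks, tau=config.tau, area_weighted=config.area_weighted)
    report.notes["alignment_accepted"] = align.accepted
    report.notes["alignment_max_residual_mm"] = align.max_residual
    return CaseResult(report, align, dmap, masks)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_case(
    sim_path,
    scan_path,
    sim_landmarks_path,
    scan_landmarks_path,
    config: RunConfig = RunConfig(),
    out_dir=None,
) -> CaseResult:
    """File-based case run; optionally persists report + manifest + map."""
    paths = {
        "simulation": Path(sim_path),
        "scan": Path(scan_path),
        "simulation_landmarks": Path(sim_landmarks_path),
        "scan_landmarks": Path(scan_landmarks_path),
    }
    sim = read_stl(paths["simulation"])
    scan = read_stl(paths["scan"])
    sim_lm = read_landmarks(paths["simulation_landmarks"])
    scan_lm = read_landmarks(paths["scan_landmarks"])
    result = analyze_case(sim, scan, sim_lm, scan_lm, config)
    result.manifest = {
        "tool": "softcongruence",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in paths.items()},
        "alignment": {
            "accepted": result.alignment.accepted,
            "max_residual_mm": result.alignment.max_residual,
            "rms_residual_mm": result.alignment.rms_residual,
        },
        "n_valid_vertices": result.dmap.n_valid,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.report.to_csv(out / "report.csv")
        result.alignment.transform.to_json(out / "alignment.json")
        (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
        if config.save_error_map:
            export_colour_map(result.dmap, out / "error_map.ply",
                              scale=(-config.tau, config.tau))
    return result


def shapiro_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Per-region Shapiro-Wilk results (NaN where the test is undefined)."""
    rows = []
    for region in REGION_NAMES:
        vals = table[region].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        try:
            w, p = shapiro_wilk(vals)
        except ValueError as exc:
            warnings.warn(f"Shapiro-Wilk skipped for {region!r}: {exc}")
            w, p = float("nan"), float("nan")
        rows.append({"region": region, "W": w, "p": p})
    return pd.DataFrame(rows)


def screen_study_table(table: pd.DataFrame, alpha: float = 0.05):
    """Shapiro-Wilk per region + the GLM factor screen on a study table."""
    return shapiro_frame(table), glm_factor_screen(table, alpha=alpha)


def run_study(
    case_specs: list[dict],
    factor_table: pd.DataFrame,
    config: RunConfig = RunConfig(),
    out_dir=None,
    alpha: float = 0.05,
) -> dict:
    """Run >= 2 cases, stack their IO%, and screen the patient factors.

    ``case_specs``: each a dict with keys ``patient_id, simulation, scan,
    simulation_landmarks, scan_landmarks``.  Failed cases are recorded,
    excluded and flagged; the study aborts only if fewer than 2 survive.
    """
    if len(case_specs) < 2:
        raise ValueError("a study needs at least 2 cases")
    rows = []
    failures = {}
    for spec in case_specs:
        pid = spec["patient_id"]
        try:
            res = run_case(
                spec["simulation"],
                spec["scan"],
                spec["simulation_landmarks"],
                spec["scan_landmarks"],
                config=config,
            )
        except Exception as exc:  # recorded, not fatal
            logger.error("case %s failed: %s", pid, exc)
            failures[pid] = str(exc)
            continue
        row = {"patient_id": pid}
        for region in REGION_NAMES:
            row[region] = float(res.report.table.loc[region, "io_pct"])
        row["alignment_accepted"] = res.alignment.accepted
        rows.append(row)
    if len(rows) < 2:
        raise RuntimeError(f"fewer than 2 cases succeeded; failures: {failures}")
    io_table = pd.DataFrame(rows)
    table = io_table.merge(factor_table, on="patient_id", how="inner")
    if len(table) < len(io_table):
        missing = set(io_table.patient_id) - set(table.patient_id)
        warnings.warn(f"no factor rows for case(s) {sorted(missing)}; excluded")

    shapiro_df = shapiro_frame(table)
    try:
        grid = glm_factor_screen(table, alpha=alpha)
    except ValueError as exc:
        warnings.warn(f"factor screen skipped: {exc}")
        grid = None
    result = {
        "table": table,
        "shapiro": shapiro_df,
        "grid": grid,
        "failures": failures,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "study_table.csv", index=False, float_format="%.10g")
        shapiro_df.to_csv(out / "shapiro.csv", index=False, float_format="%.10g")
        if grid is not None:
            cohort_report(table, grid, out)
        (out / "manifest.json").write_text(
            json.dumps(
                {
                    "tool": "softcongruence",
                    "version": __version__,
                    "config": config.to_dict(),
                    "n_cases": len(case_specs),
                    "n_succeeded": len(rows),
                    "failures": failures,
                },
                indent=1,
            )
        )
    return result
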