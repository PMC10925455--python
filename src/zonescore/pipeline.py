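"""End-to-end orchestration: score, sweep, null-test and fixture generation.

Each entry point consumes a :class:`RunConfig` (usually read from YAML),
processes every case it can, logs a structured reason for every exclusion,
and writes deterministic CSV outputs plus a machine-readable run manifest
(config hash, package version, per-case status).  A run exits non-zero only
when *all* cases fail.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import ALPHA, PairedTestResult, cohort_tests, spearman_correlation
from .mask_model import (
    IMMUNE_ROLES, LabelMask, read_mask, read_metadata, read_roi, write_table,
)
from .null_simulation import DEFAULT_N_REPS, simulate_null
from .scoring import CellGeometry, digital_k17_score, scores_to_frame, zone_scores
from .synthetic import SyntheticSpec, write_fixture
from .zoning import (
    DEFAULT_BAND_DEPTH_UM, DEFAULT_SWEEP_DEPTHS_UM, classify_zones, depth_sweep,
)

logger = logging.getLogger(__name__)

_MASK_SUFFIXES = (".tif", ".tiff", ".png")


@dataclass
class RunConfig:
    """Configuration for a pipeline run; every study constant is a default here."""

    mask_dir: str = ""
    scheme_path: str = ""
    out_dir: str = "zonescore_out"
    roi_dir: str | None = None
    metadata_path: str | None = None
    band_depth_um: float = DEFAULT_BAND_DEPTH_UM
    sweep_depths_um: list[float] = field(
        default_factory=lambda: list(DEFAULT_SWEEP_DEPTHS_UM)
    )
    n_reps: int = DEFAULT_N_REPS
    seed: int = 0
    null_compartment: str = "peritumoral"
    lymphocyte_diameter_um: float = 8.0
    macrophage_diameter_um: float = 16.0
    tie_break: str = "pos"
    connectivity: int = 8
    tile_shape: tuple[int, int] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.tile_shape is not None:
            cfg.tile_shape = tuple(int(v) for v in cfg.tile_shape)  # type: ignore[assignment]
        return cfg

    def geometry(self) -> CellGeometry:
        return CellGeometry(
            lymphocyte_diameter_um=self.lymphocyte_diameter_um,
            macrophage_diameter_um=self.macrophage_diameter_um,
        )

    def validate_paths(self) -> None:
        if not Path(self.mask_dir).is_dir():
            raise FileNotFoundError(f"mask_dir not found: {self.mask_dir}")
        if not Path(self.scheme_path).is_file():
            raise FileNotFoundError(f"scheme not found: {self.scheme_path}")
        if self.roi_dir is not None and not Path(self.roi_dir).is_dir():
            raise FileNotFoundError(f"roi_dir not found: {self.roi_dir}")
        if self.metadata_path is not None and not Path(self.metadata_path).is_file():
            raise FileNotFoundError(
                f"metadata not found: {self.metadata_path}"
            )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _discover_cases(config: RunConfig) -> list[Path]:
    paths = [p for p in sorted(Path(config.mask_dir).iterdir())
             if p.suffix.lower() in _MASK_SUFFIXES
             and not p.stem.endswith("_roi")]
    if not paths:
        raise FileNotFoundError(f"no mask rasters in {config.mask_dir}")
    return paths


def _load_case(config: RunConfig, path: Path):
    mask = read_mask(path, config.scheme_path)
    roi = None
    if config.roi_dir is not None:
        roi_path = None
        for suf in _MASK_SUFFIXES:
            cand = Path(config.roi_dir) / f"{path.stem}_roi{suf}"
            if cand.is_file():
                roi_path = cand
                break
        if roi_path is not None:
            roi = read_roi(roi_path, mask.shape)
    return mask, roi


def _write_manifest(config: RunConfig, out_dir: Path, command: str,
                    case_status: list[dict]) -> None:
    manifest = {
        "command": command,
        "package": "zonescore",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "n_cases": len(case_status),
        "n_failed": sum(1 for c in case_status if c["status"] == "failed"),
        "cases": case_status,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )


def _tests_frame(results: list[PairedTestResult]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    return df


def run_score(config: RunConfig) -> int:
    """Per-case zone scores at the configured band depth + cohort-level tests."""
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry = config.geometry()

    rows = []
    case_status = []
    for path in _discover_cases(config):
        try:
            mask, roi = _load_case(config, path)
            partition = classify_zones(
                mask, band_depth_um=config.band_depth_um, roi=roi,
                tie_break=config.tie_break, connectivity=config.connectivity,
                tile_shape=config.tile_shape,
            )
            scores = zone_scores(mask, partition, geometry)
            flags = []
            if not mask.role_mask("tumor_k17neg").any():
                flags.append("no K17- tumor")
            if not mask.role_mask("tumor_k17pos").any():
                flags.append("no K17+ tumor")
            rows.extend(scores)
            case_status.append({
                "case_id": mask.case_id, "status": "ok", "flags": flags,
                "digital_k17_score": digital_k17_score(mask, roi),
            })
        except Exception as exc:  # logged + tallied, run continues
            logger.error("case %s failed: %s", path.stem, exc)
            case_status.append({
                "case_id": path.stem, "status": "failed", "reason": str(exc),
            })
    if rows:
        write_table(scores_to_frame(rows), out_dir / "zone_scores.csv")
        frame = scores_to_frame(rows)
        try:
            results = cohort_tests(frame)
            write_table(_tests_frame(results), out_dir / "cohort_tests.csv")
            _write_report(out_dir / "report.txt", frame, results, case_status)
        except ValueError as exc:
            logger.warning("cohort tests skipped: %s", exc)
    _write_manifest(config, out_dir, "score", case_status)
    return 0 if any(c["status"] == "ok" for c in case_status) else 1


def _write_report(path: Path, scores: pd.DataFrame,
                  results: list[PairedTestResult],
                  case_status: list[dict]) -> None:
    lines = [
        "zonescore cohort report",
        f"cases analysed: {sum(1 for c in case_status if c['status'] == 'ok')}",
        f"cases failed:   {sum(1 for c in case_status if c['status'] == 'failed')}",
        "flags:",
    ]
    for c in case_status:
        if c.get("flags"):
            lines.append(f"  {c['case_id']}: {', '.join(c['flags'])}")
    lines.append("")
    lines.append("paired t-tests of zs_neg vs zs_pos "
                 "(two-sided, no multiplicity adjustment):")
    for r in results:
        sig = "significant" if r.p_value <= ALPHA else "n.s."
        lines.append(
            f"  {r.marker:6s} {r.compartment:12s} n={r.n_cases:3d} "
            f"t={r.t_statistic:+.3f} p={r.p_value:.4g} ({sig}); "
            f"ratio>1 in {r.fraction_neg_dominant:.0%} of "
            f"{r.n_ratio_defined} defined cases, "
            f"{r.n_excluded} excluded"
        )
    path.write_text("\n".join(lines) + "\n")


def run_sweep(config: RunConfig) -> int:
    """Zone scores across the configured band-depth sweep (25-200 um default)."""
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry = config.geometry()
    rows = []
    case_status = []
    for path in _discover_cases(config):
        try:
            mask, roi = _load_case(config, path)
            for partition in depth_sweep(
                mask, config.sweep_depths_um, roi=roi,
                tie_break=config.tie_break, connectivity=config.connectivity,
            ):
                rows.extend(zone_scores(mask, partition, geometry))
            case_status.append({"case_id": mask.case_id, "status": "ok"})
        except Exception as exc:
            logger.error("case %s failed: %s", path.stem, exc)
            case_status.append({
                "case_id": path.stem, "status": "failed", "reason": str(exc),
            })
    if rows:
        write_table(scores_to_frame(rows), out_dir / "depth_sweep.csv")
    _write_manifest(config, out_dir, "sweep", case_status)
    return 0 if any(c["status"] == "ok" for c in case_status) else 1


def run_null(config: RunConfig) -> int:
    """Random-placement null test per case and marker."""
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry = config.geometry()
    rows = []
    case_status = []
    for path in _discover_cases(config):
        try:
            mask, roi = _load_case(config, path)
            partition = classify_zones(
                mask, band_depth_um=config.band_depth_um, roi=roi,
                tie_break=config.tie_break, connectivity=config.connectivity,
            )
            skipped = []
            for marker in IMMUNE_ROLES:
                try:
                    res = simulate_null(
                        mask, partition, marker,
                        n_reps=config.n_reps, seed=config.seed,
                        compartment=config.null_compartment,
                        geometry=geometry,
                    )
                    rows.append({
                        "case_id": res.case_id, "marker": res.marker,
                        "compartment": res.compartment,
                        "observed_log_ratio": res.observed_log_ratio,
                        "p_empirical": res.p_empirical,
                        "n_cells": res.n_cells,
                        "n_reps": res.n_reps, "seed": res.seed,
                    })
                except ValueError as exc:
                    skipped.append(f"{marker}: {exc}")
            case_status.append({
                "case_id": mask.case_id, "status": "ok", "skipped": skipped,
            })
        except Exception as exc:
            logger.error("case %s failed: %s", path.stem, exc)
            case_status.append({
                "case_id": path.stem, "status": "failed", "reason": str(exc),
            })
    if rows:
        write_table(pd.DataFrame(rows), out_dir / "null_tests.csv")
    _write_manifest(config, out_dir, "null", case_status)
    return 0 if any(c["status"] == "ok" for c in case_status) else 1


def run_synth(spec_path: str | Path | None, out_dir: str | Path,
              n_cases: int, seed: int | None = None) -> int:
    """Generate a synthetic fixture directory loadable by ``run_score``."""
    if spec_path is not None:
        data = yaml.safe_load(Path(spec_path).read_text()) or {}
        if "image_shape" in data:
            data["image_shape"] = tuple(data["image_shape"])
        spec = SyntheticSpec(**data)
    else:
        spec = SyntheticSpec()
    if seed is not None:
        spec.seed = seed
    write_fixture(out_dir, spec, n_cases)
    return 0


def run_report(scores_path: str | Path, metadata_path: str | Path,
               group_columns: list[str], out_dir: str | Path) -> int:
    """Stratified cohort analyses + manual-vs-digital K17 correlation."""
    from .cohort_stats import stratified_analysis

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = pd.read_csv(scores_path, dtype={"case_id": str})
    metadata = read_metadata(metadata_path)
    all_results: list[PairedTestResult] = []
    for col in group_columns:
        all_results.extend(stratified_analysis(scores, metadata, col))
    if all_results:
        df = _tests_frame(all_results)
        write_table(df, out_dir / "stratified_tests.csv")
    lines = ["zonescore stratified report",
             "(no multiplicity adjustment applied)"]
    for r in all_results:
        if r.skipped_reason:
            lines.append(
                f"  [{r.stratum}] {r.marker}/{r.compartment}: "
                f"skipped ({r.skipped_reason})"
            )
        else:
            lines.append(
                f"  [{r.stratum}] {r.marker}/{r.compartment}: "
                f"n={r.n_cases} t={r.t_statistic:+.3f} p={r.p_value:.4g}"
            )
    (out_dir / "stratified_report.txt").write_text("\n".join(lines) + "\n")
    return 0
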