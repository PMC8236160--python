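"""End-to-end QA workflows: calibration runs and patient-specific QA runs.

Configuration is a flat INI file with ``[paths]``, ``[gamma]``,
``[profiles]``, ``[registration]``, ``[calibration]`` and ``[general]``
sections; every CLI flag overrides its config counterpart.  Reports are
plain JSON/CSV and are byte-reproducible for identical inputs (no
timestamps).
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import plane_io, profile_analysis, scan_processing
from .calibration import (
    CalibrationCurve,
    GridGeometry,
    extract_grid_means,
    fit_calibration,
    select_channel,
    standard_grid_doses,
)
from .dose_engine import apply_calibration, saturation_report
from .gamma_analysis import parse_criteria, compute_gamma
from .plane_io import RegistrationSpec
from .planes import DosePlane

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE_PCT = 90.0  # institutional gamma pass-rate tolerance


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class QAConfig:
    scan_paths: list[Path] = field(default_factory=list)
    unexposed_path: Path | None = None
    plan_path: Path | None = None
    calibration_paths: list[Path] = field(default_factory=list)
    detector_path: Path | None = None
    out_dir: Path = Path("radfilm_out")
    criteria: list[str] = field(default_factory=lambda: ["3%/3 mm", "3%/1 mm", "2%/2 mm"])
    modes: list[str] = field(default_factory=lambda: ["absolute", "relative"])
    threshold_pct: float = 10.0
    tolerance_pct: float = DEFAULT_TOLERANCE_PCT
    registration_center_px: tuple[float, float] | None = None  # (row, col); None = film center
    rotation_deg: float = 0.0
    flip_lr: bool = False
    channel: str = "auto"
    profile_mode: str = "relative_sf"
    grid_geometry: GridGeometry = field(default_factory=GridGeometry)
    doses_gy: list[float] = field(default_factory=standard_grid_doses)
    register_scans: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "QAConfig":
        parser = configparser.ConfigParser(interpolation=None)  # criteria contain '%'
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(path)
        cfg = cls()
        base = Path(path).parent

        def _paths(value: str) -> list[Path]:
            return [base / p.strip() for p in value.split(",") if p.strip()]

        if parser.has_section("paths"):
            p = parser["paths"]
            cfg.scan_paths = _paths(p.get("scans", ""))
            if p.get("unexposed"):
                cfg.unexposed_path = base / p["unexposed"]
            if p.get("plan"):
                cfg.plan_path = base / p["plan"]
            cfg.calibration_paths = _paths(p.get("calibration", ""))
            if p.get("detector"):
                cfg.detector_path = base / p["detector"]
            if p.get("out_dir"):
                cfg.out_dir = base / p["out_dir"]
        if parser.has_section("gamma"):
            g = parser["gamma"]
            if g.get("criteria"):
                cfg.criteria = [c.strip() for c in g["criteria"].split(",") if c.strip()]
            if g.get("modes"):
                cfg.modes = [m.strip() for m in g["modes"].split(",") if m.strip()]
            cfg.threshold_pct = g.getfloat("threshold_pct", cfg.threshold_pct)
            cfg.tolerance_pct = g.getfloat("tolerance_pct", cfg.tolerance_pct)
        if parser.has_section("registration"):
            r = parser["registration"]
            if r.get("center_px"):
                row, col = (float(v) for v in r["center_px"].split(","))
                cfg.registration_center_px = (row, col)
            cfg.rotation_deg = r.getfloat("rotation_deg", cfg.rotation_deg)
            cfg.flip_lr = r.getboolean("flip_lr", cfg.flip_lr)
        if parser.has_section("profiles"):
            cfg.profile_mode = parser["profiles"].get("mode", cfg.profile_mode)
        if parser.has_section("calibration"):
            c = parser["calibration"]
            doses = c.get("doses", "standard")
            if doses.strip() != "standard":
                cfg.doses_gy = [float(v) for v in doses.split(",")]
            cfg.grid_geometry = GridGeometry(
                block_size_mm=(c.getfloat("block_size_mm", 40.0),) * 2,
                block_pitch_mm=(c.getfloat("block_pitch_mm", 60.0),) * 2,
                margin_fraction=c.getfloat("margin_fraction", 0.25),
                film_size_mm=(
                    c.getfloat("film_width_mm", 203.2),
                    c.getfloat("film_height_mm", 254.0),
                ),
            )
            cfg.channel = c.get("channel", cfg.channel)
        if parser.has_section("general"):
            cfg.seed = parser["general"].getint("seed", cfg.seed)
            cfg.register_scans = parser["general"].getboolean("register_scans", cfg.register_scans)
        return cfg


# ---------------------------------------------------------------------------


def _load_netod(config: QAConfig) -> scan_processing.NetODMap:
    """Shared front end: read scans, undo orientations, average, netOD."""
    if not config.scan_paths:
        raise ValueError("no scan paths configured")
    for p in list(config.scan_paths) + ([config.unexposed_path] if config.unexposed_path else []):
        if not Path(p).exists():
            raise FileNotFoundError(f"scan file not found: {p}")
    scans = [
        scan_processing.read_scan(p, scan_index=i + 1) for i, p in enumerate(config.scan_paths)
    ]
    aligned = [scan_processing.align_orientation(s) for s in scans]
    averaged = scan_processing.average_scans(aligned, register=config.register_scans)
    logger.info("averaged %d scans; checksum %s", len(aligned), _checksum(averaged.pixels))
    if config.unexposed_path is None:
        raise ValueError("an unexposed reference scan is required")
    unexposed_scan = scan_processing.read_scan(config.unexposed_path)
    unexposed = scan_processing.average_scans([scan_processing.align_orientation(unexposed_scan)])
    netod = scan_processing.compute_netod(averaged, unexposed)
    logger.info("netOD checksum %s", _checksum(netod.netod))
    return netod


def run_calibrate(config: QAConfig) -> dict:
    """Calibration workflow: grid scans → netOD → nine block means → cubic fits.

    Fits red and green curves (blue is carried but never auto-selected) and
    writes ``calibration_<channel>.json`` plus a fit report to
    ``config.out_dir``.  Returns the report dict.
    """
    netod = _load_netod(config)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"doses_gy": list(config.doses_gy), "curves": {}}
    for channel in ("red", "green"):
        points = extract_grid_means(netod, config.grid_geometry, channel)
        for pt, dose in zip(points, config.doses_gy):
            pt.dose_gy = float(dose)
        curve = fit_calibration(points, channel)
        out = config.out_dir / f"calibration_{channel}.json"
        curve.to_json(out)
        report["curves"][channel] = {
            "path": str(out),
            "coefficients": list(curve.coefficients),
            "rms_residual_gy": curve.rms_residual_gy,
            "monotone": curve.monotone,
        }
        logger.info("fitted %s curve, rms residual %.3g Gy", channel, curve.rms_residual_gy)
    (config.out_dir / "calibration_report.json").write_text(json.dumps(report, indent=1))
    return report


def _pick_curve(config: QAConfig, plan_max_gy: float) -> CalibrationCurve:
    curves = [CalibrationCurve.from_json(p) for p in config.calibration_paths]
    if not curves:
        raise ValueError("no calibration curve configured")
    channel = config.channel if config.channel != "auto" else select_channel(plan_max_gy)
    for curve in curves:
        if curve.channel == channel:
            return curve
    raise ValueError(f"no calibration curve for the {channel} channel among {[c.channel for c in curves]}")


def run_psqa(config: QAConfig) -> dict:
    """Patient-specific QA workflow.

    Scans → film dose plane → registration onto the plan grid → gamma for
    every configured (criteria, mode) → central x/y profile comparison →
    JSON + CSV report with a pass/fail verdict at the configured pass-rate
    tolerance (default 90%).
    """
    if config.plan_path is None:
        raise FileNotFoundError("no plan plane configured")
    plan = plane_io.read_plan_plane(config.plan_path)
    netod = _load_netod(config)
    curve = _pick_curve(config, plan.max_dose())
    film = apply_calibration(netod, curve, channel=curve.channel)
    sat = saturation_report(film)

    nrow, ncol = film.shape
    center = config.registration_center_px or ((nrow - 1) / 2.0, (ncol - 1) / 2.0)
    spec = RegistrationSpec(center, rotation_deg=config.rotation_deg, flip_lr=config.flip_lr)
    film_on_plan, _ = plane_io.register_film_to_plan(film, plan, spec)

    rows = []
    for crit_text in config.criteria:
        for mode in config.modes:
            criteria = parse_criteria(
                crit_text, threshold_pct=config.threshold_pct, normalization=mode
            )
            result = compute_gamma(plan, film_on_plan, criteria)
            rows.append(
                {
                    "criteria": criteria.label(),
                    "mode": mode,
                    "pass_rate_pct": result.pass_rate_pct,
                    "mean_gamma": result.mean_gamma,
                    "max_gamma": result.max_gamma,
                    "n_evaluated": result.n_evaluated,
                }
            )

    profiles = {}
    for axis in ("x", "y"):
        ref = profile_analysis.extract_profile(plan, axis)
        meas = profile_analysis.extract_profile(film_on_plan, axis)
        lo = max(ref.positions_mm[0], meas.positions_mm[0])
        hi = min(ref.positions_mm[-1], meas.positions_mm[-1])
        common = ref.positions_mm[(ref.positions_mm >= lo) & (ref.positions_mm <= hi)]
        cmp_ = profile_analysis.compare_profiles(
            profile_analysis.resample_to_positions(meas, common),
            profile_analysis.resample_to_positions(ref, common),
            mode=config.profile_mode,
        )
        profiles[axis] = {
            "mean_abs_diff_pct": cmp_.mean_abs_diff_pct,
            "max_abs_diff_pct": cmp_.max_abs_diff_pct,
            "max_diff_position_mm": cmp_.max_diff_position_mm,
            "sf": cmp_.sf,
        }

    verdict = "PASS" if all(r["pass_rate_pct"] >= config.tolerance_pct for r in rows) else "FAIL"
    report = {
        "verdict": verdict,
        "tolerance_pct": config.tolerance_pct,
        "gamma": rows,
        "profiles": profiles,
        "saturation": sat,
        "plan_max_gy": plan.max_dose(),
        "channel": curve.channel,
        "registration": {
            "center_px": list(center),
            "rotation_deg": config.rotation_deg,
            "flip_lr": config.flip_lr,
            "coverage": film_on_plan.meta.get("registration_coverage"),
        },
    }
    config.out_dir.mkdir(parents=True, exist_ok=True)
    (config.out_dir / "psqa_report.json").write_text(json.dumps(report, indent=1))
    import pandas as pd

    pd.DataFrame(rows).to_csv(config.out_dir / "pass_table.csv", index=False)
    worst = parse_criteria(config.criteria[0], threshold_pct=config.threshold_pct)
    gamma_plane = DosePlane(
        compute_gamma(plan, film_on_plan, worst).gamma_map,
        plan.pixel_spacing_mm,
        plan.origin_mm,
        provenance="film",
        unit="gamma",
        label=f"gamma {worst.label()}",
    )
    plane_io.write_plane(gamma_plane, config.out_dir / "gamma_map.txt")
    logger.info("PSQA verdict: %s", verdict)
    return report
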