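"""Cohort runs: generate eyes, scan both correction modalities, summarize.

Produces the descriptive statistics the study design calls for: uncorrected
Zernike and Seidel refractions and VSX, best spherical and best toric
corrections per modality, and the foci statistics (counts, dioptric
distances, axis differences) per cohort.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .eye import EyeBiometry, compute_is_value, compute_keratometry
from .foci import DEFAULT_THRESHOLD_FRACTION, axis_difference, dioptric_distance, find_foci, summarize_eye
from .generator import CohortParams, default_params, generate_cohort
from .pipeline import analyze_eye, dioptric_pupil_radius
from .refraction import SpherocylRx, rx_to_power_vector
from .scanner import CorrectionEvaluator, ScanConfig, ScanResult, refine_peak, smart_scan
from .viq import VsxEngine

__all__ = ["CohortConfig", "CohortResult", "run_eye", "run_cohort"]


@dataclass
class CohortConfig:
    """Configuration of one cohort run (YAML-serializable)."""

    cohort: str = "normal"
    n_eyes: int = 20
    seed: int = 1
    modalities: tuple = ("spectacle", "scleral")
    scan: ScanConfig = field(default_factory=ScanConfig)
    generator: Optional[CohortParams] = None
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    pupil_grid: int = 256
    pad_factor: int = 2
    refine_steps: Optional[tuple] = (0.25, 0.25, 2.5)
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scan" in raw:
            raw["scan"] = ScanConfig(**raw["scan"])
        if raw.get("generator"):
            raw["generator"] = CohortParams(**raw["generator"])
        if "modalities" in raw:
            raw["modalities"] = tuple(raw["modalities"])
        if raw.get("refine_steps") is not None:
            raw["refine_steps"] = tuple(raw["refine_steps"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["modalities"] = list(self.modalities)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class CohortResult:
    config: CohortConfig
    eyes: list
    records: pd.DataFrame  # one row per eye
    scans: list  # per eye: dict modality -> ScanResult
    summary: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for key, (mean, sd) in self.summary.items():
            rows.append({"quantity": key, "mean": mean, "sd": sd})
        return pd.DataFrame(rows)


def run_eye(
    eye: EyeBiometry,
    config: CohortConfig,
    engine: Optional[VsxEngine] = None,
) -> tuple:
    """Uncorrected analysis plus smart scans of every modality for one eye.

    Returns (record dict, scans dict)."""
    engine = engine or VsxEngine(pupil_grid=config.pupil_grid, pad_factor=config.pad_factor)
    r_d = dioptric_pupil_radius(eye)
    an = analyze_eye(eye, dioptric_radius_mm=r_d)
    zrx, srx = an.zernike_rx, an.seidel_rx
    record = {
        "label": eye.label,
        "Kmax_D": compute_keratometry(eye)["Kmax"],
        "IS_D": compute_is_value(eye),
        "axial_length_mm": eye.axial_length_mm,
        "uncorrected_vsx": engine.vsx(an.wavefront),
        "seidel_sphere_D": srx.sphere_D,
        "seidel_cyl_D": srx.cylinder_D,
        "seidel_axis_deg": srx.axis_deg,
        "zernike_sphere_D": zrx.sphere_D,
        "zernike_cyl_D": zrx.cylinder_D,
        "zernike_axis_deg": zrx.axis_deg,
    }
    scans = {}
    evaluators = {}
    for modality in config.modalities:
        evaluator = CorrectionEvaluator(eye, modality, engine=engine)
        evaluators[modality] = evaluator
        anchor = srx.sphere_D if modality == "spectacle" else 0.0
        result = smart_scan(evaluator, anchor, config.scan, modality)
        scans[modality] = result
        best_rx, best_vsx = result.best_rx, result.best_vsx
        sph_rx, sph_vsx = result.spherical_best_rx, result.spherical_best_vsx
        if config.refine_steps is not None:
            best_rx, best_vsx = refine_peak(evaluator, best_rx, config.refine_steps)
            # sphere-only hill climb at the fine step for the spherical best
            step = config.refine_steps[0]
            s = round(sph_rx.sphere_D / step) * step
            sph_rx = SpherocylRx(s, 0.0, 0.0)
            sph_vsx = evaluator.vsx(sph_rx)
            for _ in range(20):
                cands = [SpherocylRx(s - step, 0.0, 0.0), SpherocylRx(s + step, 0.0, 0.0)]
                vals = [evaluator.vsx(c) for c in cands]
                j = int(np.argmax(vals))
                if vals[j] <= sph_vsx + 1e-12:
                    break
                sph_rx, sph_vsx = cands[j], vals[j]
                s = sph_rx.sphere_D
        record.update(
            {
                f"{modality}_spherical_best_D": sph_rx.sphere_D,
                f"{modality}_spherical_vsx": sph_vsx,
                f"{modality}_toric_sphere_D": best_rx.sphere_D,
                f"{modality}_toric_cyl_D": best_rx.cylinder_D,
                f"{modality}_toric_axis_deg": best_rx.axis_deg,
                f"{modality}_toric_vsx": best_vsx,
                f"{modality}_n_evaluations": result.n_evaluations,
                f"{modality}_low_ceiling": result.low_ceiling_warning,
            }
        )
    foci_summary = summarize_eye(
        scans, threshold_fraction=config.threshold_fraction, evaluators=evaluators
    )
    for modality, entry in foci_summary.items():
        record[f"{modality}_n_foci"] = entry["n_foci"]
        record[f"{modality}_focus_distance_D"] = entry["focus_distance_D"]
        ad = entry["axis_difference_deg"]
        record[f"{modality}_axis_diff_deg"] = None if ad is None else ad["unfolded"]
        record[f"{modality}_axis_diff_folded_deg"] = None if ad is None else ad["folded"]
    return record, scans


def _mean_sd(series) -> tuple:
    vals = pd.to_numeric(series, errors="coerce").dropna()
    if len(vals) == 0:
        return (math.nan, math.nan)
    return (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)


def run_cohort(config: CohortConfig) -> CohortResult:
    """Generate and analyze a full cohort; deterministic in the seed."""
    engine = VsxEngine(pupil_grid=config.pupil_grid, pad_factor=config.pad_factor)
    params = config.generator or default_params(config.cohort)
    eyes = generate_cohort(config.n_eyes, config.cohort, config.seed, params)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    records = []
    all_scans = []
    failures = 0
    for i, eye in enumerate(eyes):
        try:
            record, scans = run_eye(eye, config, engine)
        except Exception as err:  # per-eye failures logged and excluded
            failures += 1
            records.append({"label": eye.label, "error": str(err)})
            all_scans.append({})
            continue
        record["eye_index"] = i
        records.append(record)
        all_scans.append(scans)
        if outdir is not None:
            eye.to_json(outdir / f"eye_{i:02d}.json")
            for modality, res in scans.items():
                res.to_csv(outdir / f"eye_{i:02d}_{modality}_cloud.csv")
    frame = pd.DataFrame(records)
    summary = {}
    for col in frame.columns:
        if col in ("label", "error", "eye_index") or frame[col].dtype == object:
            continue
        summary[col] = _mean_sd(frame[col])
    for modality in config.modalities:
        col = f"{modality}_n_foci"
        if col in frame:
            counts = frame[col].dropna().astype(int)
            summary[f"{modality}_two_foci_eyes"] = (
                int((counts == 2).sum()),
                0.0,
            )
    summary["n_failures"] = (failures, 0.0)
    result = CohortResult(config, eyes, frame, all_scans, summary)
    if outdir is not None:
        frame.to_csv(outdir / "per_eye.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump({k: list(v) for k, v in summary.items()}, fh, indent=2)
    return result
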