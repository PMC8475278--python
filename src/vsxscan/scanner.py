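"""Smart scanning of the spherocylindrical correction space.

The scan ladder:

* **spherical scan** - every sphere in 0.25-D steps over +/-10 D around the
  uncorrected Seidel refraction (spectacles) or a plano lens (sclerals);
* **stage A** - coarse spherocylindrical grid (1-D sphere and cylinder
  steps, 10-degree axis steps) over the modality's sphere half-range
  (+/-7 D spectacles, +/-3 D sclerals) around the best sphere;
* **stage B** - all corrections within +/-0.5 D (sphere, cylinder) and
  +/-5 degrees of every stage-A point with VSX > 0.03;
* **stage C** - all corrections within +/-0.25 D and +/-2.5 degrees of every
  stage-B point with VSX > 0.01, on the final phoropter grid
  (0.25 D / 0.25 D / 2.5 degrees).

Every prescription lies on the final grid (coarser stages are integer
multiples of it); duplicate grid points are evaluated once through a cache.
Every point gets a full PSF evaluation: in highly aberrated eyes the best
corrections can sit many diopters away from the paraxial (Seidel)
refraction - that is the multifocal phenomenon under study - so no
residual-blur shortcut is sound.  Far from focus the finite pupil grid
undersamples the wavefront, but the resulting VSX stays well below the
ladder thresholds (checked in the tests), so aliased evaluations can never
seed refinement stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .correction import make_correction
from .eye import EyeBiometry
from .pipeline import analyze_eye, dioptric_pupil_radius
from .raytrace import TraceError, pupil_samples
from .refraction import PowerVector, SpherocylRx, rx_to_power_vector
from .viq import VsxEngine

__all__ = [
    "ScanConfig",
    "ScanResult",
    "CorrectionEvaluator",
    "spherical_scan",
    "smart_scan",
    "exhaustive_scan",
    "refine_peak",
]


@dataclass
class ScanConfig:
    """Grid ladder parameters (diopters and degrees)."""

    sphere_step: float = 0.25
    cyl_step: float = 0.25
    axis_step: float = 2.5
    spherical_scan_halfrange: float = 10.0
    sphere_halfrange_spectacle: float = 7.0
    sphere_halfrange_scleral: float = 3.0
    coarse_sphere_step: float = 1.0
    coarse_cyl_step: float = 1.0
    coarse_axis_step: float = 10.0
    refine1_d: float = 0.5
    refine1_axis_deg: float = 5.0
    keep_threshold_1: float = 0.03
    keep_threshold_2: float = 0.01
    cylinder_min: float = -16.0

    def __post_init__(self) -> None:
        if not (0 < self.keep_threshold_2 <= self.keep_threshold_1 < 1):
            raise ValueError("thresholds must satisfy 0 < t2 <= t1 < 1")
        for name in ("sphere_step", "cyl_step", "axis_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for coarse, fine in (
            (self.coarse_sphere_step, self.sphere_step),
            (self.coarse_cyl_step, self.cyl_step),
            (self.coarse_axis_step, self.axis_step),
            (self.refine1_d, self.sphere_step),
            (self.refine1_axis_deg, self.axis_step),
        ):
            if abs(round(coarse / fine) - coarse / fine) > 1e-9:
                raise ValueError("stage steps must be integer multiples of the final steps")
        if abs(round(180.0 / self.axis_step) - 180.0 / self.axis_step) > 1e-9:
            raise ValueError("axis step must divide 180 degrees")

    def sphere_halfrange(self, modality: str) -> float:
        return (
            self.sphere_halfrange_spectacle
            if modality == "spectacle"
            else self.sphere_halfrange_scleral
        )

    @property
    def axis_period(self) -> int:
        return int(round(180.0 / self.axis_step))


@dataclass
class ScanResult:
    """Point cloud and bookkeeping of one smart scan."""

    cloud: pd.DataFrame
    best_rx: SpherocylRx
    best_vsx: float
    anchor_sphere_D: float
    modality: str
    config: ScanConfig
    spherical_best_rx: SpherocylRx
    spherical_best_vsx: float
    n_evaluations: int
    low_ceiling_warning: bool = False  # no stage-A point above threshold 1

    def to_csv(self, path) -> None:
        self.cloud.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        import json

        payload = {
            "modality": self.modality,
            "anchor_sphere_D": self.anchor_sphere_D,
            "best_rx": vars(self.best_rx).copy(),
            "best_vsx": self.best_vsx,
            "spherical_best_rx": vars(self.spherical_best_rx).copy(),
            "spherical_best_vsx": self.spherical_best_vsx,
            "n_evaluations": self.n_evaluations,
            "low_ceiling_warning": self.low_ceiling_warning,
            "points": self.cloud.to_dict(orient="records"),
        }
        txt = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(txt)
        return txt


class CorrectionEvaluator:
    """Cached VSX of (modality, prescription) pairs for one eye."""

    def __init__(
        self,
        eye: EyeBiometry,
        modality: str,
        engine: Optional[VsxEngine] = None,
    ):
        self.eye = eye
        self.modality = modality
        self.engine = engine or _shared_engine()
        self.dioptric_radius_mm = dioptric_pupil_radius(eye)
        self.samples = pupil_samples()
        self.cache: dict = {}
        self.n_trace_failures = 0

    @staticmethod
    def key(rx: SpherocylRx) -> tuple:
        return (
            int(round(rx.sphere_D * 1000)),
            int(round(rx.cylinder_D * 1000)),
            int(round((rx.axis_deg % 180.0) * 100)),
        )

    def vsx(self, rx: SpherocylRx) -> float:
        k = self.key(rx)
        v = self.cache.get(k)
        if v is None:
            v = self._evaluate(rx)
            self.cache[k] = v
        return v

    __call__ = vsx

    def _evaluate(self, rx: SpherocylRx) -> float:
        try:
            lens = make_correction(rx, self.modality)
            an = analyze_eye(
                self.eye,
                lens,
                samples_norm=self.samples,
                dioptric_radius_mm=self.dioptric_radius_mm,
            )
        except (TraceError, ValueError):
            self.n_trace_failures += 1
            return 0.0
        return self.engine.vsx(an.wavefront)


_ENGINE: Optional[VsxEngine] = None


def _shared_engine() -> VsxEngine:
    global _ENGINE
    if _ENGINE is None:
        _ENGINE = VsxEngine()
    return _ENGINE


# --------------------------------------------------------------------------
# Grid arithmetic: lattice integers (sphere, cylinder, axis) in final steps


def _rx_from_lattice(i_s: int, i_c: int, i_a: int, cfg: ScanConfig) -> SpherocylRx:
    cyl = min(i_c * cfg.cyl_step, 0.0)
    if abs(cyl) < 1e-12:
        return SpherocylRx(i_s * cfg.sphere_step, 0.0, 0.0)
    axis = (i_a % cfg.axis_period) * cfg.axis_step
    return SpherocylRx(i_s * cfg.sphere_step, cyl, axis)


def _canonical(i_s: int, i_c: int, i_a: int, cfg: ScanConfig) -> tuple:
    if i_c >= 0:
        return (i_s, 0, 0)
    return (i_s, i_c, i_a % cfg.axis_period)


def _tiebreak_key(rx: SpherocylRx, v: float) -> tuple:
    # maximize vsx; ties: smaller |sphere|, then smaller |cylinder|, then axis
    return (-v, abs(rx.sphere_D), abs(rx.cylinder_D), rx.axis_deg)


def spherical_scan(
    evaluate: Callable[[SpherocylRx], float],
    anchor_sphere_D: float,
    cfg: ScanConfig,
) -> tuple:
    """Best spherical correction over anchor +/- the spherical half-range.

    Returns (best_rx, best_vsx, trace) where ``trace`` lists every
    (rx, vsx) evaluated, in scan order."""
    anchor_i = int(round(anchor_sphere_D / cfg.sphere_step))
    half_i = int(round(cfg.spherical_scan_halfrange / cfg.sphere_step))
    results = []
    for i in range(anchor_i - half_i, anchor_i + half_i + 1):
        rx = SpherocylRx(i * cfg.sphere_step, 0.0, 0.0)
        results.append((rx, evaluate(rx)))
    if not any(np.isfinite(v) and v > 0 for _, v in results):
        raise RuntimeError("all spherical evaluations failed")
    best_rx, best_v = min(results, key=lambda t: _tiebreak_key(*t))
    return best_rx, best_v, results


def smart_scan(
    evaluate: Callable[[SpherocylRx], float],
    anchor_sphere_D: float,
    cfg: ScanConfig,
    modality: str = "spectacle",
) -> ScanResult:
    """Three-stage coarse-to-fine scan around the best spherical correction.

    ``evaluate`` maps a prescription to VSX (a stub surface in tests, the
    traced metric in production)."""
    cache: dict = {}

    def ev(latt) -> float:
        k = _canonical(*latt, cfg)
        v = cache.get(k)
        if v is None:
            v = evaluate(_rx_from_lattice(*k, cfg))
            cache[k] = v
        return v

    stage_of: dict = {}

    # ---- spherical scan
    anchor_i = int(round(anchor_sphere_D / cfg.sphere_step))
    half_i = int(round(cfg.spherical_scan_halfrange / cfg.sphere_step))
    sph_results = []
    for i in range(anchor_i - half_i, anchor_i + half_i + 1):
        k = (i, 0, 0)
        v = ev(k)
        stage_of.setdefault(k, "spherical")
        sph_results.append((_rx_from_lattice(*k, cfg), v))
    if not any(np.isfinite(v) and v > 0 for _, v in sph_results):
        raise RuntimeError("all spherical evaluations failed")
    sph_rx, sph_v = min(sph_results, key=lambda t: _tiebreak_key(*t))
    best_i = int(round(sph_rx.sphere_D / cfg.sphere_step))

    # ---- stage A: coarse grid
    cs = int(round(cfg.coarse_sphere_step / cfg.sphere_step))
    cc = int(round(cfg.coarse_cyl_step / cfg.cyl_step))
    ca = int(round(cfg.coarse_axis_step / cfg.axis_step))
    half = int(round(cfg.sphere_halfrange(modality) / cfg.sphere_step))
    cmin = int(round(cfg.cylinder_min / cfg.cyl_step))
    stage_a = []
    for i_s in range(best_i - half, best_i + half + 1, cs):
        for i_c in range(0, cmin - 1, -cc):
            axes = [0] if i_c == 0 else range(0, cfg.axis_period, ca)
            for i_a in axes:
                k = _canonical(i_s, i_c, i_a, cfg)
                ev(k)
                stage_of.setdefault(k, "A")
                stage_a.append(k)

    survivors = [k for k in stage_a if cache[k] > cfg.keep_threshold_1]
    low_ceiling = len(survivors) == 0

    # ---- stage B: +/- refine1 neighborhoods at half-steps
    r1s = int(round(cfg.refine1_d / cfg.sphere_step))
    r1c = int(round(cfg.refine1_d / cfg.cyl_step))
    r1a = int(round(cfg.refine1_axis_deg / cfg.axis_step))
    stage_b = set()
    for (i_s, i_c, i_a) in survivors:
        for ds in (-r1s, 0, r1s):
            for dc in (-r1c, 0, r1c):
                for da in (-r1a, 0, r1a):
                    k = _canonical(i_s + ds, min(i_c + dc, 0), i_a + da, cfg)
                    if k[1] < cmin:
                        continue
                    ev(k)
                    stage_of.setdefault(k, "B")
                    stage_b.add(k)

    # ---- stage C: final-step neighborhoods of stage-B points above t2
    parents_c = [k for k in stage_b if cache[k] > cfg.keep_threshold_2]
    for (i_s, i_c, i_a) in parents_c:
        for ds in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for da in (-1, 0, 1):
                    k = _canonical(i_s + ds, min(i_c + dc, 0), i_a + da, cfg)
                    if k[1] < cmin:
                        continue
                    ev(k)
                    stage_of.setdefault(k, "C")

    rows = []
    for k, v in cache.items():
        rx = _rx_from_lattice(*k, cfg)
        pv = rx_to_power_vector(rx)
        rows.append(
            (
                rx.sphere_D,
                rx.cylinder_D,
                rx.axis_deg,
                pv.M,
                pv.J0,
                pv.J45,
                v,
                math.log10(v) if v > 0 else -np.inf,
                stage_of.get(k, "C"),
            )
        )
    cloud = pd.DataFrame(
        rows,
        columns=["sphere", "cylinder", "axis", "M", "J0", "J45", "vsx", "log_vsx", "stage"],
    ).sort_values(["sphere", "cylinder", "axis"], kind="mergesort", ignore_index=True)

    best_k = min(cache, key=lambda k: _tiebreak_key(_rx_from_lattice(*k, cfg), cache[k]))
    best_rx = _rx_from_lattice(*best_k, cfg)
    return ScanResult(
        cloud=cloud,
        best_rx=best_rx,
        best_vsx=cache[best_k],
        anchor_sphere_D=anchor_sphere_D,
        modality=modality,
        config=cfg,
        spherical_best_rx=sph_rx,
        spherical_best_vsx=sph_v,
        n_evaluations=len(cache),
        low_ceiling_warning=low_ceiling,
    )


def exhaustive_scan(
    evaluate: Callable[[SpherocylRx], float],
    anchor_sphere_D: float,
    cfg: ScanConfig,
    modality: str = "spectacle",
) -> tuple:
    """Full final-grid search over the same bounds as the smart scan; used
    as the completeness oracle in tests (exponentially more evaluations)."""
    sph_rx, _, _ = spherical_scan(evaluate, anchor_sphere_D, cfg)
    best_i = int(round(sph_rx.sphere_D / cfg.sphere_step))
    half = int(round(cfg.sphere_halfrange(modality) / cfg.sphere_step))
    cmin = int(round(cfg.cylinder_min / cfg.cyl_step))
    best = None
    for i_s in range(best_i - half, best_i + half + 1):
        for i_c in range(0, cmin - 1, -1):
            axes = [0] if i_c == 0 else range(cfg.axis_period)
            for i_a in axes:
                rx = _rx_from_lattice(i_s, i_c, i_a, cfg)
                v = evaluate(rx)
                cand = (_tiebreak_key(rx, v), rx, v)
                if best is None or cand[0] < best[0]:
                    best = cand
    return best[1], best[2]


def refine_peak(
    evaluate: Callable[[SpherocylRx], float],
    start_rx: SpherocylRx,
    steps=(0.25, 0.25, 2.5),
    max_moves: int = 40,
) -> tuple:
    """Greedy hill climb on a fine local grid around a scan's argmax.

    Keeps reported best corrections at phoropter resolution even when the
    scan itself ran on a coarsened lattice."""
    s_step, c_step, a_step = steps
    cur = SpherocylRx.normalized(
        round(start_rx.sphere_D / s_step) * s_step,
        min(round(start_rx.cylinder_D / c_step) * c_step, 0.0),
        round(start_rx.axis_deg / a_step) * a_step,
    )
    cur_v = evaluate(cur)
    for _ in range(max_moves):
        best_n, best_v = None, cur_v
        for ds in (-s_step, 0.0, s_step):
            for dc in (-c_step, 0.0, c_step):
                for da in (-a_step, 0.0, a_step):
                    if ds == dc == da == 0.0:
                        continue
                    cyl = min(cur.cylinder_D + dc, 0.0)
                    cand = SpherocylRx.normalized(cur.sphere_D + ds, cyl, cur.axis_deg + da)
                    v = evaluate(cand)
                    if v > best_v + 1e-12:
                        best_n, best_v = cand, v
        if best_n is None:
            break
        cur, cur_v = best_n, best_v
    return cur, cur_v
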