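"""Foci of a correction-space cloud: superlevel-set components and their
dioptric separations.

A *focus* is a local-maximum region of VSX in correction space: keep every
point with VSX >= (2/3) x max(VSX), link kept points that are adjacent on
the final scan lattice (26-neighborhood in sphere x cylinder x axis with the
axis wrapping at 180 degrees), and call each connected component one focus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .refraction import PowerVector, SpherocylRx, power_vector_to_rx, rx_to_power_vector

__all__ = [
    "Focus",
    "find_foci",
    "merge_connected_foci",
    "dioptric_distance",
    "axis_difference",
    "summarize_eye",
]

DEFAULT_THRESHOLD_FRACTION = 2.0 / 3.0


@dataclass
class Focus:
    """One local-maximum region of the correction-space cloud."""

    peak_rx: SpherocylRx
    peak_vsx: float
    member_index: np.ndarray  # row indices into the source cloud
    centroid_pv: PowerVector

    @property
    def n_members(self) -> int:
        return len(self.member_index)


def _lattice(cloud: pd.DataFrame, steps) -> np.ndarray:
    s_step, c_step, a_step = steps
    i_s = np.round(cloud["sphere"].to_numpy() / s_step).astype(int)
    i_c = np.round(cloud["cylinder"].to_numpy() / c_step).astype(int)
    i_a = np.round(cloud["axis"].to_numpy() / a_step).astype(int)
    return np.stack([i_s, i_c, i_a], axis=1)


def find_foci(
    cloud: pd.DataFrame,
    steps=(0.25, 0.25, 2.5),
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    neighbor_multiple: int = 1,
) -> list:
    """Distinct foci of a scan cloud under the two-thirds-of-maximum rule.

    ``steps`` are the final lattice steps (sphere D, cylinder D, axis deg)
    the cloud was scanned on; adjacency is a 26-neighborhood on that
    lattice with the axis index wrapping at 180 degrees.
    ``neighbor_multiple`` widens the adjacency to that many lattice steps -
    used when the superlevel set contains only coarse-stage points, whose
    spacing is a multiple of the final step.  Returns foci sorted by peak
    VSX, descending.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    if "M" not in cloud.columns:  # externally supplied CSVs may omit the
        cloud = cloud.copy()  # power-vector columns; derive them
        pvs = [
            rx_to_power_vector(SpherocylRx.normalized(s, c, a))
            for s, c, a in zip(cloud["sphere"], cloud["cylinder"], cloud["axis"])
        ]
        cloud["M"] = [p.M for p in pvs]
        cloud["J0"] = [p.J0 for p in pvs]
        cloud["J45"] = [p.J45 for p in pvs]
    if neighbor_multiple > 1:
        steps = tuple(s * neighbor_multiple for s in steps)
        # indices round to the coarser lattice; colliding points merge
    axis_period = max(int(round(180.0 / steps[2])), 1)
    vsx = cloud["vsx"].to_numpy()
    vmax = float(np.max(vsx))
    keep = np.where(vsx >= threshold_fraction * vmax)[0]
    latt = _lattice(cloud, steps)
    index_of: dict = {}
    for row in keep:
        i_s, i_c, i_a = latt[row]
        key = (i_s, i_c, i_a % axis_period) if i_c < 0 else (i_s, i_c, 0)
        index_of.setdefault(key, []).append(row)

    seen = set()
    foci = []
    for start in index_of:
        if start in seen:
            continue
        comp = []
        stack = [start]
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.extend(index_of[node])
            i_s, i_c, i_a = node
            for ds in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    for da in (-1, 0, 1):
                        if ds == dc == da == 0:
                            continue
                        nc = i_c + dc
                        nb = (
                            (i_s + ds, nc, (i_a + da) % axis_period)
                            if nc < 0
                            else (i_s + ds, nc, 0)
                        )
                        if nb in index_of and nb not in seen:
                            seen.add(nb)
                            stack.append(nb)
        comp = np.asarray(sorted(comp))
        sub = cloud.iloc[comp]
        peak_row = sub["vsx"].idxmax()
        peak = cloud.loc[peak_row]
        peak_rx = SpherocylRx.normalized(
            float(peak["sphere"]), float(peak["cylinder"]), float(peak["axis"])
        )
        centroid = PowerVector(
            float(sub["M"].mean()), float(sub["J0"].mean()), float(sub["J45"].mean())
        )
        foci.append(
            Focus(
                peak_rx=peak_rx,
                peak_vsx=float(peak["vsx"]),
                member_index=comp,
                centroid_pv=centroid,
            )
        )
    foci.sort(key=lambda f: -f.peak_vsx)
    return foci


def merge_connected_foci(
    foci: list,
    evaluate,
    threshold_vsx: float,
    step_D: float = 0.25,
    max_pair_distance_D: float = 12.0,
) -> list:
    """Merge candidate foci that a fine-resolution path check connects.

    On a scaled-down scan lattice a single ridge can fragment into several
    superlevel components because the intermediate prescriptions were never
    evaluated.  For every focus pair closer than ``max_pair_distance_D``
    this re-evaluates VSX along the straight segment between the two peak
    prescriptions in (M, J0, J45) space at ``step_D`` resolution; if the
    whole segment stays at or above ``threshold_vsx`` the two components
    are genuinely one superlevel region and are merged.  The check is
    conservative: a curved connecting ridge may still be counted as two
    foci, exactly as the lattice criterion would.
    """
    n = len(foci)
    if n < 2:
        return foci
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a = rx_to_power_vector(foci[i].peak_rx).as_array()
            b = rx_to_power_vector(foci[j].peak_rx).as_array()
            dist = float(np.linalg.norm(a - b))
            if dist > max_pair_distance_D or dist < 1e-9:
                connected = dist < 1e-9
            else:
                nseg = max(2, int(math.ceil(dist / step_D)))
                connected = True
                for t in range(1, nseg):
                    p = a + (b - a) * (t / nseg)
                    rx = power_vector_to_rx(PowerVector(*p))
                    if evaluate(rx) < threshold_vsx:
                        connected = False
                        break
            if connected and find(i) != find(j):
                parent[find(j)] = find(i)

    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members in groups.values():
        fs = [foci[i] for i in members]
        best = max(fs, key=lambda f: f.peak_vsx)
        idx = np.unique(np.concatenate([f.member_index for f in fs]))
        ms = [rx_to_power_vector(f.peak_rx) for f in fs]
        centroid = PowerVector(
            float(np.mean([f.centroid_pv.M for f in fs])),
            float(np.mean([f.centroid_pv.J0 for f in fs])),
            float(np.mean([f.centroid_pv.J45 for f in fs])),
        )
        merged.append(
            Focus(
                peak_rx=best.peak_rx,
                peak_vsx=best.peak_vsx,
                member_index=idx,
                centroid_pv=centroid,
            )
        )
    merged.sort(key=lambda f: -f.peak_vsx)
    return merged


def dioptric_distance(f1, f2) -> float:
    """Euclidean distance between two focus peaks in (M, J0, J45) space."""
    rx1 = f1.peak_rx if isinstance(f1, Focus) else f1
    rx2 = f2.peak_rx if isinstance(f2, Focus) else f2
    a = rx_to_power_vector(rx1).as_array()
    b = rx_to_power_vector(rx2).as_array()
    return float(np.linalg.norm(a - b))


def axis_difference(f1, f2) -> dict:
    """Cylinder-axis difference between two foci, in degrees.

    Returns both conventions: ``unfolded`` is the raw |a1 - a2| of axis
    values in [0, 180) and ``folded`` the minimal meridian angle
    (<= 90 degrees).  Undefined (None) when either focus has zero cylinder.
    """
    rx1 = f1.peak_rx if isinstance(f1, Focus) else f1
    rx2 = f2.peak_rx if isinstance(f2, Focus) else f2
    if abs(rx1.cylinder_D) < 1e-12 or abs(rx2.cylinder_D) < 1e-12:
        return {"unfolded": None, "folded": None}
    d = abs(rx1.axis_deg - rx2.axis_deg)
    return {"unfolded": d, "folded": min(d, 180.0 - d)}


def summarize_eye(
    scans: dict,
    steps=(0.25, 0.25, 2.5),
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    evaluators: Optional[dict] = None,
) -> dict:
    """Per-eye record over correction modalities.

    ``scans`` maps modality name to a ScanResult (or any object with
    ``cloud``, ``best_rx``, ``best_vsx``, ``low_ceiling_warning``).
    Records the foci count per modality, the best prescription and VSX, and
    the inter-focus distance and axis difference when two or more foci are
    present.  When ``evaluators`` supplies a VSX callable per modality,
    candidate foci on coarsened lattices are additionally verified with the
    fine-resolution path check of :func:`merge_connected_foci`.
    """
    record: dict = {}
    for modality, scan in scans.items():
        steps_here = steps
        mult = 1
        cfg = getattr(scan, "config", None)
        if cfg is not None:
            steps_here = (cfg.sphere_step, cfg.cyl_step, cfg.axis_step)
            cloud = scan.cloud
            vmax = float(cloud["vsx"].max())
            top = cloud[cloud["vsx"] >= threshold_fraction * vmax]
            if not top["stage"].isin(["B", "C"]).all():
                # superlevel set contains coarse-stage points: widen the
                # adjacency to the coarse lattice so isolated coarse samples
                # of one region are not counted as separate foci
                mult = max(
                    int(round(cfg.coarse_sphere_step / cfg.sphere_step)),
                    int(round(cfg.coarse_cyl_step / cfg.cyl_step)),
                    int(round(cfg.coarse_axis_step / cfg.axis_step)),
                )
        foci = find_foci(scan.cloud, steps_here, threshold_fraction, neighbor_multiple=mult)
        if evaluators is not None and modality in evaluators and len(foci) > 1:
            thresh = threshold_fraction * float(scan.cloud["vsx"].max())
            foci = merge_connected_foci(foci, evaluators[modality], thresh)
        entry = {
            "n_foci": len(foci),
            "best_rx": scan.best_rx,
            "best_vsx": scan.best_vsx,
            "low_ceiling_warning": bool(getattr(scan, "low_ceiling_warning", False)),
            "foci": foci,
            "focus_distance_D": None,
            "axis_difference_deg": None,
        }
        if len(foci) >= 2:
            entry["focus_distance_D"] = dioptric_distance(foci[0], foci[1])
            entry["axis_difference_deg"] = axis_difference(foci[0], foci[1])
        record[modality] = entry
    return record
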