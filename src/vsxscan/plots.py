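"""Double-angle correction-space plots and chart-image export."""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["double_angle_coordinates", "export_double_angle", "save_image_png"]


def double_angle_coordinates(cloud: pd.DataFrame) -> pd.DataFrame:
    """Cylindrical double-angle coordinates of a correction cloud.

    The cylinder magnitude is the radius at twice the axis angle (so axes
    theta and theta+180 map to the same point) and the sphere is the
    vertical coordinate: x = |C| cos(2 axis), y = |C| sin(2 axis), z = S.
    """
    c = np.abs(cloud["cylinder"].to_numpy())
    two_ax = np.radians(2.0 * cloud["axis"].to_numpy())
    out = cloud.copy()
    out["x_da"] = c * np.cos(two_ax)
    out["y_da"] = c * np.sin(two_ax)
    out["z_da"] = cloud["sphere"].to_numpy()
    return out


def export_double_angle(cloud: pd.DataFrame, png_path=None, csv_path=None, title=""):
    """Render the cloud as a 3-D double-angle scatter colored/sized by
    logVSX (cooler colors and larger markers = better VSX)."""
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    da = double_angle_coordinates(cloud)
    if csv_path is not None:
        da.to_csv(csv_path, index=False)
    if png_path is None:
        return da
    finite = np.isfinite(da["log_vsx"].to_numpy())
    d = da[finite]
    lv = d["log_vsx"].to_numpy()
    lv_clip = np.clip(lv, -4.0, 0.0)
    size = 4.0 + 40.0 * (lv_clip + 4.0) / 4.0
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(111, projection="3d")
    sc = ax.scatter(
        d["x_da"], d["y_da"], d["z_da"], c=lv_clip, s=size, cmap="viridis_r", alpha=0.7
    )
    ax.set_xlabel("|C| cos 2$\\theta$ (D)")
    ax.set_ylabel("|C| sin 2$\\theta$ (D)")
    ax.set_zlabel("sphere (D)")
    ax.set_title(title or "correction space (double-angle)")
    fig.colorbar(sc, label="log10 VSX", shrink=0.6)
    fig.tight_layout()
    fig.savefig(png_path, dpi=110)
    plt.close(fig)
    return da


def save_image_png(image: np.ndarray, path, pixel_scale_arcmin: float) -> None:
    """Save a luminance image as 16-bit PNG with a JSON sidecar recording
    the angular pixel scale."""
    from PIL import Image

    arr = np.asarray(image, float)
    lo, hi = float(arr.min()), float(arr.max())
    scaled = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo)
    img = Image.fromarray((scaled * 65535).astype(np.uint16))
    img.save(path)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(
        json.dumps({"pixel_scale_arcmin": pixel_scale_arcmin, "min": lo, "max": hi})
    )
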