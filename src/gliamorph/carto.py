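"""2D in-situ cartography: colour-coded single-cell maps over the mosaic.

Each retained cell is drawn as a glyph at its centroid over the (dimmed)
projection.  Three colour modes:

* ``gradient`` — the rank of the z-scored CI + CEA composite, mapped on a
  yellow-to-red scale (low complexity/territory -> yellow, high -> red);
* ``cluster`` — the k-means cluster index, categorical palette;
* ``subpopulation`` — SP1-SP4 / amoeboid, categorical palette.

Rendering is a pure array operation with a fixed LUT — identical inputs
always produce identical PNG bytes — and every plotted value is echoed to
a machine-readable annotation table.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import matplotlib
import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .errors import DataError

__all__ = ["render_cartography", "CATEGORY_COLORS"]

matplotlib.use("Agg")

#: fixed categorical palette (RGB, 0-255)
CATEGORY_COLORS: dict[str, tuple[int, int, int]] = {
    "SP1": (255, 237, 111),
    "SP2": (254, 178, 76),
    "SP3": (252, 108, 37),
    "SP4": (215, 25, 28),
    "amoeboid": (120, 198, 255),
    "0": (215, 25, 28),
    "1": (253, 174, 97),
    "2": (171, 221, 164),
    "3": (43, 131, 186),
}


def _gradient_lut(n: int = 256) -> np.ndarray:
    cmap = matplotlib.colormaps["autumn_r"]  # yellow -> red
    return (np.asarray(cmap(np.linspace(0, 1, n)))[:, :3] * 255).astype(np.uint8)


def render_cartography(
    records: pd.DataFrame,
    mode: str = "gradient",
    background: np.ndarray | None = None,
    pixel_size_um: float = 0.19,
    glyph_radius_um: float = 3.0,
    out_png: str | Path | None = None,
    out_csv: str | Path | None = None,
    value_column: str | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the cartography; returns (RGB image, annotation table).

    ``background`` is a grayscale raster; records outside its bounds are
    clipped with a warning column in the annotations.  In gradient mode
    the composite score is the rank of z(CI) + z(CEA) normalized to
    [0, 1]; the two extremes always receive the scale's end colours.
    """
    if mode not in ("gradient", "cluster", "subpopulation"):
        raise DataError(f"unknown cartography mode {mode!r}")
    if background is None:
        w = int(np.ceil(records["centroid_x_um"].max() / pixel_size_um)) + 50 if len(records) else 100
        h = int(np.ceil(records["centroid_y_um"].max() / pixel_size_um)) + 50 if len(records) else 100
        background = np.zeros((h, w), dtype=np.float32)
    bg = np.asarray(background, dtype=np.float32)
    if bg.max() > 0:
        bg = bg / bg.max()
    rgb = (np.stack([bg, bg, bg], axis=-1) * 110).astype(np.uint8)

    ann = records.copy()
    if len(records):
        if mode == "gradient":
            ci = records["CI"].to_numpy(dtype=float)
            cea = records["CEA_um2"].to_numpy(dtype=float)
            z = np.zeros(len(records))
            for v in (ci, cea):
                sd = v.std()
                z = z + (v - v.mean()) / sd if sd > 0 else z
            order = sps_rank(z)
            score = order / max(len(records) - 1, 1)
            lut = _gradient_lut()
            colors = lut[np.round(score * (len(lut) - 1)).astype(int)]
            ann["composite_score"] = score
        else:
            col = value_column or ("cluster" if mode == "cluster" else "subpopulation")
            if col not in records.columns:
                raise DataError(f"records lack the {col!r} column required by mode {mode!r}")
            keys = records[col].astype(str)
            colors = np.array(
                [CATEGORY_COLORS.get(k, (200, 200, 200)) for k in keys], dtype=np.uint8
            )
        r_px = max(1, int(round(glyph_radius_um / pixel_size_um)))
        clipped = np.zeros(len(records), dtype=bool)
        H, W = rgb.shape[:2]
        for i, (_, rec) in enumerate(records.iterrows()):
            row = int(round(rec["centroid_y_um"] / pixel_size_um))
            col_px = int(round(rec["centroid_x_um"] / pixel_size_um))
            if not (0 <= row < H and 0 <= col_px < W):
                clipped[i] = True
                continue
            rr, cc = draw_disk((row, col_px), r_px, shape=(H, W))
            rgb[rr, cc] = colors[i]
        ann["glyph_clipped"] = clipped

    if out_png is not None:
        iio.imwrite(Path(out_png), rgb)
    if out_csv is not None:
        ann.to_csv(out_csv, index=False)
    return rgb, ann


def sps_rank(x: np.ndarray) -> np.ndarray:
    """Dense 0-based rank (ties broken by position for determinism)."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    ranks[order] = np.arange(len(x))
    return ranks
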