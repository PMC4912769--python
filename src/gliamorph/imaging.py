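"""Image-stack handling: TIFF I/O, sub-volume maximum-intensity projection,
and tile-mosaic assembly with a physical coordinate map.

A confocal acquisition is modelled as a z-stack of single-channel planes
with an isotropic in-plane calibration (``pixel_size_um``) and a fixed
z-increment (``z_step_um``).  The default acquisition geometry is 16 focal
planes at 2 um increments, 920 x 920 px tiles at 0.19 um/px, assembled as a
10 x 10 field mosaic.  For 2D analysis the stack is divided into three
contiguous ~10-um sub-volumes, each reduced by maximum-intensity projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

from .errors import GeometryError

#: default in-plane calibration, um per pixel
DEFAULT_PIXEL_SIZE_UM = 0.19
#: default z increment between focal planes, um
DEFAULT_Z_STEP_UM = 2.0
#: default number of focal planes per stack
DEFAULT_N_PLANES = 16


@dataclass
class ImageStack:
    """A calibrated single-channel z-stack, ``planes[n_planes, H, W]``."""

    planes: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim == 2:
            self.planes = self.planes[None]
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise GeometryError("stack must be [n_planes, H, W] with n_planes >= 1")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise GeometryError("calibration values must be positive")

    @property
    def n_planes(self) -> int:
        return int(self.planes.shape[0])

    @property
    def shape_2d(self) -> tuple[int, int]:
        return tuple(self.planes.shape[1:])  # type: ignore[return-value]


@dataclass
class ProjectionSet:
    """Maximum-intensity projections of the sub-volumes of one stack."""

    projections: list[np.ndarray]
    plane_ranges: list[tuple[int, int]]
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.projections)


@dataclass
class MosaicLayout:
    """Regular, non-overlapping grid of equally sized tiles."""

    grid_rows: int
    grid_cols: int
    tile_h_px: int
    tile_w_px: int

    def origin_px(self, row: int, col: int) -> tuple[int, int]:
        """Mosaic pixel offset (top-left) of tile (row, col)."""
        return row * self.tile_h_px, col * self.tile_w_px


def partition_planes(n_planes: int, n_subvolumes: int) -> list[tuple[int, int]]:
    """Contiguous, disjoint, jointly covering plane intervals.

    Blocks are as equal as possible with earlier blocks larger, e.g.
    16 planes over 3 sub-volumes -> sizes (6, 5, 5), i.e. intervals
    [0, 6), [6, 11), [11, 16).
    """
    if n_subvolumes < 1:
        raise GeometryError("need at least one sub-volume")
    if n_planes < n_subvolumes:
        raise GeometryError(
            f"cannot split {n_planes} planes into {n_subvolumes} sub-volumes"
        )
    base, rem = divmod(n_planes, n_subvolumes)
    sizes = [base + 1 if i < rem else base for i in range(n_subvolumes)]
    ranges, start = [], 0
    for s in sizes:
        ranges.append((start, start + s))
        start += s
    return ranges


def split_and_project(stack: ImageStack, n_subvolumes: int = 3) -> ProjectionSet:
    """Split a stack into contiguous sub-volumes and max-project each.

    Each output pixel is the maximum of that pixel over the sub-volume's
    planes.  Projecting a 1-plane stack with ``n_subvolumes=1`` is the
    identity.
    """
    ranges = partition_planes(stack.n_planes, n_subvolumes)
    projections = [stack.planes[a:b].max(axis=0) for a, b in ranges]
    return ProjectionSet(projections, ranges, stack.pixel_size_um)


def assemble_mosaic(
    tiles: Sequence[Sequence[np.ndarray]],
    layout: MosaicLayout | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[np.ndarray, "CoordinateMap"]:
    """Stitch a rectangular grid of pre-registered tiles (no overlap, no
    blending) and return the mosaic plus its pixel->um coordinate map."""
    rows = len(tiles)
    if rows == 0:
        raise GeometryError("empty tile grid")
    cols = len(tiles[0])
    shapes = {np.asarray(t).shape for row in tiles for t in row}
    if any(len(row) != cols for row in tiles) or len(shapes) != 1:
        raise GeometryError("ragged tile grid: all tiles must share dimensions")
    tile_h, tile_w = shapes.pop()
    if layout is None:
        layout = MosaicLayout(rows, cols, tile_h, tile_w)
    elif (layout.grid_rows, layout.grid_cols) != (rows, cols) or (
        layout.tile_h_px,
        layout.tile_w_px,
    ) != (tile_h, tile_w):
        raise GeometryError("layout does not match the provided tiles")
    mosaic = np.block([[np.asarray(t) for t in row] for row in tiles])
    return mosaic, CoordinateMap(pixel_size_um)


@dataclass
class CoordinateMap:
    """Pixel <-> physical coordinate conversion for a mosaic/projection.

    Convention: x is the column axis, y the row axis; the physical origin is
    the centre of pixel (0, 0).
    """

    pixel_size_um: float

    def px_to_um(self, row: float, col: float) -> tuple[float, float]:
        return col * self.pixel_size_um, row * self.pixel_size_um

    def um_to_px(self, x_um: float, y_um: float) -> tuple[float, float]:
        return y_um / self.pixel_size_um, x_um / self.pixel_size_um


# ---------------------------------------------------------------------------
# TIFF + sidecar-YAML I/O


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a multi-page grayscale TIFF plus a calibration sidecar YAML."""
    path = Path(path)
    tifffile.imwrite(path, stack.planes, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "pixel_size_um": float(stack.pixel_size_um),
                "z_step_um": float(stack.z_step_um),
            }
        )
    )


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> ImageStack:
    """Read a TIFF stack; calibration from the sidecar YAML unless given."""
    path = Path(path)
    planes = tifffile.imread(path)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    return ImageStack(
        planes,
        pixel_size_um=pixel_size_um or meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM),
        z_step_um=z_step_um or meta.get("z_step_um", DEFAULT_Z_STEP_UM),
    )
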