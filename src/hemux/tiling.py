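"""Tile grid, tissue masking, cell aggregation, normalization and splits.

The H&E frame is divided into a regular grid of square tiles (default
256 px, roughly 128 μm × 128 μm at 0.5 μm/px). Tile ``(i, j)`` covers the
half-open pixel box ``[j*s, (j+1)*s) × [i*s, (i+1)*s)``, so every in-bounds
pixel — and every mapped cell — belongs to exactly one tile.

Per-tile expression is the aggregate (by default the mean of ``log1p``
intensities) of all cells falling in the tile, z-scored per slide and marker
over tissue tiles that contain cells. Train/validation/test splits are
spatial: the three non-bottom-left quadrants of the tissue bounding box
train the model, and the bottom-left quadrant is held out (right half
validation, left half test), so evaluation tiles come from tissue regions
the model never saw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellTable
from .panel import MarkerPanel

logger = logging.getLogger(__name__)

SPLITS = ("train", "val", "test", "external", "masked")


@dataclass(frozen=True)
class TileGrid:
    tile_size_px: int
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.tile_size_px <= 0 or self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("tile size and grid dimensions must be positive")

    @classmethod
    def for_image(cls, shape: tuple[int, ...], tile_size_px: int = 256) -> "TileGrid":
        h, w = shape[0], shape[1]
        return cls(
            tile_size_px=tile_size_px,
            n_rows=int(np.ceil(h / tile_size_px)),
            n_cols=int(np.ceil(w / tile_size_px)),
        )

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def tile_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Tile (row, col) of pixel coordinates under the half-open box rule."""
        col = np.floor(np.asarray(x, float) / self.tile_size_px).astype(int)
        row = np.floor(np.asarray(y, float) / self.tile_size_px).astype(int)
        return row, col

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(center_x, center_y) arrays of shape (n_rows, n_cols), in pixels."""
        s = self.tile_size_px
        cx = (np.arange(self.n_cols) + 0.5) * s
        cy = (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(cx, cy)


@dataclass
class TissueMask:
    is_tissue: np.ndarray  # (n_rows, n_cols) bool
    tissue_fraction: np.ndarray  # fraction of tissue pixels per tile


def make_tissue_mask(
    he_image: np.ndarray,
    grid: TileGrid,
    saturation_threshold: float = 0.05,
    white_cutoff: float = 0.95,
    min_tissue_frac: float = 0.1,
) -> TissueMask:
    """Flag tiles containing tissue.

    A pixel is tissue-like when its saturation exceeds
    ``saturation_threshold`` and its luminance is below ``white_cutoff``
    (background on a bright-field scan is near-white and colorless); a tile
    is tissue when the fraction of such pixels exceeds ``min_tissue_frac``.
    """
    from .io import image_as_float

    rgb = image_as_float(np.asarray(he_image))
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("tissue masking expects an RGB H&E image")
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-12), 0.0)
    lum = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    tissue_px = (sat > saturation_threshold) & (lum < white_cutoff)

    s = grid.tile_size_px
    frac = np.zeros((grid.n_rows, grid.n_cols))
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            block = tissue_px[i * s : (i + 1) * s, j * s : (j + 1) * s]
            frac[i, j] = block.mean() if block.size else 0.0
    return TissueMask(is_tissue=frac > min_tissue_frac, tissue_fraction=frac)


def aggregate_cells(
    cells: CellTable,
    grid: TileGrid,
    panel: MarkerPanel,
    slide_id: str = "slide",
    statistic: str = "mean_log1p",
) -> pd.DataFrame:
    """Aggregate mapped cells into per-tile marker expression.

    Returns a tile table with one row per grid tile: ``n_cells`` counts the
    cells whose (x, y) falls in the tile's half-open box, and
    ``<marker>_raw`` holds the aggregate of those cells' intensities
    (default: mean of ``log1p``). Tiles without cells carry NaN expression.
    Cells flagged out-of-bounds or with negative coordinates are excluded
    (counted in the log).
    """
    if statistic not in {"mean_log1p", "mean", "median", "sum"}:
        raise ValueError(f"unknown aggregation statistic {statistic!r}")
    x, y, expr = cells.x, cells.y, cells.expr
    ok = (
        cells.in_bounds
        & (x >= 0)
        & (y >= 0)
        & (x < grid.n_cols * grid.tile_size_px)
        & (y < grid.n_rows * grid.tile_size_px)
    )
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("aggregate_cells: excluded %d out-of-bounds cells", n_excluded)
    x, y, expr = x[ok], y[ok], expr[ok]
    row, col = grid.tile_of(x, y)
    flat = row * grid.n_cols + col

    values = np.log1p(expr) if statistic == "mean_log1p" else expr
    n_tiles = grid.n_tiles
    counts = np.bincount(flat, minlength=n_tiles)
    M = len(panel)
    agg = np.full((n_tiles, M), np.nan)
    if statistic in {"mean_log1p", "mean"}:
        for m in range(M):
            sums = np.bincount(flat, weights=values[:, m], minlength=n_tiles)
            with np.errstate(invalid="ignore"):
                agg[:, m] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    elif statistic == "sum":
        for m in range(M):
            sums = np.bincount(flat, weights=values[:, m], minlength=n_tiles)
            agg[:, m] = np.where(counts > 0, sums, np.nan)
    else:  # median
        order = np.argsort(flat, kind="stable")
        flat_s = flat[order]
        vals_s = values[order]
        starts = np.searchsorted(flat_s, np.arange(n_tiles))
        ends = np.searchsorted(flat_s, np.arange(n_tiles), side="right")
        for t in range(n_tiles):
            if ends[t] > starts[t]:
                agg[t] = np.median(vals_s[starts[t] : ends[t]], axis=0)

    rows, cols = np.divmod(np.arange(n_tiles), grid.n_cols)
    out = pd.DataFrame(
        {
            "slide_id": slide_id,
            "tile_row": rows,
            "tile_col": cols,
            "n_cells": counts,
            "split": "train",
        }
    )
    for m, name in enumerate(panel.names):
        out[f"{name}_raw"] = agg[:, m]
    return out


def zscore_per_slide(
    tiles: pd.DataFrame, panel: MarkerPanel, ddof: int = 0
) -> pd.DataFrame:
    """Standardize raw tile expression per slide and marker.

    z = (raw − mean) / sd over tiles with cells (population sd by default),
    computed within each slide. Constant markers get z = 0 with a warning;
    fewer than 2 usable tiles in a slide is an error.
    """
    tiles = tiles.copy()
    for name in panel.names:
        tiles[f"{name}_z"] = np.nan
    for slide_id, idx in tiles.groupby("slide_id").groups.items():
        sub = tiles.loc[idx]
        usable = (sub["n_cells"].to_numpy() > 0) & (
            sub["split"].to_numpy() != "masked"
        )
        if usable.sum() < 2:
            raise ValueError(
                f"slide {slide_id!r}: need >= 2 tiles with cells to z-score, "
                f"have {int(usable.sum())}"
            )
        for name in panel.names:
            raw = sub[f"{name}_raw"].to_numpy(dtype=float)
            vals = raw[usable]
            mu = float(np.mean(vals))
            sd = float(np.std(vals, ddof=ddof))
            if sd < 1e-12:
                logger.warning(
                    "zscore: marker %s constant on slide %s; z set to 0", name, slide_id
                )
                z = np.where(usable, 0.0, np.nan)
            else:
                z = np.where(usable, (raw - mu) / sd, np.nan)
            tiles.loc[idx, f"{name}_z"] = z
    return tiles


def assign_splits(grid: TileGrid, mask: TissueMask | None = None) -> np.ndarray:
    """Quadrant-based train/val/test assignment per tile.

    Quadrant boundaries sit at the midpoints of the tissue bounding box.
    Tiles whose center lies in the bottom-left quadrant (center_x <= mid_x,
    center_y >= mid_y; "bottom" = larger row index) are held out; within
    that quadrant a tile is validation when its left edge reaches the
    quadrant's right half, else test. All other tissue tiles train.
    Non-tissue tiles are labeled "masked".
    """
    s = grid.tile_size_px
    cx, cy = grid.centers()
    if mask is not None and mask.is_tissue.any():
        tissue = mask.is_tissue
        rows = np.nonzero(tissue.any(axis=1))[0]
        cols = np.nonzero(tissue.any(axis=0))[0]
        x0, x1 = cols[0] * s, (cols[-1] + 1) * s
        y0, y1 = rows[0] * s, (rows[-1] + 1) * s
    else:
        tissue = np.ones((grid.n_rows, grid.n_cols), dtype=bool)
        x0, x1 = 0, grid.n_cols * s
        y0, y1 = 0, grid.n_rows * s
    mid_x = (x0 + x1) / 2
    mid_y = (y0 + y1) / 2
    quarter_x = (x0 + mid_x) / 2

    bottom_left = (cx <= mid_x) & (cy >= mid_y)
    left_edge = cx - s / 2
    val = bottom_left & (left_edge >= quarter_x)
    test = bottom_left & ~val

    split = np.full((grid.n_rows, grid.n_cols), "train", dtype=object)
    split[val] = "val"
    split[test] = "test"
    split[~tissue] = "masked"
    return split


def apply_splits(tiles: pd.DataFrame, split: np.ndarray) -> pd.DataFrame:
    tiles = tiles.copy()
    rr = tiles["tile_row"].to_numpy(dtype=int)
    cc = tiles["tile_col"].to_numpy(dtype=int)
    tiles["split"] = split[rr, cc]
    return tiles
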