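"""Readers and writers for cell tables, slide rasters and tile matrices.

Conventions used throughout:

* coordinates are 0-based pixels, ``x`` = column, ``y`` = row, origin at the
  top-left of the image;
* RGB rasters are ``(H, W, 3)`` arrays, channel order R, G, B;
* cell tables are delimited text with a header holding at least ``x``, ``y``
  and one column per panel marker (extra columns — morphology, QC flags — are
  ignored);
* tile tables are CSV with columns ``slide_id, tile_row, tile_col, n_cells,
  split, <marker>_raw ..., <marker>_z ...``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .panel import MarkerPanel


class SchemaError(ValueError):
    """A file is readable but does not have the expected columns/structure."""


@dataclass
class CellTable:
    """Per-cell coordinates and marker intensities for one slide.

    ``x``/``y`` are pixel coordinates in whichever frame the table currently
    lives in (the multiplexed frame on input; the H&E frame after cell
    mapping). ``expr`` is ``(n_cells, M)`` with columns in panel order.
    """

    x: np.ndarray
    y: np.ndarray
    expr: np.ndarray
    panel: MarkerPanel
    cell_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    in_bounds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.expr = np.asarray(self.expr, dtype=float)
        n = self.x.shape[0]
        if self.y.shape[0] != n or self.expr.shape[0] != n:
            raise ValueError("x, y and expr must have one row per cell")
        if self.expr.ndim != 2 or self.expr.shape[1] != len(self.panel):
            raise ValueError(
                f"expr must be (n_cells, {len(self.panel)}); got {self.expr.shape}"
            )
        if not np.isfinite(self.expr).all():
            raise ValueError("marker intensities must be finite")
        if self.cell_id is None:
            self.cell_id = np.arange(n, dtype=int)
        else:
            self.cell_id = np.asarray(self.cell_id, dtype=int)
        if self.in_bounds is None:
            self.in_bounds = np.ones(n, dtype=bool)
        else:
            self.in_bounds = np.asarray(self.in_bounds, dtype=bool)

    def __len__(self) -> int:
        return self.x.shape[0]


def read_cell_table(path: str | Path, panel: MarkerPanel) -> CellTable:
    """Read a delimited single-cell table and validate it against the panel.

    Raises :class:`SchemaError` naming any missing marker/coordinate column,
    and a parse error carrying the (1-based, header-exclusive) row number for
    a non-numeric coordinate.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("x", "y", *panel.names) if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    for coord in ("x", "y"):
        vals = pd.to_numeric(df[coord], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[coord].notna().to_numpy())[0]
        if df[coord].isna().any():
            bad = np.union1d(bad, np.nonzero(df[coord].isna().to_numpy())[0])
        if bad.size:
            raise ValueError(
                f"{path.name}: non-numeric {coord!r} at data row {bad[0] + 1}"
            )
        df[coord] = vals
    cell_id = (
        df["cell_id"].to_numpy(dtype=int)
        if "cell_id" in df.columns
        else np.arange(len(df))
    )
    expr = df[list(panel.names)].to_numpy(dtype=float)
    return CellTable(
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        expr=expr,
        panel=panel,
        cell_id=cell_id,
    )


def write_cell_table(cells: CellTable, path: str | Path) -> None:
    df = pd.DataFrame({"cell_id": cells.cell_id, "x": cells.x, "y": cells.y})
    for m, name in enumerate(cells.panel.names):
        df[name] = cells.expr[:, m]
    df.to_csv(path, index=False)


def read_slide_image(
    path: str | Path, level: int = 0, channel: int | None = None
) -> np.ndarray:
    """Read one level of a (possibly pyramidal) TIFF.

    Returns ``(H, W, 3)`` for RGB pages and ``(H, W)`` for single-channel
    pages (or when ``channel`` selects one plane of a multi-channel stack).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        n_levels = len(series.levels) if series.levels else 1
        if level < 0 or level >= n_levels:
            raise ValueError(
                f"{path.name}: level {level} unavailable; "
                f"levels are 0..{n_levels - 1}"
            )
        arr = series.levels[level].asarray() if series.levels else series.asarray()
    if arr.dtype.kind not in "uif":
        raise ValueError(f"{path.name}: unsupported pixel type {arr.dtype}")
    arr = np.asarray(arr)
    if channel is not None:
        if arr.ndim == 3:
            ax = int(np.argmin(arr.shape))  # channel axis is the small one
            arr = np.take(arr, channel, axis=ax)
        elif channel != 0:
            raise ValueError(f"{path.name}: single-channel image has no channel {channel}")
    if arr.ndim == 3 and arr.shape[0] in (3, 4) and arr.shape[2] not in (3, 4):
        arr = np.moveaxis(arr, 0, 2)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def write_slide_image(arr: np.ndarray, path: str | Path, pyramid_levels: int = 1) -> None:
    """Write an array as TIFF; ``pyramid_levels > 1`` writes a 2x pyramid."""
    arr = np.asarray(arr)
    if pyramid_levels <= 1:
        tifffile.imwrite(path, arr)
        return
    with tifffile.TiffWriter(path) as tw:
        photometric = "rgb" if arr.ndim == 3 else "minisblack"
        tw.write(arr, subifds=pyramid_levels - 1, photometric=photometric)
        lvl = arr
        for _ in range(pyramid_levels - 1):
            lvl = lvl[::2, ::2]
            tw.write(lvl, subfiletype=1, photometric=photometric)


def image_as_float(arr: np.ndarray) -> np.ndarray:
    """Convert an integer raster to float in [0, 1]; floats pass through."""
    arr = np.asarray(arr)
    if arr.dtype.kind == "u":
        return arr.astype(float) / np.iinfo(arr.dtype).max
    if arr.dtype.kind == "i":
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def rgb_to_luminance(rgb: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of an RGB raster scaled to [0, 1]."""
    rgbf = image_as_float(rgb)
    return 0.299 * rgbf[..., 0] + 0.587 * rgbf[..., 1] + 0.114 * rgbf[..., 2]


# ---------------------------------------------------------------------------
# Tile tables


def write_tile_table(tiles: pd.DataFrame, path: str | Path) -> None:
    tiles.to_csv(path, index=False)


def read_tile_table(path: str | Path, panel: MarkerPanel | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["slide_id", "tile_row", "tile_col", "n_cells", "split"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing column(s) {missing}")
    if panel is not None:
        for name in panel.names:
            if f"{name}_z" not in df.columns:
                raise SchemaError(f"{Path(path).name}: missing column {name}_z")
    return df


# ---------------------------------------------------------------------------
# Expression maps


def expression_map_array(
    values: np.ndarray,
    mask: np.ndarray,
    tile_size_px: int,
    background: float = 0.0,
) -> np.ndarray:
    """De-tile per-tile values into a pixel raster.

    Pixel block ``(i, j)`` (``tile_size_px`` square) carries ``values[i, j]``;
    tiles where ``mask`` is False render as ``background``.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    filled = np.where(mask, values, background)
    return np.kron(filled, np.ones((tile_size_px, tile_size_px)))


def write_expression_map(
    tiles: pd.DataFrame,
    marker: str,
    panel: MarkerPanel,
    path: str | Path,
    tile_size_px: int = 256,
    column: str = "z",
) -> np.ndarray:
    """Render one marker's per-tile values as a de-tiled raster image file.

    Returns the rendered array as well as writing it (PNG via matplotlib
    colormap, or raw float TIFF for ``.tif``).
    """
    if marker not in panel.names:
        raise KeyError(f"unknown marker {marker!r}; panel is {list(panel.names)}")
    col = f"{marker}_{column}"
    n_rows = int(tiles["tile_row"].max()) + 1
    n_cols = int(tiles["tile_col"].max()) + 1
    grid = np.zeros((n_rows, n_cols))
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    rr = tiles["tile_row"].to_numpy(dtype=int)
    cc = tiles["tile_col"].to_numpy(dtype=int)
    vals = tiles[col].to_numpy(dtype=float)
    ok = np.isfinite(vals)
    if "split" in tiles.columns:
        ok &= tiles["split"].to_numpy() != "masked"
    grid[rr[ok], cc[ok]] = vals[ok]
    mask[rr[ok], cc[ok]] = True
    arr = expression_map_array(grid, mask, tile_size_px)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr.astype(np.float32))
    else:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(arr, cmap="viridis")
        ax.set_title(marker)
        ax.axis("off")
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
    return arr
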