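"""Ranking and correlation metrics for predicted vs measured tile expression.

Two metrics drive all reporting:

* Pearson correlation between measured and predicted z-scores, computed per
  (slide, split, marker) group, with medians across slides per marker;
* top-X% accuracy — the overlap percentage between the highest X% of tiles
  by measured value and the highest X% by predicted value for the same
  marker, which scores how well the model finds the strongly expressing
  regions regardless of calibration.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MarkerPanel


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Pearson correlation; NaN when either vector is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"misaligned vectors: {a.shape} vs {b.shape}")
    if a.size < 3:
        return float("nan")
    av = a - a.mean()
    bv = b - b.mean()
    den = np.sqrt((av**2).sum() * (bv**2).sum())
    if den == 0:
        return float("nan")
    return float((av * bv).sum() / den)


def top_k_indices(values: np.ndarray, k: int) -> set[int]:
    """Indices of the k largest values; ties broken by ascending index."""
    values = np.asarray(values, dtype=float)
    order = np.lexsort((np.arange(values.size), -values))
    return set(order[:k].tolist())


def top_x_accuracy(measured, predicted, X: float) -> float:
    """Overlap percentage of the measured and predicted top-X% tile sets.

    ``k = round(X*n/100)``, at least 1; returns
    ``100 * |topk(measured) ∩ topk(predicted)| / k``.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape or measured.ndim != 1:
        raise ValueError("measured and predicted must be aligned 1-D vectors")
    n = measured.size
    if n < 1:
        raise ValueError("need at least one tile")
    if not (0 < X <= 100):
        raise ValueError(f"X must be in (0, 100], got {X}")
    k = max(1, int(np.floor(X * n / 100.0 + 0.5)))
    top_m = top_k_indices(measured, k)
    top_p = top_k_indices(predicted, k)
    return 100.0 * len(top_m & top_p) / k


def grouped_pearson(
    measured_z: np.ndarray,
    predicted_z: np.ndarray,
    groups: pd.DataFrame,
    panel: MarkerPanel,
) -> pd.DataFrame:
    """Pearson r per (slide, split, marker) group.

    ``groups`` must carry ``slide_id`` and ``split`` aligned with the rows of
    the two matrices. Groups with fewer than 3 tiles or a constant vector
    are reported with NaN and excluded from medians downstream.
    """
    measured_z = np.asarray(measured_z, dtype=float)
    predicted_z = np.asarray(predicted_z, dtype=float)
    if measured_z.shape != predicted_z.shape:
        raise ValueError("measured and predicted matrices must be aligned")
    if measured_z.shape[0] != len(groups):
        raise ValueError("group labels must align with matrix rows")
    records = []
    for (slide_id, split), idx in groups.groupby(
        ["slide_id", "split"], sort=True
    ).groups.items():
        loc = groups.index.get_indexer(idx)
        for m, name in enumerate(panel.names):
            a = measured_z[loc, m]
            b = predicted_z[loc, m]
            ok = np.isfinite(a) & np.isfinite(b)
            r = pearson_r(a[ok], b[ok]) if ok.sum() >= 3 else float("nan")
            records.append(
                {
                    "slide_id": slide_id,
                    "split": split,
                    "marker": name,
                    "n_tiles": int(ok.sum()),
                    "pearson_r": r,
                }
            )
    return pd.DataFrame.from_records(records)


def median_by_marker(report: pd.DataFrame) -> pd.DataFrame:
    """Median correlation across slides, per marker and split (defined only)."""
    ok = report[np.isfinite(report["pearson_r"])]
    return (
        ok.groupby(["marker", "split"])["pearson_r"]
        .median()
        .reset_index()
        .rename(columns={"pearson_r": "median_r"})
    )


def evaluate_run(
    tiles: pd.DataFrame,
    predictions: np.ndarray,
    panel: MarkerPanel,
    x_values: tuple[float, ...] = (5.0, 10.0, 20.0),
    out_dir: str | Path | None = None,
    tile_size_px: int = 256,
    write_maps: bool = True,
) -> dict[str, pd.DataFrame]:
    """Full evaluation report for one prediction run.

    ``tiles`` is a tile table restricted to rows with predictions
    (tissue tiles with cells); ``predictions`` the aligned (n, M) matrix.
    Writes correlation and top-X% tables (and optional measured/predicted
    map images) under ``out_dir``.
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != (len(tiles), len(panel)):
        raise ValueError(
            f"predictions shape {predictions.shape} does not match "
            f"{len(tiles)} tiles x {len(panel)} markers"
        )
    measured = tiles[[f"{n}_z" for n in panel.names]].to_numpy(dtype=float)
    corr = grouped_pearson(measured, predictions, tiles, panel)

    top_records = []
    for (slide_id, split), idx in tiles.groupby(
        ["slide_id", "split"], sort=True
    ).groups.items():
        loc = tiles.index.get_indexer(idx)
        for m, name in enumerate(panel.names):
            a = measured[loc, m]
            b = predictions[loc, m]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3:
                continue
            for X in x_values:
                top_records.append(
                    {
                        "slide_id": slide_id,
                        "split": split,
                        "marker": name,
                        "X": X,
                        "n_tiles": int(ok.sum()),
                        "top_x_accuracy": top_x_accuracy(a[ok], b[ok], X),
                    }
                )
    topx = pd.DataFrame.from_records(top_records)
    medians = median_by_marker(corr)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        corr.to_csv(out_dir / "pearson_by_group.csv", index=False)
        topx.to_csv(out_dir / "top_x_accuracy.csv", index=False)
        medians.to_csv(out_dir / "median_r_by_marker.csv", index=False)
        if write_maps:
            from .io import write_expression_map

            pred_tiles = tiles.copy()
            for m, name in enumerate(panel.names):
                pred_tiles[f"{name}_z"] = predictions[:, m]
            for name in panel.names:
                write_expression_map(
                    tiles, name, panel,
                    out_dir / f"{name}_measured.png", tile_size_px,
                )
                write_expression_map(
                    pred_tiles, name, panel,
                    out_dir / f"{name}_predicted.png", tile_size_px,
                )
    return {"pearson": corr, "top_x": topx, "medians": medians}
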