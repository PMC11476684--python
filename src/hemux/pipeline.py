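"""Stage orchestration: register → tile → embed → train → predict → eval → gate.

Stages communicate only through files under the run's output directory, so
any stage can be rerun or replaced in isolation; ``run_all`` executes them
in order and writes a manifest recording the config hash, seeds, package
version and a checksum per stage output. Identical config + inputs
reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .features import get_embedder
from .gating import (
    DEFAULT_CLASSES,
    call_markers,
    class_precision,
    confusion_by_class,
    fit_gates,
)
from .io import (
    image_as_float,
    read_cell_table,
    read_slide_image,
    read_tile_table,
    rgb_to_luminance,
    write_tile_table,
)
from .model import ExpressionRegressor
from .panel import MarkerPanel
from .registration import (
    RegistrationConfig,
    estimate_global_affine,
    load_transform,
    map_cells,
    refine_local,
    save_transform,
)
from .tiling import (
    TileGrid,
    aggregate_cells,
    apply_splits,
    assign_splits,
    make_tissue_mask,
    zscore_per_slide,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _load_panel(cfg: RunConfig) -> MarkerPanel:
    return MarkerPanel.from_file(cfg.panel_file) if cfg.panel_file else MarkerPanel()


def usable_rows(tiles: pd.DataFrame) -> pd.DataFrame:
    """Tissue tiles containing cells — the rows the model trains/evaluates on."""
    return tiles[(tiles["n_cells"] > 0) & (tiles["split"] != "masked")]


# ---------------------------------------------------------------- stages


def stage_register(cfg: RunConfig, out: Path) -> Path:
    he = read_slide_image(cfg.he_image)
    cy = read_slide_image(cfg.cycif_image)
    # invert bright-field luminance so tissue is bright, as in the reference
    he_gray = 1.0 - rgb_to_luminance(he) if he.ndim == 3 else image_as_float(he)
    cy_gray = image_as_float(cy)
    reg_cfg = RegistrationConfig(
        metric=cfg.metric, max_displacement_px=cfg.max_displacement_px, seed=cfg.seed
    )
    affine = estimate_global_affine(he_gray, cy_gray, reg_cfg)
    grid = TileGrid.for_image(he_gray.shape, cfg.tile_size_px)
    field = refine_local(he_gray, cy_gray, affine, grid, reg_cfg)
    path = out / "registration.json"
    save_transform(path, affine, field)
    return path


def stage_tile(cfg: RunConfig, out: Path, panel: MarkerPanel) -> Path:
    cell_path = Path(cfg.cell_table)
    if not cell_path.exists():
        raise FileNotFoundError(f"cell table not found: {cell_path}")
    he = read_slide_image(cfg.he_image)
    grid = TileGrid.for_image(he.shape, cfg.tile_size_px)
    cells = read_cell_table(cell_path, panel)
    reg_path = out / "registration.json"
    if reg_path.exists():
        affine, field = load_transform(reg_path)
        cells = map_cells(cells, affine, field, bounds=he.shape[:2])
    mask = make_tissue_mask(he, grid, min_tissue_frac=cfg.min_tissue_frac)
    tiles = aggregate_cells(
        cells, grid, panel, slide_id=cfg.slide_id, statistic=cfg.aggregation
    )
    tiles = apply_splits(tiles, assign_splits(grid, mask))
    tiles = zscore_per_slide(tiles, panel)
    path = out / "tiles.csv"
    write_tile_table(tiles, path)
    return path


def _extract_tiles_rgb(he: np.ndarray, rows, cols, s: int) -> list[np.ndarray]:
    he_f = image_as_float(he)
    out = []
    for r, c in zip(rows, cols):
        patch = he_f[r * s : (r + 1) * s, c * s : (c + 1) * s]
        if patch.shape[:2] != (s, s):  # pad edge tiles to full size
            pad = np.ones((s, s, 3))
            pad[: patch.shape[0], : patch.shape[1]] = patch
            patch = pad
        out.append(patch)
    return out


def stage_embed(cfg: RunConfig, out: Path, panel: MarkerPanel) -> Path:
    tiles = read_tile_table(out / "tiles.csv", panel)
    use = usable_rows(tiles)
    he = read_slide_image(cfg.he_image)
    embedder = get_embedder(cfg.provider, seed=cfg.seed, dim=cfg.provider_dim)
    patches = _extract_tiles_rgb(
        he, use["tile_row"].to_numpy(int), use["tile_col"].to_numpy(int),
        cfg.tile_size_px,
    )
    emb = embedder.embed_batch(patches)
    df = pd.DataFrame(emb, columns=[f"e{i}" for i in range(emb.shape[1])])
    df.insert(0, "tile_row", use["tile_row"].to_numpy(int))
    df.insert(1, "tile_col", use["tile_col"].to_numpy(int))
    path = out / "embeddings.csv"
    df.to_csv(path, index=False)
    return path


def _split_matrices(tiles: pd.DataFrame, emb: pd.DataFrame, panel: MarkerPanel):
    use = usable_rows(tiles).reset_index(drop=True)
    z = use[[f"{n}_z" for n in panel.names]].to_numpy(float)
    E = emb[[c for c in emb.columns if c.startswith("e")]].to_numpy(float)
    split = use["split"].to_numpy()
    return use, E, z, split


def stage_train(cfg: RunConfig, out: Path, panel: MarkerPanel) -> Path:
    tiles = read_tile_table(out / "tiles.csv", panel)
    emb = pd.read_csv(out / "embeddings.csv")
    _, E, z, split = _split_matrices(tiles, emb, panel)
    tr = split == "train"
    va = split == "val"
    est = ExpressionRegressor(
        architecture=cfg.architecture,
        hidden_sizes=cfg.hidden_sizes,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        dropout=cfg.dropout,
        random_state=cfg.seed,
    )
    est.fit(E[tr], z[tr], E[va] if va.any() else None, z[va] if va.any() else None)
    path = out / "model.json"
    est.save(path)
    return path


def stage_predict(cfg: RunConfig, out: Path, panel: MarkerPanel) -> Path:
    tiles = read_tile_table(out / "tiles.csv", panel)
    emb = pd.read_csv(out / "embeddings.csv")
    use, E, _, _ = _split_matrices(tiles, emb, panel)
    model_path = Path(cfg.model_path) if cfg.model_path else out / "model.json"
    est = ExpressionRegressor.load(model_path)
    pred = est.predict(E)
    df = use[["slide_id", "tile_row", "tile_col", "split"]].copy()
    for m, name in enumerate(panel.names):
        df[f"{name}_z"] = pred[:, m]
    path = out / "predictions.csv"
    df.to_csv(path, index=False)
    return path


def stage_eval(cfg: RunConfig, out: Path, panel: MarkerPanel) -> Path:
    from .evaluation import evaluate_run

    tiles = read_tile_table(out / "tiles.csv", panel)
    use = usable_rows(tiles).reset_index(drop=True)
    pred = pd.read_csv(out / "predictions.csv")
    if len(pred) != len(use):
        raise ValueError(
            f"predictions cover {len(pred)} tiles but {len(use)} are expected"
        )
    P = pred[[f"{n}_z" for n in panel.names]].to_numpy(float)
    report_dir = out / "report"
    evaluate_run(
        use, P, panel, x_values=cfg.x_values, out_dir=report_dir,
        tile_size_px=cfg.tile_size_px,
    )
    return report_dir / "pearson_by_group.csv"


def stage_gate(cfg: RunConfig, out: Path, panel: MarkerPanel) -> Path:
    tiles = read_tile_table(out / "tiles.csv", panel)
    use = usable_rows(tiles).reset_index(drop=True)
    pred = pd.read_csv(out / "predictions.csv")
    pred_tiles = use[["slide_id", "tile_row", "tile_col", "n_cells", "split"]].copy()
    for name in panel.names:
        pred_tiles[f"{name}_z"] = pred[f"{name}_z"].to_numpy(float)

    gates_true = fit_gates(use, panel, seed=cfg.seed, column=cfg.gate_on)
    gates_pred = fit_gates(pred_tiles, panel, seed=cfg.seed, column=cfg.gate_on)
    true_calls = call_markers(use, gates_true, panel, column=cfg.gate_on)
    pred_calls = call_markers(pred_tiles, gates_pred, panel, column=cfg.gate_on)

    classes = _classes_for_panel(panel)
    gate_dir = out / "calls"
    gate_dir.mkdir(parents=True, exist_ok=True)
    true_calls.to_csv(gate_dir / "calls_measured.csv", index=False)
    pred_calls.to_csv(gate_dir / "calls_predicted.csv", index=False)
    if classes:
        cm = confusion_by_class(true_calls, pred_calls, classes)
        cm.to_csv(gate_dir / "confusion_classes.csv")
        prec = pd.DataFrame(
            {
                "class": [c.name for c in classes],
                "precision": [
                    class_precision(true_calls, pred_calls, c) for c in classes
                ],
            }
        )
        prec.to_csv(gate_dir / "class_precision.csv", index=False)
    return gate_dir / "calls_predicted.csv"


def _classes_for_panel(panel: MarkerPanel):
    """Known co-occurrence classes whose markers all exist in the panel."""
    from .fixtures import FIXTURE_CLASSES

    seen: dict[str, object] = {}
    for c in (*DEFAULT_CLASSES, *FIXTURE_CLASSES):
        if c.name not in seen and all(m in panel.names for m in c.markers):
            seen[c.name] = c
    return tuple(seen.values())


STAGES = ("register", "tile", "embed", "train", "predict", "eval", "gate")


def run_all(cfg: RunConfig, skip_register: bool = False) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = _load_panel(cfg)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "stages": {},
    }
    for stage in STAGES:
        if stage == "register" and (skip_register or not cfg.cycif_image):
            continue
        if stage == "train" and cfg.model_path:
            continue
        fn = {
            "register": lambda: stage_register(cfg, out),
            "tile": lambda: stage_tile(cfg, out, panel),
            "embed": lambda: stage_embed(cfg, out, panel),
            "train": lambda: stage_train(cfg, out, panel),
            "predict": lambda: stage_predict(cfg, out, panel),
            "eval": lambda: stage_eval(cfg, out, panel),
            "gate": lambda: stage_gate(cfg, out, panel),
        }[stage]
        try:
            artifact = fn()
        except Exception as e:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise StageError(stage, e) from e
        manifest["stages"][stage] = {
            "artifact": str(artifact),
            "checksum": _checksum(Path(artifact)),
        }
        logger.info("stage %s done -> %s", stage, artifact)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def run_inference(cfg: RunConfig) -> dict:
    """Deployment mode: pretrained head + a new H&E, no multiplexed data.

    Produces per-tile predictions and gate calls from the H&E image alone;
    requires ``cfg.model_path``.
    """
    if not cfg.model_path:
        raise ValueError("inference mode requires model_path")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = _load_panel(cfg)
    he = read_slide_image(cfg.he_image)
    grid = TileGrid.for_image(he.shape, cfg.tile_size_px)
    mask = make_tissue_mask(he, grid, min_tissue_frac=cfg.min_tissue_frac)
    split = assign_splits(grid, mask)
    rows, cols = np.nonzero(mask.is_tissue)
    embedder = get_embedder(cfg.provider, seed=cfg.seed, dim=cfg.provider_dim)
    patches = _extract_tiles_rgb(he, rows, cols, cfg.tile_size_px)
    E = embedder.embed_batch(patches)
    est = ExpressionRegressor.load(cfg.model_path)
    pred = est.predict(E)
    df = pd.DataFrame(
        {
            "slide_id": cfg.slide_id,
            "tile_row": rows,
            "tile_col": cols,
            "n_cells": 0,
            "split": split[rows, cols],
        }
    )
    for m, name in enumerate(panel.names):
        df[f"{name}_z"] = pred[:, m]
    df.to_csv(out / "predictions.csv", index=False)
    gates = fit_gates(df, panel, seed=cfg.seed, column="z")
    calls = call_markers(df, gates, panel, column="z")
    calls.to_csv(out / "calls_predicted.csv", index=False)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "mode": "inference",
        "n_tiles": int(len(df)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
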