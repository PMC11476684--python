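# hemux

Tile-level multiplexed protein expression inference from H&E whole-slide
images.

Routine hematoxylin & eosin (H&E) histology is cheap and ubiquitous;
multiplexed imaging such as cyclic immunofluorescence (CyCIF), which
measures per-cell intensities for a panel of protein markers (immune,
stromal and tumor markers like CD3, CD8a, PD1, PDL1, cytokeratin), is
expensive and rare. When adjacent serial sections of the same tissue have
been imaged both ways, one can train a model that predicts the multiplexed
readout from the H&E image alone — turning any H&E slide into an
approximate spatial protein map. `hemux` is a complete, tested pipeline
for that task, aimed at computational-pathology researchers who want the
full training/evaluation loop reproducible at desk scale.

## The method

The slide is divided into square tiles (default 256 px ≈ 128 μm at
0.5 μm/px). For a marker panel of size *M* and per-cell intensities
*e<sub>c</sub>* from the multiplexed slide:

1. **Registration.** The multiplexed image is aligned onto the H&E of the
   adjacent section in two steps: a whole-slide affine *A* maximizing
   Mattes mutual information (multi-resolution, polished by a
   normalized-correlation fine stage), then a tile-level non-linear
   refinement — one translation per tile from the normalized
   cross-correlation peak of the warped reference against the H&E,
   smoothed across the grid. Cell coordinates map through both.
2. **Aggregation.** Tile expression is the mean of log1p cell intensities
   over the cells falling in the tile; per slide and marker these are
   standardized to z-scores over tiles containing cells.
3. **Splits.** Quadrant-based: the three non-bottom-left quadrants of the
   tissue bounding box train the model (≈75% of tiles); in the held-out
   bottom-left quadrant the right half validates and the left half tests,
   so evaluation tiles come from tissue the model never saw.
4. **Model.** A frozen embedding provider maps each 3-channel tile to a
   *d*-vector (d = 384 for the texture-aware provider, d = 3 for the
   mean-color baseline); a four-layer fully connected head
   (d → 256 → 256 → 256 → M, GELU, dropout) is trained with Adam on mean
   squared error against the z-scored expression, with early stopping on
   the validation quadrant. Pathology-style augmentation (flips, 90°
   rotations, HED stain jitter, brightness/contrast, blur, JPEG) is
   available at training time.
5. **Evaluation.** Pearson *r* per (slide, split, marker) with medians
   across slides, plus *top-X% accuracy*: the overlap percentage between
   the measured and predicted top-X% tiles for a marker.
6. **Gating.** Per slide and marker, a two-component Gaussian mixture on
   the z-scores; the positive/negative threshold is the smallest value
   between the component means whose posterior for the high component
   reaches 1/2. Binary calls feed co-occurrence classes (e.g. PD1+/PDL1+,
   read as cell–cell interaction at tile resolution), column-normalized
   confusion matrices whose diagonal is per-class precision, and a
   one-sided paired (by slide) t-test for enrichment of a context marker
   in interacting tiles.

A seeded synthetic generator (`hemux.fixtures`) produces paired
H&E-like/CyCIF-like slides with fully known ground truth — planted warp,
marker fields, mixture structure and color/texture coupling — so the whole
system is testable without any download.

## Worked example

Generate a synthetic paired slide and run the full pipeline:

```bash
hemux fixture --out slide/ --seed 0
hemux run --config cfg.yaml
```

with `cfg.yaml`:

```yaml
he_image: slide/he.tif
cycif_image: slide/cycif_ref.tif
cell_table: slide/cells.csv
panel_file: slide/panel.yaml
out_dir: run/
tile_size_px: 64
provider: randproj
seed: 0
```

The run writes `run/manifest.json` (stage checksums),
`run/report/pearson_by_group.csv`, top-X% tables, expression maps and
gating outputs. On this fixture the held-out (test-quadrant) correlations
per marker are:

```
Ki-67        0.961   <- coupled to the image (chromatin texture + color)
cytokeratin  0.961   <- coupled to the image (eosin color)
CD45         0.043
CD4          0.122
FOXP3       -0.091
CD8a         0.071
PD1         -0.135
PDL1        -0.105
```

The two markers whose planted fields drive the image's color and texture
are recovered almost perfectly from the H&E alone; the six markers whose
fields are independent of the image correlate near zero, exactly as they
should. The mean-color + linear baseline reaches only 0.92 mean on the
coupled pair versus 0.96 for the texture-aware provider, and the planted
Ki-67+/cytokeratin+ co-occurrence class is called with precision 0.80
against a 0.19 base rate.

The same trained head runs in deployment mode on a new H&E with no
multiplexed data at all:

```bash
hemux run --config cfg.yaml --inference
```

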