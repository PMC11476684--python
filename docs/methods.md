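# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `hemux`, and what the passing tests do and do not show.

## Problem setting

Adjacent serial sections of one tissue block are imaged twice: routine
H&E, and multiplexed immunofluorescence yielding a single-cell table
(x, y, and one intensity per marker of an M-marker panel; the default
panel is the 16-marker colorectal set: cytokeratin, Ki-67, CD3, CD20,
CD45RO, CD4, CD8a, CD68, CD163, FOXP3, PD1, PDL1, CD31, aSMA, desmin,
CD45). Sections are *nearly* the same cells, so supervision is only
meaningful at an aggregate scale: we predict per-tile expression, which
tolerates the few-micron residual misalignment that cell-level matching
cannot.

Coordinates are 0-based pixels, x = column, y = row, origin top-left.
Tiles are half-open boxes `[j·s, (j+1)·s) × [i·s, (i+1)·s)`, so every
in-bounds cell belongs to exactly one tile. The default tile side is
256 px ≈ 128 μm at 0.5 μm/px.

## Registration

Two stages, matching how serial sections actually disagree:

* **Global affine** (multiplexed frame → H&E frame). Working copies are
  capped at 2048 px. Stage one maximizes Mattes mutual information
  (50 bins; MI because cross-modality intensities are not comparable) over
  a 2-level pyramid (shrink 8, 4) with moments initialization and ITK
  gradient descent using per-iteration learning-rate estimation — plain
  fixed-step descent reliably stalled on 5°-rotation/5%-scale
  misalignments. Stage two polishes at shrink 2, 1 with a normalized
  correlation metric and regular-step descent, which settles sub-pixel
  where MI's sampling noise leaves a ~4 px wander. Correlation is
  polarity-insensitive here, so the fine stage works for both bright-field
  and fluorescence contrast; inputs should nevertheless be tissue-bright
  (the pipeline inverts H&E luminance) because the moments initializer
  centers on image mass. Blank or constant images raise a degenerate-input
  error.
* **Local refinement.** One translation per tile from the NCC peak
  (±32 px search, `skimage.feature.match_template`) of the affinely warped
  reference against the H&E, with 3-point parabolic subpixel refinement.
  Both images are high-pass filtered first (subtract a σ = 8 px Gaussian):
  modality-specific smooth structure — e.g. cytoplasmic stain present only
  in the H&E — otherwise dominates the correlation and drags peaks tens of
  pixels. Peak height is the tile's confidence; tiles below 0.3 inherit
  the confidence-weighted Gaussian-smoothed (σ = 1 tile) neighborhood
  value, confident tiles keep their own measurement (this preserves the
  per-tile improvement guarantee and avoids attenuating genuine smooth
  warps). The field is interpolated bilinearly between tile centers.

Cell mapping composes affine then local correction; out-of-bounds cells
are flagged, never silently dropped. On the default synthetic fixture
(planted 5° / 1.05× / (10, −20) px affine plus a 3 px sinusoidal residual,
period 8 tiles) the recovered transform leaves ≈ 1–1.4 px mean landmark
residual.

## Aggregation and normalization

Tile expression is the mean of `log1p` cell intensities (configurable:
mean, median, sum). The log tames the heavy right tail of fluorescence
intensities; `log1p` keeps zero a fixed point. Tiles without cells carry
NaN and are excluded from training, correlation and gating (rendered as
background in maps). z-scores use the population standard deviation
(denominator n) over a slide's tiles with cells; constant markers z-score
to 0 with a warning.

Splits are purely spatial. Quadrant boundaries sit at the midpoints of
the tissue bounding box; a tile is bottom-left when its center satisfies
center_x ≤ mid_x and center_y ≥ mid_y ("bottom" = larger row index, as
rendered). Within the bottom-left quadrant a tile is validation when its
left edge reaches the quadrant's right half, else test; everything else
trains. The left-edge rule makes the degenerate 1×1 grid come out `test`
(held out) rather than `val`, which is the conservative choice for a
boundary case. On a uniformly covered slide the train fraction is ≈ 75%.

## Embeddings and the regression head

Providers are frozen maps from an RGB tile to a feature vector:

* `meancolor` (d = 3): per-channel means — deliberately morphology-blind.
* `randproj` (d = 384): per-channel 8×8 block means and block standard
  deviations (384 local color/texture statistics) passed through a fixed,
  seeded Gaussian random projection. The projection is invertible almost
  surely, so the statistics stay recoverable; the provider stands in for a
  pretrained self-supervised backbone at desk scale without any weights to
  download. Block standard deviations matter: they give a *linear* readout
  of local texture energy, which purely pixel-level random features could
  not extract reliably at these sample sizes.
* `external`: an adapter slot for a real frozen backbone (any callable
  tile → vector); never required by tests.

The head is d → 256 → 256 → 256 → M, GELU, dropout 0.1, trained with Adam
(lr 1e-3, batch 256, up to 300 epochs) on mean squared error summed over
markers, early stopping with patience 10 on the validation split and
restoration of the best weights. Inputs are standardized on training
statistics (stored in the saved model) — without this, Adam converges
impractically slowly on [0, 1]-scaled color features. The mean-color
baseline uses `architecture="linear"`, a single linear layer trained the
same way. Everything is seeded: same seed, bit-identical training history
and predictions on one machine.

The augmentation policy (flips and 90° rotations p = 0.5; HED stain
jitter ±0.05, brightness/contrast/saturation ±10%, Gaussian blur
σ ∈ [0, 1], JPEG quality ∈ [60, 100], each p = 0.25) emulates scanner and
staining artifacts; labels are untouched by construction.

## Evaluation

Pearson r per (slide, split, marker); groups with fewer than 3 tiles or a
constant vector are reported undefined and excluded from medians (not set
to 0). Top-X% accuracy uses k = round(X·n/100), minimum 1, with ties at
the k-th value broken by ascending tile index so results are
deterministic; the overlap of two independent rankings is X% in
expectation, which the tests verify at n = 10 000. Under additive
Gaussian prediction noise of standard deviation σ on standardized targets,
r = 1/√(1+σ²) — the σ = 0.5 case (r ≈ 0.894) is checked as a closed-form
oracle.

## Gating and co-occurrence

Per slide and marker, a two-component Gaussian mixture (scikit-learn EM:
k-means++ init, 10 restarts, tol 1e-6, ≤ 500 iterations, seeded; spherical
covariance in 1-D) on the tile z-scores, requiring ≥ 50 values. Components
are ordered by mean; the decision threshold is the smallest value **within
[μ0, μ1]** whose posterior for the high component reaches 1/2, refined by
bisection. Restricting to the inter-mean interval matters: with unequal
variances the broad component also dominates the far-left tail, and the
unrestricted "smallest crossing" would call every tile positive. Fits
whose means differ by less than 0.1 pooled standard deviations are flagged
degenerate and call everything negative. Calls are threshold-monotone by
construction.

A co-occurrence class is a named marker subset; a tile belongs when all
members are called positive. For the confusion matrix each tile gets one
exclusive label — the largest matching class wins, earlier classes break
ties — plus a "none" background class; columns (predicted classes) are
normalized to sum to 1, so the diagonal is per-class precision. Empty
predicted classes are reported undefined. The enrichment test compares,
per slide, the fraction of context-positive tiles among interacting
(both pair markers positive) versus non-interacting tiles, and applies a
one-sided paired t-test across slides to the differences; slides lacking
either tile kind are dropped with a warning, fewer than 3 usable slides is
an error, and zero-variance differences are reported degenerate with no
p-value. "Interaction" is co-positivity within one tile — no spatial
adjacency beyond the tile is claimed.

## Synthetic study conditions

The default fixture is a 2048² px slide, 20 000 cells, 8 markers, seed 0:

* Tissue is a union of 6 random disks; cells are uniform over tissue.
* Each marker has a smooth Gaussian random field (correlation length
  48 px). The field's top 30% (within tissue) is the marker's positive
  region; cells draw log-normal intensities, log-mean 3.0 inside versus
  1.0 outside, log-sd 0.5. The 48 px correlation length gives the held-out
  quadrant enough independent field patches that a near-zero correlation
  bound is statistically meaningful; much longer fields make any
  correlation estimate on one quadrant unstable.
* PD1/PDL1 share 80% of their field and CD4/FOXP3 70%, planting tile-level
  co-occurrence in the measured data.
* The H&E is rendered by *linear* transmitted-light stain mixing
  (1 − 0.45·OD with H&E-like absorption vectors) plus Gaussian pixel noise
  (sd 0.02). Hematoxylin density = 0.25 + 0.1·f(Ki-67) + 0.6·stipple +
  0.5·f(Ki-67)·stripes, where stipple is the blurred cell point pattern
  and stripes is a zero-mean 8 px chromatin-like texture; eosin density =
  0.20 + 0.9·f(cytokeratin). So the stromal marker is readable from mean
  color while the proliferation marker lives mostly in texture amplitude —
  mean-color baselines have signal, texture-aware providers have more.
  Linear mixing (rather than Beer–Lambert exponentials) keeps the
  zero-mean texture exactly invisible to tile-mean color; with the
  exponential, convexity leaks texture amplitude into the mean.
* The nuclear reference shares the chromatin texture and stipple (it is
  the same physical structure on an adjacent section) and is rendered in
  the warped frame: planted affine 5° rotation, 1.05 scale, (10, −20) px
  shift about the center, plus a 3 px sinusoidal residual with period
  8 tiles. Cell coordinates are emitted in the warped frame.

What this fixture does **not** emulate: real nuclear morphology,
staining chemistry, section-to-section biological variation, imaging
artifacts (the grid patterns of cyclic acquisition), or any cell-type
structure beyond the planted fields. Passing tests therefore demonstrate
that the pipeline's machinery is correct and identifiable under its own
assumptions — not that any particular correlation level will be reached
on real tissue.

## Desk-scale problem sizes

End-to-end runs on the default fixture use 64 px tiles (≈ 800 tissue
tiles, ~25 cells each). At the 256 px production default a 2048² slide
yields only ~40 tissue tiles — too few to fit per-slide mixtures (≥ 50
values required) or estimate held-out correlations stably; 64 px tiles
keep every stage statistically meaningful at a size that runs in about a
minute. The registration stage keeps the 256 px grid for its local
refinement. The full test suite and the acceptance script each finish in
a few minutes on one CPU.

## Known limitations

* The local alignment model is translation-only per tile; strong local
  rotation or shear between sections is absorbed only as far as the
  smoothed translation field allows.
* Gating operates on z-scores by default (config-switchable to raw);
  published single-cell tables sometimes gate on log intensities, and
  thresholds are not transferable between conventions.
* Group correlations on few tiles are noisy; medians across slides are
  only reported over defined groups.
* The external-backbone adapter is an interface, not an integration: no
  pretrained weights ship with the package.
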