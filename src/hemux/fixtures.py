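"""Seeded synthetic paired "H&E"/"CyCIF" data with full ground truth.

The generator emulates the statistical structure the pipeline assumes —
not histology itself:

* a tissue region (union of random disks) on a white background;
* per-marker smooth random fields defining where the marker is "on": cells
  inside a marker's positive region draw log-intensities from the positive
  component of a two-component log-normal mixture, all others from the
  background component;
* an H&E-like RGB rendered through Beer–Lambert stain optics, where the
  hematoxylin density tracks one planted marker field (a proliferation-like
  marker) plus a fine cell stipple, and the eosin density tracks a second
  (stromal) marker — so color/texture carry real signal for the coupled
  markers and none for the decoupled ones;
* a single-channel "CyCIF" nuclear reference rendered in a warped frame:
  the planted ground-truth warp (affine about the image center plus a
  smooth sinusoidal residual) maps H&E-frame positions to CyCIF-frame
  positions, and cell coordinates are emitted in the CyCIF frame.

Everything is a pure function of the spec and seed: the same spec gives
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import CellTable
from .panel import MarkerPanel
from .registration import AffineTransform
from .tiling import TileGrid
from .gating import CooccurrenceClass

FIXTURE_MARKERS = (
    "Ki-67",        # coupled: drives hematoxylin density
    "cytokeratin",  # coupled: drives eosin density
    "CD45",
    "CD4",
    "FOXP3",
    "CD8a",
    "PD1",
    "PDL1",
)

FIXTURE_CLASSES = (
    CooccurrenceClass("PD1+/PDL1+", ("PD1", "PDL1")),
    CooccurrenceClass("CD4+/FOXP3+", ("CD4", "FOXP3")),
    CooccurrenceClass("Ki-67+/cytokeratin+", ("Ki-67", "cytokeratin")),
)

# Beer-Lambert stain absorption vectors (R, G, B), roughly H&E-like
_STAIN_H = np.array([0.65, 0.70, 0.29])
_STAIN_E = np.array([0.07, 0.99, 0.11])


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions of the default desk-scale paired fixture."""

    image_size: int = 2048
    n_cells: int = 20_000
    panel: MarkerPanel = field(default_factory=lambda: MarkerPanel(FIXTURE_MARKERS))
    coupled_markers: tuple[str, ...] = ("Ki-67", "cytokeratin")
    n_tissue_disks: int = 6
    field_sigma_px: float = 48.0  # correlation length of marker fields
    positive_fraction: float = 0.3
    log_mu_background: float = 1.0
    log_mu_positive: float = 3.0
    log_sd: float = 0.5
    image_noise_sd: float = 0.02
    # planted warp: H&E frame -> CyCIF frame
    rotation_deg: float = 5.0
    scale: float = 1.05
    translation: tuple[float, float] = (10.0, -20.0)
    warp_amplitude_px: float = 3.0
    warp_period_tiles: float = 8.0
    tile_size_px: int = 256
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    spec: FixtureSpec
    affine_he_to_cy: AffineTransform
    fields: np.ndarray          # (M, H, W) smooth marker fields in [0, 1]
    positive_masks: np.ndarray  # (M, H, W) bool positive regions
    cell_xy_he: np.ndarray      # (n, 2) cell positions in the H&E frame
    cell_positive: np.ndarray   # (n, M) bool true mixture component
    tissue_mask: np.ndarray     # (H, W) bool
    coupled_indices: tuple[int, ...]
    classes: tuple[CooccurrenceClass, ...]

    def warp(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Planted forward warp: H&E-frame (x, y) -> CyCIF-frame (x, y)."""
        ax, ay = self.affine_he_to_cy.apply(x, y)
        dx, dy = _sinusoid(self.spec, np.asarray(x, float), np.asarray(y, float))
        return ax + dx, ay + dy

    def landmark_grid(self, n_per_side: int = 16) -> np.ndarray:
        s = self.spec.image_size
        coords = np.linspace(0.1 * s, 0.9 * s, n_per_side)
        xx, yy = np.meshgrid(coords, coords)
        return np.column_stack([xx.ravel(), yy.ravel()])


def _sinusoid(
    spec: FixtureSpec, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    period = spec.warp_period_tiles * spec.tile_size_px
    a = spec.warp_amplitude_px
    k = 2 * np.pi / period
    return a * np.sin(k * y), a * np.cos(k * x)


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    noise = rng.normal(size=shape)
    f = ndimage.gaussian_filter(noise, sigma, mode="reflect")
    f -= f.min()
    rng_span = f.max() - f.min()
    return f / rng_span if rng_span > 0 else f


def generate_pair(
    spec: FixtureSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, CellTable, GroundTruth]:
    """Generate one paired slide: (he_rgb, cycif_ref, cells, ground_truth).

    ``he_rgb`` is (H, W, 3) float in [0, 1] in the H&E frame; ``cycif_ref``
    (H, W) float in [0, 1] in the warped CyCIF frame; the cell table's
    coordinates are in the CyCIF frame with intensities drawn from the
    planted mixture at each cell's true (H&E-frame) location.
    """
    spec = spec or FixtureSpec()
    n = spec.image_size
    rng = np.random.default_rng(spec.seed)
    M = len(spec.panel)

    # --- tissue geometry: union of disks
    yy, xx = np.mgrid[0:n, 0:n]
    tissue = np.zeros((n, n), dtype=bool)
    for _ in range(spec.n_tissue_disks):
        cx, cy = rng.uniform(0.2 * n, 0.8 * n, size=2)
        r = rng.uniform(0.15 * n, 0.35 * n)
        tissue |= (xx - cx) ** 2 + (yy - cy) ** 2 < r**2
    if not tissue.any():
        raise ValueError("fixture spec produced zero tissue area")

    # --- marker fields (downsampled for speed, then upsampled)
    ds = 8
    small = (n // ds, n // ds)
    coupled_idx = tuple(spec.panel.index(m) for m in spec.coupled_markers)
    fields = np.zeros((M, n, n))
    raw_small = {}
    for m in range(M):
        raw_small[m] = _smooth_field(small, spec.field_sigma_px / ds, rng)
    # plant co-occurrence: PD1 and PDL1 share most of their field
    if "PD1" in spec.panel.names and "PDL1" in spec.panel.names:
        i1 = spec.panel.index("PD1")
        i2 = spec.panel.index("PDL1")
        shared = _smooth_field(small, spec.field_sigma_px / ds, rng)
        raw_small[i1] = 0.8 * shared + 0.2 * raw_small[i1]
        raw_small[i2] = 0.8 * shared + 0.2 * raw_small[i2]
    if all(mk in spec.panel.names for mk in ("CD4", "FOXP3")):
        i1 = spec.panel.index("CD4")
        i2 = spec.panel.index("FOXP3")
        shared = _smooth_field(small, spec.field_sigma_px / ds, rng)
        raw_small[i1] = 0.7 * shared + 0.3 * raw_small[i1]
        raw_small[i2] = 0.7 * shared + 0.3 * raw_small[i2]
    for m in range(M):
        fields[m] = np.repeat(np.repeat(raw_small[m], ds, 0), ds, 1)[:n, :n]

    positive_masks = np.zeros((M, n, n), dtype=bool)
    for m in range(M):
        thr = np.quantile(fields[m][tissue], 1.0 - spec.positive_fraction)
        positive_masks[m] = fields[m] > thr

    # --- cells: uniform over tissue
    t_idx = np.flatnonzero(tissue.ravel())
    pick = rng.choice(t_idx, size=spec.n_cells, replace=True)
    cy_r, cx_c = np.divmod(pick, n)
    cell_x = cx_c + rng.uniform(0, 1, spec.n_cells)
    cell_y = cy_r + rng.uniform(0, 1, spec.n_cells)
    cell_px = np.clip(cell_x.astype(int), 0, n - 1)
    cell_py = np.clip(cell_y.astype(int), 0, n - 1)

    cell_positive = positive_masks[:, cell_py, cell_px].T  # (n_cells, M)
    log_mu = np.where(cell_positive, spec.log_mu_positive, spec.log_mu_background)
    expr = np.exp(rng.normal(log_mu, spec.log_sd))

    # --- nuclear density (stipple): cells rendered as blurred points
    stipple = np.zeros((n, n))
    np.add.at(stipple, (cell_py, cell_px), 1.0)
    stipple = ndimage.gaussian_filter(stipple, 2.0)
    if stipple.max() > 0:
        stipple = stipple / stipple.max()

    # --- H&E rendering: stain densities track the density of marker-positive
    # tissue for the coupled markers (it is the positive cells that stain),
    # plus the nuclear stipple. The first coupled (proliferation-like)
    # marker expresses mostly through a fine chromatin-like texture whose
    # local amplitude follows its positive density — zero-mean at tile
    # scale, so mean-color features see only its weak flat component while
    # texture-aware features see the full signal; the second (stromal)
    # marker is a flat eosin coupling that mean color captures directly.
    f_h = (
        ndimage.gaussian_filter(positive_masks[coupled_idx[0]].astype(float), 16.0)
        if len(coupled_idx) > 0
        else np.zeros((n, n))
    )
    f_e = (
        ndimage.gaussian_filter(positive_masks[coupled_idx[1]].astype(float), 16.0)
        if len(coupled_idx) > 1
        else np.zeros((n, n))
    )
    stripes = np.sin(2 * np.pi * xx / 8.0) * np.sin(2 * np.pi * yy / 8.0)
    dens_h = np.where(
        tissue, 0.25 + 0.1 * f_h + 0.6 * stipple + 0.5 * f_h * stripes, 0.0
    )
    dens_e = np.where(tissue, 0.20 + 0.9 * f_e, 0.0)
    od = dens_h[..., None] * _STAIN_H + dens_e[..., None] * _STAIN_E
    # linear transmitted-light mixing keeps zero-mean texture invisible to
    # tile-mean color exactly
    he_rgb = 1.0 - 0.45 * od
    he_rgb += rng.normal(0.0, spec.image_noise_sd, he_rgb.shape)
    he_rgb = np.clip(he_rgb, 0.0, 1.0)

    # --- planted warp and the CyCIF-frame reference image
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    affine = AffineTransform.from_params(
        rotation_deg=spec.rotation_deg,
        scale=spec.scale,
        translation=spec.translation,
        center=center,
    )
    truth = GroundTruth(
        spec=spec,
        affine_he_to_cy=affine,
        fields=fields,
        positive_masks=positive_masks,
        cell_xy_he=np.column_stack([cell_x, cell_y]),
        cell_positive=cell_positive,
        tissue_mask=tissue,
        coupled_indices=coupled_idx,
        classes=FIXTURE_CLASSES,
    )

    # chromatin-like texture shows in the DNA reference as well as in the
    # hematoxylin — it is the same physical structure on adjacent sections
    nuclear = np.where(
        tissue, 0.15 + 0.5 * f_h + 0.8 * stipple + 0.4 * f_h * stripes, 0.0
    )
    nuclear = np.clip(nuclear, 0.0, 1.0)
    # sample nuclear at W^{-1}(q) for each CyCIF-frame pixel q; the residual
    # warp is small and smooth, so a first-order inverse suffices
    inv = affine.inverse()
    qx, qy = xx.astype(float), yy.astype(float)
    px0, py0 = inv.apply(qx, qy)
    dx, dy = _sinusoid(spec, px0, py0)
    px, py = px0 - inv.matrix[0, 0] * dx - inv.matrix[0, 1] * dy, py0 - inv.matrix[
        1, 0
    ] * dx - inv.matrix[1, 1] * dy
    cycif_ref = ndimage.map_coordinates(
        nuclear, [py.ravel(), px.ravel()], order=1, mode="constant", cval=0.0
    ).reshape(n, n)
    cycif_ref = np.clip(
        cycif_ref + rng.normal(0.0, spec.image_noise_sd, cycif_ref.shape), 0.0, 1.0
    )

    wx, wy = truth.warp(cell_x, cell_y)
    cells = CellTable(
        x=wx, y=wy, expr=expr, panel=spec.panel, cell_id=np.arange(spec.n_cells)
    )
    return he_rgb, cycif_ref, cells, truth


def generate_cells_only(
    spec: FixtureSpec, rng_offset: int = 0
) -> tuple[CellTable, GroundTruth]:
    """Cheap variant for aggregation tests: identity warp, no images."""
    spec2 = replace(
        spec,
        rotation_deg=0.0,
        scale=1.0,
        translation=(0.0, 0.0),
        warp_amplitude_px=0.0,
        seed=spec.seed + rng_offset,
    )
    _, _, cells, truth = generate_pair(spec2)
    return cells, truth


def generate_linear_regression_fixture(
    d: int, M: int, n: int, noise_sd: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear teacher data: embeddings E ~ N(0,1), targets E @ W + noise.

    Returns ``(E, Z, W)`` with ``W`` of shape (d, M), for weight-recovery
    tests against an ordinary-least-squares oracle.
    """
    if d <= 0 or M <= 0 or n <= 0:
        raise ValueError("d, M, n must be positive")
    rng = np.random.default_rng(seed)
    E = rng.normal(size=(n, d))
    W = rng.normal(size=(d, M))
    Z = E @ W + rng.normal(0.0, noise_sd, size=(n, M))
    return E, Z, W


def tile_grid_for_spec(spec: FixtureSpec) -> TileGrid:
    return TileGrid.for_image((spec.image_size, spec.image_size), spec.tile_size_px)
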