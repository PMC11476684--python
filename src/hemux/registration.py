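"""Serial-section registration: whole-slide affine then tile-level refinement.

Adjacent tissue slices stained differently (H&E vs multiplexed
immunofluorescence) are nearly, but not exactly, the same tissue. A single
affine transform captures the slide-level pose (rotation, scale, shear,
shift); the residual is a smooth, spatially varying misalignment from
sectioning and mounting. We model that residual as one translation per tile,
estimated by normalized cross-correlation, smoothed across the tile grid and
interpolated to pixel resolution.

Conventions: :class:`AffineTransform` maps multiplexed-frame pixel ``(x, y)``
to H&E-frame pixel; the displacement field is a *correction in the H&E
frame* — content that the affine places at H&E position ``p`` actually
belongs at ``p + d(p)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage.feature import match_template

from .io import CellTable
from .tiling import TileGrid


class DegenerateImageError(ValueError):
    """Raised when an image has no usable contrast for registration."""


class RegistrationError(RuntimeError):
    """Raised when the similarity optimization fails to converge."""


@dataclass(frozen=True)
class AffineTransform:
    """2x3 matrix mapping multiplexed-frame (x, y, 1) to H&E-frame (x, y)."""

    matrix: np.ndarray  # (2, 3)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        det = np.linalg.det(m[:, :2])
        if not np.isfinite(det) or abs(det) < 1e-12:
            raise ValueError("linear part of affine is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_params(
        cls,
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        translation: tuple[float, float] = (0.0, 0.0),
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform":
        """Similarity transform rotating/scaling about ``center`` then shifting."""
        th = np.deg2rad(rotation_deg)
        L = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float) + c - L @ c
        return cls(np.column_stack([L, t]))

    def apply(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        m = self.matrix
        return (
            m[0, 0] * x + m[0, 1] * y + m[0, 2],
            m[1, 0] * x + m[1, 1] * y + m[1, 2],
        )

    def inverse(self) -> "AffineTransform":
        L = self.matrix[:, :2]
        t = self.matrix[:, 2]
        Li = np.linalg.inv(L)
        return AffineTransform(np.column_stack([Li, -Li @ t]))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self ∘ other (apply ``other`` first)."""
        L1, t1 = self.matrix[:, :2], self.matrix[:, 2]
        L2, t2 = other.matrix[:, :2], other.matrix[:, 2]
        return AffineTransform(np.column_stack([L1 @ L2, L1 @ t2 + t1]))


@dataclass
class LocalDisplacementField:
    """Per-tile (dx, dy) corrections in pixels with per-tile confidence."""

    dx: np.ndarray  # (n_rows, n_cols)
    dy: np.ndarray
    confidence: np.ndarray
    tile_size_px: int

    def interpolate(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bilinear interpolation of tile-center vectors at pixel positions."""
        n_rows, n_cols = self.dx.shape
        s = self.tile_size_px
        centers_y = (np.arange(n_rows) + 0.5) * s
        centers_x = (np.arange(n_cols) + 0.5) * s
        pts = np.column_stack(
            [
                np.clip(np.asarray(y, float).ravel(), centers_y[0], centers_y[-1]),
                np.clip(np.asarray(x, float).ravel(), centers_x[0], centers_x[-1]),
            ]
        )
        if n_rows == 1 and n_cols == 1:
            shape = np.shape(x)
            return (np.full(shape, self.dx[0, 0]), np.full(shape, self.dy[0, 0]))
        kwargs = dict(bounds_error=False, fill_value=None)
        if n_rows == 1 or n_cols == 1:
            # degenerate axis: interpolate along the non-degenerate one
            axis_pts = pts[:, 1] if n_rows == 1 else pts[:, 0]
            grid = centers_x if n_rows == 1 else centers_y
            dxv = np.interp(axis_pts, grid, self.dx.ravel())
            dyv = np.interp(axis_pts, grid, self.dy.ravel())
        else:
            fx = RegularGridInterpolator((centers_y, centers_x), self.dx, **kwargs)
            fy = RegularGridInterpolator((centers_y, centers_x), self.dy, **kwargs)
            dxv = fx(pts)
            dyv = fy(pts)
        return dxv.reshape(np.shape(x)), dyv.reshape(np.shape(x))

    def dense(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.interpolate(xx, yy)


@dataclass
class RegistrationConfig:
    """Knobs for the two registration stages.

    ``metric`` is the slide-level similarity ("mattes" mutual information by
    default — cross-modality intensities are not directly comparable — or
    "correlation"); the local stage always uses normalized cross-correlation
    restricted to ``max_displacement_px``.
    """

    metric: str = "mattes"
    working_size_px: int = 2048
    shrink_factors: tuple[int, ...] = (8, 4, 1)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    sampling_fractions: tuple[float, ...] = (0.5, 0.25, 0.05)
    histogram_bins: int = 50
    learning_rate: float = 1.0
    min_step: float = 1e-4
    iterations: int = 300
    max_displacement_px: int = 32
    confidence_threshold: float = 0.3
    smoothing_sigma_tiles: float = 1.0
    highpass_sigma_px: float = 8.0  # local stage: remove modality-specific
    # smooth structure before NCC; 0 disables
    seed: int = 0


def _to_sitk(img: np.ndarray) -> sitk.Image:
    lo, hi = float(np.min(img)), float(np.max(img))
    arr = (img - lo) / (hi - lo) if hi > lo else img * 0.0
    return sitk.GetImageFromArray(arr.astype(np.float32))


def _check_contrast(img: np.ndarray, name: str) -> None:
    img = np.asarray(img)
    if img.size == 0 or float(np.std(img)) < 1e-8:
        raise DegenerateImageError(f"{name} image is blank/constant; cannot register")


def estimate_global_affine(
    he_gray: np.ndarray,
    cycif_ref: np.ndarray,
    config: RegistrationConfig | None = None,
) -> AffineTransform:
    """Whole-slide affine aligning the multiplexed reference onto the H&E.

    Multi-resolution (coarse-to-fine) maximization of the configured
    similarity metric, moments-based initialization. Returns the transform
    mapping multiplexed-frame pixels into the H&E frame.

    Both inputs must be single-channel with tissue *bright* on a dark
    background — bright-field grayscale should be inverted first (the
    moments initializer centers on image mass). The pipeline does this for
    the H&E luminance automatically.
    """
    config = config or RegistrationConfig()
    he_gray = np.asarray(he_gray, dtype=float)
    cycif_ref = np.asarray(cycif_ref, dtype=float)
    _check_contrast(he_gray, "H&E")
    _check_contrast(cycif_ref, "reference")

    # cap the working copy; the transform is rescaled back afterwards
    f = max(
        1,
        int(np.ceil(max(he_gray.shape + cycif_ref.shape) / config.working_size_px)),
    )
    he_w = he_gray[::f, ::f]
    cy_w = cycif_ref[::f, ::f]

    fixed = _to_sitk(he_w)
    moving = _to_sitk(cy_w)

    # stage 1: coarse capture with the configured (cross-modality) metric,
    # gradient descent with per-iteration step estimation
    reg = sitk.ImageRegistrationMethod()
    if config.metric == "mattes":
        reg.SetMetricAsMattesMutualInformation(config.histogram_bins)
    elif config.metric == "correlation":
        reg.SetMetricAsCorrelation()
    else:
        raise ValueError(f"unknown metric {config.metric!r}")
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    itk_seed = (config.seed % (2**31 - 2)) + 1  # ITK: seed 0 = wall clock
    reg.SetMetricSamplingPercentagePerLevel(
        list(config.sampling_fractions[:2]), itk_seed
    )
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsGradientDescent(
        learningRate=config.learning_rate,
        numberOfIterations=config.iterations,
        estimateLearningRate=reg.EachIteration,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    init = sitk.CenteredTransformInitializer(
        fixed,
        moving,
        sitk.AffineTransform(2),
        sitk.CenteredTransformInitializerFilter.MOMENTS,
    )
    reg.SetInitialTransform(init, inPlace=True)
    reg.SetShrinkFactorsPerLevel(list(config.shrink_factors[:2]))
    reg.SetSmoothingSigmasPerLevel(list(config.smoothing_sigmas[:2]))
    try:
        stage1 = sitk.AffineTransform(reg.Execute(fixed, moving))
    except RuntimeError as e:  # pragma: no cover - ITK failure path
        raise RegistrationError(f"coarse similarity optimization failed: {e}") from e

    # stage 2: fine polish by normalized correlation (polarity-insensitive)
    # with a regular-step descent that settles tightly at the optimum
    reg2 = sitk.ImageRegistrationMethod()
    reg2.SetMetricAsCorrelation()
    reg2.SetMetricSamplingStrategy(reg2.REGULAR)
    reg2.SetMetricSamplingPercentagePerLevel([0.25, 0.1], itk_seed)
    reg2.SetInterpolator(sitk.sitkLinear)
    reg2.SetOptimizerAsRegularStepGradientDescent(
        learningRate=config.learning_rate,
        minStep=config.min_step * 1e-2,
        numberOfIterations=config.iterations,
        relaxationFactor=0.5,
        gradientMagnitudeTolerance=1e-8,
    )
    reg2.SetOptimizerScalesFromPhysicalShift()
    reg2.SetInitialTransform(stage1, inPlace=True)
    reg2.SetShrinkFactorsPerLevel([2, 1])
    reg2.SetSmoothingSigmasPerLevel([1.0, 0.0])
    try:
        out = sitk.AffineTransform(reg2.Execute(fixed, moving))
    except RuntimeError as e:  # pragma: no cover - ITK failure path
        raise RegistrationError(f"fine similarity optimization failed: {e}") from e
    final_metric = reg2.GetMetricValue()
    if not np.isfinite(final_metric):
        raise RegistrationError(
            f"optimization did not converge (final metric {final_metric})"
        )
    # sitk transform maps fixed (H&E) physical points -> moving (ref) points;
    # with unit spacing physical == pixel (x, y). Invert for ref -> H&E.
    M = np.array(out.GetMatrix()).reshape(2, 2)
    c = np.array(out.GetCenter())
    t = np.array(out.GetTranslation())
    offset = t + c - M @ c
    he_to_cy_w = AffineTransform(np.column_stack([M, offset]))
    cy_to_he_w = he_to_cy_w.inverse()
    # undo the working-copy downsampling: x_orig = f * x_work
    S = AffineTransform(np.array([[f, 0, 0], [0, f, 0]], dtype=float))
    Si = S.inverse()
    return S.compose(cy_to_he_w).compose(Si)


def warp_reference(
    cycif_ref: np.ndarray, affine: AffineTransform, out_shape: tuple[int, int]
) -> np.ndarray:
    """Resample the multiplexed reference onto the H&E pixel grid."""
    inv = affine.inverse()  # H&E (x,y) -> reference (x,y)
    L = inv.matrix[:, :2]
    t = inv.matrix[:, 2]
    # scipy works in (row, col) = (y, x): swap axes of the map
    M_rc = np.array([[L[1, 1], L[1, 0]], [L[0, 1], L[0, 0]]])
    off_rc = np.array([t[1], t[0]])
    return ndimage.affine_transform(
        np.asarray(cycif_ref, dtype=float),
        M_rc,
        offset=off_rc,
        output_shape=out_shape,
        order=1,
        mode="constant",
        cval=0.0,
    )


def _parabolic_offset(ncc: np.ndarray, peak: tuple, axis: int) -> float:
    """Subpixel peak offset along one axis by 3-point parabola fit."""
    idx = peak[axis]
    if idx == 0 or idx >= ncc.shape[axis] - 1:
        return 0.0
    sl = list(peak)
    sl[axis] = slice(idx - 1, idx + 2)
    y0, y1, y2 = ncc[tuple(sl)]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-12:
        return 0.0
    off = 0.5 * (y0 - y2) / denom
    return float(np.clip(off, -0.5, 0.5))


def _ncc_sign(a: np.ndarray, b: np.ndarray) -> float:
    av = a - a.mean()
    bv = b - b.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    return float((av * bv).sum() / denom) if denom > 0 else 0.0


def refine_local(
    he_gray: np.ndarray,
    cycif_ref: np.ndarray,
    affine: AffineTransform,
    grid: TileGrid,
    config: RegistrationConfig | None = None,
) -> LocalDisplacementField:
    """Per-tile translation correction after the global affine.

    For each tile, the affinely warped reference patch is matched against the
    surrounding H&E window by normalized cross-correlation within
    ``±max_displacement_px``; the (parabolically subpixel-refined) peak
    location is the tile's correction and the peak height its confidence.
    Confident tiles keep their own measurement; tiles whose peak falls below
    ``confidence_threshold`` inherit the confidence-weighted
    Gaussian-smoothed neighborhood value (sigma in tiles). The field is
    interpolated bilinearly for pixel-resolution use.
    """
    config = config or RegistrationConfig()
    he = np.asarray(he_gray, dtype=float)
    warped = warp_reference(cycif_ref, affine, he.shape)
    if config.highpass_sigma_px > 0:
        # suppress modality-specific smooth structure (e.g. cytoplasmic
        # stain); matching relies on the shared fine texture
        he = he - ndimage.gaussian_filter(he, config.highpass_sigma_px)
        warped = warped - ndimage.gaussian_filter(warped, config.highpass_sigma_px)
    # H&E nuclei are dark where fluorescence is bright; flip sign if needed
    if _ncc_sign(he, warped) < 0:
        he = -he
    s = grid.tile_size_px
    md = int(config.max_displacement_px)
    n_rows, n_cols = grid.n_rows, grid.n_cols
    dx = np.zeros((n_rows, n_cols))
    dy = np.zeros((n_rows, n_cols))
    conf = np.zeros((n_rows, n_cols))
    n_clamped = 0
    for i in range(n_rows):
        for j in range(n_cols):
            y0, y1 = i * s, min((i + 1) * s, he.shape[0])
            x0, x1 = j * s, min((j + 1) * s, he.shape[1])
            template = warped[y0:y1, x0:x1]
            wy0, wy1 = max(0, y0 - md), min(he.shape[0], y1 + md)
            wx0, wx1 = max(0, x0 - md), min(he.shape[1], x1 + md)
            window = he[wy0:wy1, wx0:wx1]
            if (
                template.size == 0
                or template.std() < 1e-8
                or window.std() < 1e-8
                or window.shape[0] < template.shape[0]
                or window.shape[1] < template.shape[1]
            ):
                continue
            ncc = match_template(window, template)
            peak = np.unravel_index(np.argmax(ncc), ncc.shape)
            score = float(ncc[peak])
            sub_y = _parabolic_offset(ncc, peak, axis=0)
            sub_x = _parabolic_offset(ncc, peak, axis=1)
            dyv = (wy0 + peak[0] + sub_y) - y0
            dxv = (wx0 + peak[1] + sub_x) - x0
            if abs(dxv) > md or abs(dyv) > md:
                n_clamped += 1
                dxv = float(np.clip(dxv, -md, md))
                dyv = float(np.clip(dyv, -md, md))
            dx[i, j] = dxv
            dy[i, j] = dyv
            conf[i, j] = float(np.clip(score, 0.0, 1.0))

    sig = config.smoothing_sigma_tiles
    w = conf.copy()
    if w.sum() > 0:
        num_x = ndimage.gaussian_filter(dx * w, sig, mode="nearest")
        num_y = ndimage.gaussian_filter(dy * w, sig, mode="nearest")
        den = ndimage.gaussian_filter(w, sig, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm_x = np.where(den > 1e-12, num_x / np.maximum(den, 1e-12), 0.0)
            sm_y = np.where(den > 1e-12, num_y / np.maximum(den, 1e-12), 0.0)
        low = conf < config.confidence_threshold
        dx = np.where(low, sm_x, dx)
        dy = np.where(low, sm_y, dy)
    return LocalDisplacementField(dx=dx, dy=dy, confidence=conf, tile_size_px=s)


def map_cells(
    cells: CellTable,
    affine: AffineTransform,
    field: LocalDisplacementField | None = None,
    bounds: tuple[int, int] | None = None,
) -> CellTable:
    """Map cell coordinates from the multiplexed frame into the H&E frame.

    Composes the affine with the local correction field. Cells landing
    outside ``bounds`` (H&E ``(height, width)``) are flagged via
    ``in_bounds`` — they are excluded downstream, never dropped here.
    """
    x, y = affine.apply(cells.x, cells.y)
    if field is not None:
        ddx, ddy = field.interpolate(x, y)
        x = x + ddx
        y = y + ddy
    in_bounds = np.ones(len(cells), dtype=bool)
    if bounds is not None:
        h, w = bounds
        in_bounds = (x >= 0) & (x < w) & (y >= 0) & (y < h)
    return CellTable(
        x=x,
        y=y,
        expr=cells.expr,
        panel=cells.panel,
        cell_id=cells.cell_id,
        in_bounds=in_bounds,
    )


def mean_tile_ncc(
    he_gray: np.ndarray,
    cycif_ref: np.ndarray,
    affine: AffineTransform,
    grid: TileGrid,
    field: LocalDisplacementField | None = None,
) -> float:
    """Mean per-tile |NCC| between H&E and the (optionally corrected) warp.

    Used to verify that local refinement does not degrade alignment.
    """
    he = np.asarray(he_gray, dtype=float)
    warped = warp_reference(cycif_ref, affine, he.shape)
    s = grid.tile_size_px
    scores = []
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            y0, y1 = i * s, min((i + 1) * s, he.shape[0])
            x0, x1 = j * s, min((j + 1) * s, he.shape[1])
            if field is None:
                dxv = dyv = 0
            else:
                dxv = int(round(field.dx[i, j]))
                dyv = int(round(field.dy[i, j]))
            sy0, sy1 = y0 + dyv, y1 + dyv
            sx0, sx1 = x0 + dxv, x1 + dxv
            if sy0 < 0 or sx0 < 0 or sy1 > he.shape[0] or sx1 > he.shape[1]:
                continue
            t = warped[y0:y1, x0:x1]
            h = he[sy0:sy1, sx0:sx1]
            if t.std() < 1e-8 or h.std() < 1e-8:
                continue
            scores.append(abs(_ncc_sign(h, t)))
    return float(np.mean(scores)) if scores else 0.0


# ---------------------------------------------------------------------------
# persistence


def save_transform(
    path: str | Path,
    affine: AffineTransform,
    field: LocalDisplacementField | None = None,
) -> None:
    doc: dict = {"affine": affine.matrix.tolist()}
    if field is not None:
        doc["local_field"] = {
            "dx": field.dx.tolist(),
            "dy": field.dy.tolist(),
            "confidence": field.confidence.tolist(),
            "tile_size_px": field.tile_size_px,
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_transform(
    path: str | Path,
) -> tuple[AffineTransform, LocalDisplacementField | None]:
    doc = json.loads(Path(path).read_text())
    affine = AffineTransform(np.array(doc["affine"]))
    field = None
    if "local_field" in doc:
        lf = doc["local_field"]
        field = LocalDisplacementField(
            dx=np.array(lf["dx"]),
            dy=np.array(lf["dy"]),
            confidence=np.array(lf["confidence"]),
            tile_size_px=int(lf["tile_size_px"]),
        )
    return affine, field
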