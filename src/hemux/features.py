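"""Tile embedding providers and H&E-specific training augmentation.

Providers turn a 256×256 RGB tile into a fixed-length feature vector:

* :class:`MeanColorEmbedder` — the 3 per-channel mean intensities; the
  deliberately morphology-blind baseline.
* :class:`RandomFeatureEmbedder` — a frozen, seeded random-feature map
  (cosine features of downsampled pixels), d = 384 by default. It stands in
  for a pretrained self-supervised backbone at desk scale: deterministic,
  no weights to download, and it sees texture as well as color.
* :class:`ExternalEmbedder` — adapter slot for a real pretrained backbone;
  raises a clear error when no adapter function is supplied.

Augmentation emulates histology scan artifacts (staining intensity, focus,
compression) without touching the regression target: flips/90° rotations,
stain-space (HED) jitter, brightness/contrast jitter, Gaussian blur and
JPEG re-encoding, each applied with configured probability from a seeded
generator.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import hed2rgb, rgb2hed


def _check_tile(tile: np.ndarray) -> np.ndarray:
    tile = np.asarray(tile, dtype=float)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB tile, got shape {tile.shape}")
    return tile


def mean_color_embed(tile_rgb: np.ndarray) -> np.ndarray:
    """Per-channel mean intensity of an RGB tile (values in [0, 1])."""
    tile = _check_tile(tile_rgb)
    return tile.reshape(-1, 3).mean(axis=0)


class MeanColorEmbedder:
    name = "meancolor"
    dim = 3
    deterministic = True

    def embed(self, tile_rgb: np.ndarray) -> np.ndarray:
        return mean_color_embed(tile_rgb)

    def embed_batch(self, tiles: list[np.ndarray]) -> np.ndarray:
        return np.stack([self.embed(t) for t in tiles]) if tiles else np.zeros((0, 3))


class RandomFeatureEmbedder:
    """Frozen seeded random projection of local color/texture statistics.

    The tile is summarized by 8×8 per-channel block means (coarse color and
    layout) and 8×8 per-channel block standard deviations (local texture
    energy) — 384 statistics — and projected through a fixed Gaussian
    linear map drawn once from a seeded generator. The map is invertible
    almost surely, so the statistics remain recoverable downstream, and the
    same tile always maps to the same vector.
    """

    deterministic = True
    _GRID = 8
    _N_STATS = 2 * _GRID * _GRID * 3

    def __init__(self, dim: int = 384, seed: int = 0):
        self.name = "randproj"
        self.dim = dim
        rng = np.random.default_rng(seed)
        self._W = rng.normal(0.0, 1.0 / np.sqrt(self._N_STATS), (dim, self._N_STATS))

    def _stats(self, tile: np.ndarray) -> np.ndarray:
        h, w, _ = tile.shape
        g = self._GRID
        ys = (np.arange(h) * g // h).astype(int)
        xs = (np.arange(w) * g // w).astype(int)
        sm = np.zeros((g, g, 3))
        s2 = np.zeros((g, g, 3))
        ct = np.zeros((g, g, 1))
        np.add.at(sm, (ys[:, None], xs[None, :]), tile)
        np.add.at(s2, (ys[:, None], xs[None, :]), tile**2)
        np.add.at(ct, (ys[:, None], xs[None, :]), 1.0)
        mu = sm / np.maximum(ct, 1.0)
        var = np.maximum(s2 / np.maximum(ct, 1.0) - mu**2, 0.0)
        return np.concatenate([mu.ravel(), np.sqrt(var).ravel()])

    def embed(self, tile_rgb: np.ndarray) -> np.ndarray:
        tile = _check_tile(tile_rgb)
        return self._W @ self._stats(tile)

    def embed_batch(self, tiles: list[np.ndarray]) -> np.ndarray:
        if not tiles:
            return np.zeros((0, self.dim))
        return np.stack([self.embed(t) for t in tiles])


class ExternalEmbedder:
    """Adapter for an externally loaded frozen backbone.

    ``fn`` must map an (H, W, 3) float RGB tile to a 1-D feature vector.
    """

    deterministic = True

    def __init__(self, fn=None, dim: int = 384, name: str = "external"):
        if fn is None:
            raise RuntimeError(
                "no external backbone adapter supplied; pass a callable, or use "
                "the 'meancolor' or 'randproj' provider instead"
            )
        self._fn = fn
        self.dim = dim
        self.name = name

    def embed(self, tile_rgb: np.ndarray) -> np.ndarray:
        out = np.asarray(self._fn(_check_tile(tile_rgb)), dtype=float).ravel()
        if out.shape[0] != self.dim:
            raise ValueError(f"adapter returned dim {out.shape[0]}, expected {self.dim}")
        return out

    def embed_batch(self, tiles: list[np.ndarray]) -> np.ndarray:
        if not tiles:
            return np.zeros((0, self.dim))
        return np.stack([self.embed(t) for t in tiles])


def get_embedder(name: str, seed: int = 0, dim: int = 384, fn=None):
    if name == "meancolor":
        return MeanColorEmbedder()
    if name == "randproj":
        return RandomFeatureEmbedder(dim=dim, seed=seed)
    if name == "external":
        return ExternalEmbedder(fn=fn, dim=dim)
    raise ValueError(f"unknown embedding provider {name!r}")


# ---------------------------------------------------------------------------
# Augmentation


@dataclass
class AugmentationPolicy:
    """Probabilities and ranges for training-time tile augmentation."""

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_rot90: float = 0.5
    p_hed: float = 0.25
    hed_jitter: float = 0.05
    p_color: float = 0.25
    brightness_jitter: float = 0.1
    contrast_jitter: float = 0.1
    saturation_jitter: float = 0.1
    p_blur: float = 0.25
    blur_sigma_max: float = 1.0
    p_jpeg: float = 0.25
    jpeg_quality_range: tuple[int, int] = (60, 100)

    @classmethod
    def off(cls) -> "AugmentationPolicy":
        return cls(
            p_hflip=0, p_vflip=0, p_rot90=0, p_hed=0, p_color=0, p_blur=0, p_jpeg=0
        )


def _jpeg_roundtrip(tile: np.ndarray, quality: int) -> np.ndarray:
    from PIL import Image

    img = Image.fromarray((np.clip(tile, 0, 1) * 255).astype(np.uint8))
    buf = _io.BytesIO()
    img.save(buf, format="JPEG", quality=int(quality))
    buf.seek(0)
    back = np.asarray(Image.open(buf), dtype=float) / 255.0
    return back


def augment(
    tile_rgb: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply one random draw of the augmentation policy to a tile.

    Output has the input's shape with values clipped to [0, 1]; the tile's
    regression target is untouched by construction.
    """
    tile = _check_tile(tile_rgb).copy()
    if rng.uniform() < policy.p_hflip:
        tile = tile[:, ::-1]
    if rng.uniform() < policy.p_vflip:
        tile = tile[::-1, :]
    if rng.uniform() < policy.p_rot90:
        tile = np.rot90(tile, k=int(rng.integers(1, 4)))
    if rng.uniform() < policy.p_hed:
        hed = rgb2hed(np.clip(tile, 0, 1))
        jit = rng.uniform(-policy.hed_jitter, policy.hed_jitter, size=3)
        tile = hed2rgb(hed * (1.0 + jit[None, None, :]))
    if rng.uniform() < policy.p_color:
        b = rng.uniform(-policy.brightness_jitter, policy.brightness_jitter)
        c = 1.0 + rng.uniform(-policy.contrast_jitter, policy.contrast_jitter)
        s = 1.0 + rng.uniform(-policy.saturation_jitter, policy.saturation_jitter)
        mean = tile.mean()
        tile = (tile - mean) * c + mean + b
        gray = tile.mean(axis=2, keepdims=True)
        tile = gray + (tile - gray) * s
    if rng.uniform() < policy.p_blur:
        sigma = rng.uniform(0.0, policy.blur_sigma_max)
        if sigma > 1e-3:
            tile = ndimage.gaussian_filter(tile, sigma=(sigma, sigma, 0))
    if rng.uniform() < policy.p_jpeg:
        lo, hi = policy.jpeg_quality_range
        tile = _jpeg_roundtrip(tile, int(rng.integers(lo, hi + 1)))
    return np.ascontiguousarray(np.clip(tile, 0.0, 1.0))
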