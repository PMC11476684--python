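"""Serial-section registration: affine recovery, local refinement, cell mapping."""

import numpy as np
import pytest

from hemux.io import CellTable, rgb_to_luminance
from hemux.panel import MarkerPanel
from hemux.registration import (
    AffineTransform,
    DegenerateImageError,
    LocalDisplacementField,
    RegistrationConfig,
    estimate_global_affine,
    load_transform,
    map_cells,
    mean_tile_ncc,
    refine_local,
    save_transform,
    warp_reference,
)
from hemux.tiling import TileGrid


def _textured_image(n=512, seed=0):
    """Tissue-like test image: smooth structure plus fine cellular texture."""
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    coarse = ndimage.gaussian_filter(rng.normal(size=(n, n)), 6.0)
    fine = ndimage.gaussian_filter(rng.normal(size=(n, n)), 1.5)
    img = coarse / coarse.std() + 0.7 * fine / fine.std()
    return (img - img.min()) / (img.max() - img.min())


class TestAffineTransform:
    def test_identity_and_inverse(self):
        t = AffineTransform.from_params(30.0, 1.2, (5.0, -3.0), center=(10, 10))
        comp = t.compose(t.inverse())
        np.testing.assert_allclose(comp.matrix, AffineTransform.identity().matrix, atol=1e-10)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0]]))

    def test_apply_matches_matrix_multiply(self, rng):
        t = AffineTransform.from_params(17.0, 0.9, (3.0, 4.0))
        pts = rng.uniform(-50, 50, (100, 2))
        x, y = t.apply(pts[:, 0], pts[:, 1])
        hom = np.column_stack([pts, np.ones(100)])
        expected = hom @ t.matrix.T
        np.testing.assert_allclose(np.column_stack([x, y]), expected, atol=1e-12)


class TestGlobalAffine:
    def test_self_registration_is_near_identity(self):
        img = _textured_image(512)
        aff = estimate_global_affine(img, img, RegistrationConfig())
        L = aff.matrix[:, :2]
        angle = np.degrees(np.arctan2(L[1, 0], L[0, 0]))
        assert abs(angle) < 0.2
        # displacement of the center stays sub-pixel-ish
        cx, cy = aff.apply(256.0, 256.0)
        assert np.hypot(cx - 256, cy - 256) < 0.5

    def test_known_similarity_recovered_on_1024_image(self, rng):
        from scipy import ndimage as ndi

        n = 1024
        img = _textured_image(n, seed=3)
        true = AffineTransform.from_params(
            5.0, 1.05, (10.0, -20.0), center=((n - 1) / 2, (n - 1) / 2)
        )
        # moving image: sample img at true^{-1}(q) so that moving = img warped
        inv = true.inverse()
        yy, xx = np.mgrid[0:n, 0:n]
        px, py = inv.apply(xx.astype(float), yy.astype(float))
        moving = ndi.map_coordinates(img, [py.ravel(), px.ravel()], order=1).reshape(n, n)
        est = estimate_global_affine(img, moving, RegistrationConfig())
        # moving(q) = img(inv(q)): moving position q matches fixed p = inv(q),
        # so the estimated moving->fixed map applied at q = true(p) must
        # return p for fixed-frame landmarks p
        grid = np.linspace(100, n - 100, 10)
        gx, gy = np.meshgrid(grid, grid)
        qx, qy = true.apply(gx.ravel(), gy.ravel())
        bx, by = est.apply(qx, qy)
        resid = np.hypot(bx - gx.ravel(), by - gy.ravel())
        assert resid.mean() < 2.0

    def test_blank_reference_is_degenerate(self):
        img = _textured_image(128)
        with pytest.raises(DegenerateImageError):
            estimate_global_affine(img, np.zeros((128, 128)))

    def test_blank_he_is_degenerate(self):
        img = _textured_image(128)
        with pytest.raises(DegenerateImageError):
            estimate_global_affine(np.full((128, 128), 0.5), img)


class TestLocalRefinement:
    def test_exact_alignment_gives_near_zero_field(self):
        img = _textured_image(256, seed=1)
        grid = TileGrid(64, 4, 4)
        field = refine_local(img, img, AffineTransform.identity(), grid)
        assert np.abs(field.dx).max() < 0.5
        assert np.abs(field.dy).max() < 0.5

    def test_sinusoidal_warp_recovered_within_1px_rms(self):
        from scipy import ndimage as ndi

        n = 512
        s = 64
        img = _textured_image(n, seed=2)
        yy, xx = np.mgrid[0:n, 0:n]
        # content at H&E position p appears in the reference at p shifted:
        # ref(q) = img(q - d(q)) approximately, with smooth d
        amp, period = 3.0, 8 * s
        dx = amp * np.sin(2 * np.pi * yy / period)
        dy = amp * np.cos(2 * np.pi * xx / period)
        ref = ndi.map_coordinates(
            img, [(yy - dy).ravel(), (xx - dx).ravel()], order=1
        ).reshape(n, n)
        grid = TileGrid(s, n // s, n // s)
        field = refine_local(img, ref, AffineTransform.identity(), grid)
        cx, cy = grid.centers()
        # the correction field undoes the planted displacement: d_hat = -d
        true_dx = amp * np.sin(2 * np.pi * cy / period)
        true_dy = amp * np.cos(2 * np.pi * cx / period)
        rms = np.sqrt(np.mean((field.dx + true_dx) ** 2 + (field.dy + true_dy) ** 2))
        assert rms < 1.0

    def test_blank_tiles_inherit_neighbor_displacement(self):
        n, s = 256, 64
        img = np.zeros((n, n))
        rngl = np.random.default_rng(7)
        # informative texture only in tile (1, 1)
        img[64:128, 64:128] = rngl.uniform(0, 1, (64, 64))
        ref = np.roll(img, shift=(4, 6), axis=(0, 1))  # ref displaced by (6,4)
        grid = TileGrid(s, 4, 4)
        cfg = RegistrationConfig(highpass_sigma_px=0.0)
        field = refine_local(img, ref, AffineTransform.identity(), grid, cfg)
        assert field.confidence[1, 1] > 0.5
        # the central estimate propagates to uninformative neighbors
        assert field.dx[0, 0] == pytest.approx(field.dx[1, 1], abs=0.05)
        assert field.dy[3, 3] == pytest.approx(field.dy[1, 1], abs=0.05)
        assert field.dx[1, 1] == pytest.approx(-6.0, abs=1.0)
        assert field.dy[1, 1] == pytest.approx(-4.0, abs=1.0)

    def test_refinement_does_not_degrade_similarity(self, small_pair):
        he, cy, _, truth = small_pair
        he_inv = 1.0 - rgb_to_luminance(he)
        grid = TileGrid(64, 8, 8)
        aff = estimate_global_affine(he_inv, cy, RegistrationConfig())
        field = refine_local(he_inv, cy, aff, grid)
        before = mean_tile_ncc(he_inv, cy, aff, grid)
        after = mean_tile_ncc(he_inv, cy, aff, grid, field)
        assert after >= before - 1e-9


class TestMapCells:
    PANEL = MarkerPanel(("A",))

    def _cells(self, xy):
        xy = np.atleast_2d(xy)
        return CellTable(
            x=xy[:, 0], y=xy[:, 1], expr=np.ones((len(xy), 1)), panel=self.PANEL
        )

    def test_identity_transform_keeps_coordinates(self):
        cells = self._cells([[3.0, 4.0], [5.0, 6.0]])
        out = map_cells(cells, AffineTransform.identity())
        np.testing.assert_array_equal(out.x, cells.x)
        np.testing.assert_array_equal(out.y, cells.y)

    def test_pure_translation_shifts_all_cells(self):
        cells = self._cells([[0.0, 0.0], [1.0, 2.0]])
        t = AffineTransform(np.array([[1.0, 0, 10.0], [0, 1.0, 20.0]]))
        out = map_cells(cells, t)
        np.testing.assert_allclose(out.x, cells.x + 10)
        np.testing.assert_allclose(out.y, cells.y + 20)

    def test_matches_direct_matrix_application(self, rng):
        xy = rng.uniform(0, 1000, (1000, 2))
        cells = self._cells(xy)
        t = AffineTransform.from_params(5.0, 1.05, (10.0, -20.0))
        out = map_cells(cells, t)
        hom = np.column_stack([xy, np.ones(1000)])
        expected = hom @ t.matrix.T
        np.testing.assert_allclose(out.x, expected[:, 0], atol=1e-6)
        np.testing.assert_allclose(out.y, expected[:, 1], atol=1e-6)

    def test_out_of_bounds_cells_flagged_not_dropped(self):
        cells = self._cells([[5.0, 5.0], [150.0, 5.0]])
        out = map_cells(cells, AffineTransform.identity(), bounds=(100, 100))
        assert len(out) == 2
        assert list(out.in_bounds) == [True, False]

    def test_local_field_composes_after_affine(self):
        field = LocalDisplacementField(
            dx=np.full((2, 2), 3.0),
            dy=np.full((2, 2), -1.0),
            confidence=np.ones((2, 2)),
            tile_size_px=10,
        )
        cells = self._cells([[5.0, 5.0]])
        out = map_cells(cells, AffineTransform.identity(), field)
        assert out.x[0] == pytest.approx(8.0)
        assert out.y[0] == pytest.approx(4.0)


class TestPersistence:
    def test_transform_roundtrip(self, tmp_path):
        aff = AffineTransform.from_params(2.0, 1.01, (1.0, 2.0))
        field = LocalDisplacementField(
            dx=np.arange(4.0).reshape(2, 2),
            dy=np.arange(4.0).reshape(2, 2) * 2,
            confidence=np.full((2, 2), 0.5),
            tile_size_px=64,
        )
        save_transform(tmp_path / "reg.json", aff, field)
        aff2, field2 = load_transform(tmp_path / "reg.json")
        np.testing.assert_allclose(aff2.matrix, aff.matrix, atol=1e-12)
        np.testing.assert_allclose(field2.dx, field.dx)
        assert field2.tile_size_px == 64

    def test_warp_reference_identity_is_noop(self):
        img = _textured_image(64)
        out = warp_reference(img, AffineTransform.identity(), img.shape)
        np.testing.assert_allclose(out, img, atol=1e-8)
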