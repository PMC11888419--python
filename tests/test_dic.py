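"""DIC engine: displacement recovery against constructed warps and the
Green-Lagrange strain formula against closed forms."""

import numpy as np
import pytest

from ehtmech import synthetic as syn
from ehtmech.dic import (
    DicParams,
    DisplacementField,
    compute_strain,
    track_displacements,
)
from ehtmech.exceptions import ParameterError

PARAMS = DicParams(search_px=8)


def _axial_u(img_shape, fn):
    cols = np.arange(img_shape[1], dtype=float)
    return np.broadcast_to(fn(cols), img_shape).copy()


def _uniform_field(value_u, value_v, n=9, spacing=5.0):
    """Hand-built displacement field on a regular grid."""
    x = np.arange(n) * spacing + 30
    y = np.arange(n) * spacing + 30
    shape = (n, n)
    return DisplacementField(
        x=x,
        y=y,
        u=np.full(shape, float(value_u)),
        v=np.full(shape, float(value_v)),
        score=np.ones(shape),
        valid=np.ones(shape, bool),
    )


class TestTracking:
    def test_self_match_is_zero(self, small_speckle, small_mask):
        disp = track_displacements(small_speckle, small_speckle, PARAMS, small_mask)
        assert disp.valid.any()
        assert np.nanmax(np.abs(disp.u[disp.valid])) < 1e-3
        assert np.nanmax(np.abs(disp.v[disp.valid])) < 1e-3

    def test_integer_shift_recovered(self, small_speckle, small_mask):
        shifted = np.roll(small_speckle, 7, axis=1)
        disp = track_displacements(small_speckle, shifted, PARAMS, small_mask)
        err = np.abs(disp.u[disp.valid] - 7.0)
        assert np.median(err) < 0.05
        assert np.quantile(err, 0.95) < 0.1

    def test_subpixel_shift_recovered(self, small_speckle, small_mask):
        img = small_speckle.astype(float)
        u = _axial_u(img.shape, lambda c: np.full_like(c, 0.5))
        warped = syn.warp_image(img, u, np.zeros_like(img), warn_oob=False)
        disp = track_displacements(img, warped, PARAMS, small_mask)
        err = np.abs(disp.u[disp.valid] - 0.5)
        assert np.quantile(err, 0.95) < 0.1

    def test_initial_guess_allows_small_search(self, small_speckle, small_mask):
        shifted = np.roll(small_speckle, 12, axis=1)
        params = DicParams(search_px=4)
        blind = track_displacements(small_speckle, shifted, params, small_mask)
        # 12 px exceeds the 4 px search: the blind pass cannot find it
        assert not np.any(np.abs(blind.u[blind.valid] - 12.0) < 0.5)
        init = (np.full(blind.u.shape, 11.0), np.zeros(blind.v.shape))
        guided = track_displacements(
            small_speckle, shifted, params, small_mask, init=init
        )
        err = np.abs(guided.u[guided.valid] - 12.0)
        assert np.quantile(err, 0.95) < 0.1

    def test_featureless_region_marked_invalid(self):
        flat = np.zeros((120, 120))
        flat[30:90, 30:90] = 100.0  # featureless interior, edges have texture
        disp = track_displacements(flat, flat, DicParams(search_px=5))
        # subsets fully inside the uniform block have zero variance
        center = (np.abs(disp.x - 60) <= 5)[None, :] & (
            np.abs(disp.y - 60) <= 5
        )[:, None]
        assert not disp.valid[center].any()

    def test_shape_mismatch_raises(self, small_speckle):
        with pytest.raises(ParameterError):
            track_displacements(small_speckle, small_speckle[:-1], PARAMS)

    def test_noise_robust_translation(self, small_spec, small_mask):
        """Translation recovery stays below 0.2 px at 2% image noise."""
        img = syn.generate_speckle(small_spec).astype(float)
        u = _axial_u(img.shape, lambda c: np.full_like(c, 3.0))
        warped = syn.warp_image(img, u, np.zeros_like(img), warn_oob=False)
        for trial in range(10):
            rng = np.random.default_rng(100 + trial)
            a = syn.add_image_noise(img, 0.02, rng)
            b = syn.add_image_noise(warped, 0.02, rng)
            disp = track_displacements(a, b, PARAMS, small_mask)
            assert np.median(np.abs(disp.u[disp.valid] - 3.0)) < 0.2


class TestStrain:
    def test_rigid_translation_zero_strain(self):
        field = _uniform_field(4.2, -1.3)
        strain = compute_strain(field)
        assert np.nanmax(np.abs(strain.Exx[strain.valid])) < 1e-3

    def test_linear_gradient_closed_form(self):
        # u = 0.1 x  ->  Exx = 0.1 + 0.5 * 0.1^2 = 0.105
        field = _uniform_field(0.0, 0.0)
        X = np.broadcast_to(field.x, field.u.shape)
        field.u[:] = 0.1 * X
        strain = compute_strain(field)
        assert np.allclose(strain.Exx[strain.valid], 0.105, atol=1e-9)

    def test_small_rotation_yields_negligible_strain(self):
        # rigid rotation by 1 degree applied analytically to the grid
        theta = np.deg2rad(1.0)
        field = _uniform_field(0.0, 0.0, n=11)
        X, Y = np.meshgrid(field.x.astype(float), field.y.astype(float))
        xc, yc = X.mean(), Y.mean()
        field.u[:] = (np.cos(theta) - 1) * (X - xc) - np.sin(theta) * (Y - yc)
        field.v[:] = np.sin(theta) * (X - xc) + (np.cos(theta) - 1) * (Y - yc)
        strain = compute_strain(field)
        assert np.nanmax(np.abs(strain.Exx[strain.valid])) < 5e-4

    def test_affine_warp_matches_green_lagrange(self, small_spec, small_mask):
        """Image-based oracle: for x-stretch 1.03 with shear dv/dx = 0.01,
        Exx must equal ((F^T F - I) / 2)_xx within 5%."""
        img = syn.generate_speckle(small_spec).astype(float)
        x0 = small_spec.margin_px
        cols = np.arange(img.shape[1], dtype=float)
        u = np.broadcast_to(np.maximum(0.03 * (cols - x0), 0.0), img.shape).copy()
        v = 0.01 * np.maximum(
            np.broadcast_to(cols - x0, img.shape), 0.0
        )
        warped = syn.warp_image(img, u, v, warn_oob=False)
        disp = track_displacements(img, warped, PARAMS, small_mask)
        strain = compute_strain(disp)
        # restrict to interior (away from the fixed edge kink at x0)
        interior = (strain.x > x0 + 25)[None, :] & strain.valid
        expected = 0.03 + 0.5 * (0.03**2 + 0.01**2)
        assert np.median(strain.Exx[interior]) == pytest.approx(expected, rel=0.05)

    def test_frame_order_antisymmetry_small_strain(self, small_spec, small_mask):
        img = syn.generate_speckle(small_spec).astype(float)
        x0 = small_spec.margin_px
        cols = np.arange(img.shape[1], dtype=float)
        u = np.broadcast_to(np.maximum(0.01 * (cols - x0), 0.0), img.shape).copy()
        warped = syn.warp_image(img, u, np.zeros_like(img), warn_oob=False)
        fwd = compute_strain(track_displacements(img, warped, PARAMS, small_mask))
        bwd = compute_strain(track_displacements(warped, img, PARAMS, small_mask))
        both = fwd.valid & bwd.valid
        assert both.any()
        resid = np.abs(fwd.Exx[both] + bwd.Exx[both])
        assert np.median(resid) < 1e-3

    def test_invalid_params_raise(self):
        with pytest.raises(ParameterError):
            DicParams(subset_px=2)
        with pytest.raises(ParameterError):
            DicParams(correlation_min=0.0)
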