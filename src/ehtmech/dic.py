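"""Subset-based 2D digital image correlation (DIC).

Tracks a regular grid of square subsets from a reference frame into a
deformed frame and differentiates the resulting displacement field into
Green-Lagrange strains.  The matching strategy is the classical one:

1. integer-pixel search by zero-normalized cross-correlation (ZNCC)
   over a square search window,
2. quadratic interpolation of the correlation peak for a subpixel
   initial guess,
3. Gauss-Newton refinement of the subset translation against the
   cubic-spline-interpolated deformed frame (zero-mean residuals, so a
   constant intensity offset between frames is absorbed).

Strain is obtained per grid node by a least-squares plane fit of u and
v over a local window of valid neighbours, which suppresses
displacement noise compared with pointwise finite differences.  The
axial Green-Lagrange component is

    Exx = du/dx + 1/2 [(du/dx)^2 + (dv/dx)^2]

and analogously for Eyy and Exy, so rigid rotations produce (to
numerical precision) zero strain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import map_coordinates, spline_filter
from skimage.feature import match_template

from .exceptions import ParameterError

_EPS = 1e-12


@dataclass(frozen=True)
class DicParams:
    """Correlation parameters.

    ``subset_px`` and ``search_px`` are half-widths: subsets span
    ``2*subset_px + 1`` pixels and the integer search covers
    displacements up to ``search_px`` in each direction.
    ``strain_window_px`` is the half-width (px) of the window used for
    the local plane fit.  Points whose final ZNCC score falls below
    ``correlation_min`` are marked invalid.
    """

    subset_px: int = 15
    spacing_px: int = 5
    search_px: int = 15
    strain_window_px: int = 15
    correlation_min: float = 0.5
    refine_iters: int = 6

    def __post_init__(self) -> None:
        if self.subset_px < 3:
            raise ParameterError("subset_px must be >= 3")
        if self.spacing_px < 1:
            raise ParameterError("spacing_px must be >= 1")
        if self.search_px < 1:
            raise ParameterError("search_px must be >= 1")
        if not (0.0 < self.correlation_min <= 1.0):
            raise ParameterError("correlation_min must lie in (0, 1]")


@dataclass
class DisplacementField:
    """Gridded displacements between two frames.

    ``x`` and ``y`` are 1-D grid coordinates (px); ``u``/``v``/``score``
    are (len(y), len(x)) arrays.  Invalid points carry NaN displacements.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    score: np.ndarray
    valid: np.ndarray

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else 1.0

    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if self.valid.size else 0.0


@dataclass
class StrainField:
    """Green-Lagrange strain components on the displacement grid."""

    x: np.ndarray
    y: np.ndarray
    Exx: np.ndarray
    Eyy: np.ndarray
    Exy: np.ndarray
    valid: np.ndarray


def _zncc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """ZNCC between matching (..., S, S) stacks along the last two axes."""
    a0 = a - a.mean(axis=(-2, -1), keepdims=True)
    b0 = b - b.mean(axis=(-2, -1), keepdims=True)
    num = (a0 * b0).sum(axis=(-2, -1))
    den = np.sqrt(
        (a0**2).sum(axis=(-2, -1)) * (b0**2).sum(axis=(-2, -1))
    )
    return num / np.maximum(den, _EPS)


def track_displacements(
    ref_frame: np.ndarray,
    def_frame: np.ndarray,
    params: Optional[DicParams] = None,
    mask: Optional[np.ndarray] = None,
    init: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> DisplacementField:
    """Track the grid of subsets from ``ref_frame`` into ``def_frame``.

    Grid points are laid out every ``spacing_px`` pixels wherever the
    subset plus search window fits inside the frame and, if ``mask`` is
    given, the point centre lies on masked (tissue) pixels.  Featureless
    subsets (zero variance) are marked invalid rather than raising.

    ``init`` optionally supplies per-grid-point initial displacement
    guesses (u0, v0) on the same grid (e.g. the previous ramp step's
    field); the integer search is then centred on the rounded guess, so
    a small ``search_px`` suffices even for large accumulated motion.
    """
    params = params or DicParams()
    ref = np.asarray(ref_frame, float)
    dfm = np.asarray(def_frame, float)
    if ref.shape != dfm.shape:
        raise ParameterError("frames must have the same shape")
    if mask is not None and mask.shape != ref.shape:
        raise ParameterError("mask must match the frame shape")
    hh, ww = ref.shape
    s, r, sp = params.subset_px, params.search_px, params.spacing_px
    m = s + r
    xs = np.arange(m, ww - m, sp)
    ys = np.arange(m, hh - m, sp)
    if xs.size == 0 or ys.size == 0:
        raise ParameterError("frame too small for the requested subset/search size")
    ny, nx = ys.size, xs.size
    u = np.full((ny, nx), np.nan)
    v = np.full((ny, nx), np.nan)
    score = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), bool)

    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    keep = mask[gy, gx] if mask is not None else np.ones((ny, nx), bool)
    if init is not None:
        iu0 = np.nan_to_num(np.asarray(init[0], float))
        iv0 = np.nan_to_num(np.asarray(init[1], float))
        if iu0.shape != keep.shape or iv0.shape != keep.shape:
            raise ParameterError("init fields must match the DIC grid shape")
    else:
        iu0 = np.zeros(keep.shape)
        iv0 = np.zeros(keep.shape)

    # --- stage 1: integer ZNCC search + quadratic subpixel initialisation
    pts = np.argwhere(keep)
    init_pts = []
    for i, j in pts:
        x, y = int(gx[i, j]), int(gy[i, j])
        tpl = ref[y - s : y + s + 1, x - s : x + s + 1]
        if tpl.std() < 1e-9:
            continue  # featureless subset: leave invalid
        cu, cv = int(round(iu0[i, j])), int(round(iv0[i, j]))
        yw, xw = y + cv, x + cu
        if not (m <= yw < hh - m and m <= xw < ww - m):
            continue  # guess pushes the search window outside the frame
        win = dfm[yw - m : yw + m + 1, xw - m : xw + m + 1]
        corr = match_template(win, tpl)  # (2r+1, 2r+1) ZNCC surface
        pi, pj = np.unravel_index(np.argmax(corr), corr.shape)
        du, dv = float(cu + pj - r), float(cv + pi - r)
        # quadratic interpolation of the peak (used as refinement seed)
        if 0 < pi < corr.shape[0] - 1 and 0 < pj < corr.shape[1] - 1:
            cx = corr[pi, pj - 1 : pj + 2]
            denom = cx[0] - 2 * cx[1] + cx[2]
            if abs(denom) > _EPS:
                du += 0.5 * (cx[0] - cx[2]) / denom
            cy = corr[pi - 1 : pi + 2, pj]
            denom = cy[0] - 2 * cy[1] + cy[2]
            if abs(denom) > _EPS:
                dv += 0.5 * (cy[0] - cy[2]) / denom
        u[i, j], v[i, j] = du, dv
        score[i, j] = corr[pi, pj]
        init_pts.append((i, j))

    if not init_pts:
        return DisplacementField(x=xs, y=ys, u=u, v=v, score=score, valid=valid)

    # --- stage 2: batched Gauss-Newton subpixel refinement
    idx = np.array(init_pts)
    ii, jj = idx[:, 0], idx[:, 1]
    px = gx[ii, jj].astype(float)
    py = gy[ii, jj].astype(float)
    uk = u[ii, jj].copy()
    vk = v[ii, jj].copy()
    offs = np.arange(-s, s + 1)
    sub_y = (py[:, None, None] + offs[None, :, None]).astype(int)
    sub_x = (px[:, None, None] + offs[None, None, :]).astype(int)
    tpl_all = ref[sub_y, sub_x]  # (K, S, S)
    gy_img, gx_img = np.gradient(ref)
    tx = gx_img[sub_y, sub_x]
    ty = gy_img[sub_y, sub_x]
    tpl0 = tpl_all - tpl_all.mean(axis=(1, 2), keepdims=True)
    h00 = (tx * tx).sum(axis=(1, 2))
    h01 = (tx * ty).sum(axis=(1, 2))
    h11 = (ty * ty).sum(axis=(1, 2))
    det = np.maximum(h00 * h11 - h01**2, _EPS)

    dfm_spl = spline_filter(dfm, order=3, mode="mirror")
    limit = r + 2.0
    u0, v0 = uk.copy(), vk.copy()
    for _ in range(params.refine_iters):
        yy, xx = np.broadcast_arrays(
            py[:, None, None] + offs[None, :, None] + vk[:, None, None],
            px[:, None, None] + offs[None, None, :] + uk[:, None, None],
        )
        g = map_coordinates(
            dfm_spl, [yy.ravel(), xx.ravel()], order=3, prefilter=False, mode="mirror"
        ).reshape(tpl_all.shape)
        e = (g - g.mean(axis=(1, 2), keepdims=True)) - tpl0
        bx = (tx * e).sum(axis=(1, 2))
        by = (ty * e).sum(axis=(1, 2))
        du = (h11 * bx - h01 * by) / det
        dv = (h00 * by - h01 * bx) / det
        uk -= du
        vk -= dv
        np.clip(uk, u0 - limit, u0 + limit, out=uk)
        np.clip(vk, v0 - limit, v0 + limit, out=vk)

    yy, xx = np.broadcast_arrays(
        py[:, None, None] + offs[None, :, None] + vk[:, None, None],
        px[:, None, None] + offs[None, None, :] + uk[:, None, None],
    )
    g = map_coordinates(
        dfm_spl, [yy.ravel(), xx.ravel()], order=3, prefilter=False, mode="mirror"
    ).reshape(tpl_all.shape)
    final_score = _zncc(g, tpl_all)

    u[ii, jj] = uk
    v[ii, jj] = vk
    score[ii, jj] = final_score
    ok = np.isfinite(uk) & (final_score >= params.correlation_min)
    valid[ii[ok], jj[ok]] = True
    u[ii[~ok], jj[~ok]] = np.nan
    v[ii[~ok], jj[~ok]] = np.nan
    return DisplacementField(x=xs, y=ys, u=u, v=v, score=score, valid=valid)


def compute_strain(
    displacements: DisplacementField, params: Optional[DicParams] = None
) -> StrainField:
    """Green-Lagrange strains from a displacement field.

    Displacement gradients at each valid grid node come from a
    least-squares plane fit of u and v over the valid neighbours within
    ``strain_window_px`` (Chebyshev distance in px).  Nodes with fewer
    than three valid neighbours, or with neighbours that do not span
    both axes (rank-deficient fit), are marked invalid.
    """
    params = params or DicParams()
    fld = displacements
    ny, nx = fld.u.shape
    step = fld.spacing
    hw = max(1, int(round(params.strain_window_px / step)))
    Exx = np.full((ny, nx), np.nan)
    Eyy = np.full((ny, nx), np.nan)
    Exy = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), bool)
    X, Y = np.meshgrid(fld.x.astype(float), fld.y.astype(float))
    for i in range(ny):
        i0, i1 = max(0, i - hw), min(ny, i + hw + 1)
        for j in range(nx):
            if not fld.valid[i, j]:
                continue
            j0, j1 = max(0, j - hw), min(nx, j + hw + 1)
            sel = fld.valid[i0:i1, j0:j1]
            if sel.sum() < 3:
                continue
            dx = (X[i0:i1, j0:j1] - X[i, j])[sel]
            dy = (Y[i0:i1, j0:j1] - Y[i, j])[sel]
            A = np.column_stack([np.ones_like(dx), dx, dy])
            rhs = np.column_stack([fld.u[i0:i1, j0:j1][sel], fld.v[i0:i1, j0:j1][sel]])
            coef, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
            if rank < 3:
                continue
            dudx, dvdx = coef[1, 0], coef[1, 1]
            dudy, dvdy = coef[2, 0], coef[2, 1]
            Exx[i, j] = dudx + 0.5 * (dudx**2 + dvdx**2)
            Eyy[i, j] = dvdy + 0.5 * (dudy**2 + dvdy**2)
            Exy[i, j] = 0.5 * (dudy + dvdx) + 0.5 * (dudx * dudy + dvdx * dvdy)
            valid[i, j] = True
    return StrainField(x=fld.x, y=fld.y, Exx=Exx, Eyy=Eyy, Exy=Exy, valid=valid)


def fields_to_frame(disp: DisplacementField, strain: Optional[StrainField] = None):
    """Tidy per-point table (x_px, y_px, u, v, [Exx, Eyy, Exy,] score, valid)."""
    import pandas as pd

    X, Y = np.meshgrid(disp.x, disp.y)
    data = {
        "x_px": X.ravel(),
        "y_px": Y.ravel(),
        "u": disp.u.ravel(),
        "v": disp.v.ravel(),
        "score": disp.score.ravel(),
        "valid": disp.valid.ravel(),
    }
    if strain is not None:
        data["Exx"] = strain.Exx.ravel()
        data["Eyy"] = strain.Eyy.ravel()
        data["Exy"] = strain.Exy.ravel()
        data["strain_valid"] = strain.valid.ravel()
    return pd.DataFrame(data)
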