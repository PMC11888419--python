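"""Seeded synthetic inputs emulating the cryowounded-EHT recordings.

Everything the downstream analysis consumes can be generated here:
speckle-textured grayscale frames of a rectangular tissue, beat
sequences (diastole -> systole), stepped force-ramp sequences whose
per-zone strain equals stress divided by a prescribed zone modulus, and
multichannel fluorescence maps with prescribed zonal density
reductions.  All generators are pure functions of their specification
(including its seed).

Geometric conventions
---------------------
The long axis is x (image columns), the transverse axis y (rows); the
fixed, non-piston end is at x = 0 and displacement is zero there.  The
tissue is a rectangle of ``length_mm`` x ``width_mm`` placed with a
background margin on all sides; background pixels are zero.

Mechanical zones
----------------
The wound midline sits at ``wound_center_mm``.  The mechanical border
zone of width ``border_width_mm`` is centred on each wound *edge* (the
injury margin), so with the standard 1 mm wound and 0.5 mm border the
zone boundaries fall at the midpoints of the gaps between analysis
subregions and every 0.3 mm subregion samples a single strain plateau.
When a border value is prescribed the strain profile has three plateaus
joined by short linear transitions; when it is not (beat mode without a
border entry), strain ramps linearly across the border zone from the
wound value to the remote value.

Fluorescence zones use the contiguous-extent convention instead (wound
= full wound width, border = bands just outside it), matching how the
region partition integrates intensity traces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import map_coordinates

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

ZONES = ("wound", "border", "remote")
CHANNELS = ("nuclei", "fibroblast", "cardiomyocyte")


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class SyntheticTissueSpec:
    """Geometry, texture and imaging parameters of one synthetic tissue.

    Lengths in mm, image scale in px/mm.  ``noise_sd`` is the additive
    Gaussian image noise as a fraction of the 8-bit dynamic range and is
    applied independently to every emitted frame.
    """

    length_mm: float = 4.0
    width_mm: float = 4.0
    wound_center_mm: float = 2.0
    wound_width_mm: float = 1.0
    border_width_mm: float = 0.5
    px_per_mm: float = 50.0
    speckle_density: float = 0.3
    speckle_sigma_px: float = 2.0
    noise_sd: float = 0.0
    margin_px: int = 20
    base_intensity: int = 64
    speckle_amplitude: int = 160
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ParameterError("px_per_mm must be positive")
        if not (0.0 <= self.speckle_density <= 1.0):
            raise ParameterError("speckle_density must lie in [0, 1]")
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ParameterError("tissue dimensions must be positive")
        if self.wound_width_mm + 2 * self.border_width_mm >= self.length_mm:
            raise ParameterError(
                "wound plus border zones must fit inside the tissue length"
            )
        if not (0.0 < self.wound_center_mm < self.length_mm):
            raise ParameterError("wound center must lie inside the tissue")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")

    # image layout -----------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int]:
        h = int(round(self.width_mm * self.px_per_mm)) + 2 * self.margin_px
        w = int(round(self.length_mm * self.px_per_mm)) + 2 * self.margin_px
        return h, w

    @property
    def tissue_origin_px(self) -> Tuple[int, int]:
        """(row, col) of the tissue's upper-left corner."""
        return self.margin_px, self.margin_px

    @property
    def tissue_shape_px(self) -> Tuple[int, int]:
        return (
            int(round(self.width_mm * self.px_per_mm)),
            int(round(self.length_mm * self.px_per_mm)),
        )

    def x_mm(self, col: np.ndarray) -> np.ndarray:
        """Long-axis position (mm) of image column(s)."""
        return (np.asarray(col, float) - self.margin_px) / self.px_per_mm


@dataclass(frozen=True)
class ZoneMechanicsSpec:
    """Per-zone mechanical and compositional ground truth.

    ``modulus_by_zone`` (kPa) drives ramp generation via
    strain = stress / modulus.  ``systolic_strain_by_zone`` prescribes
    peak axial beat strain per zone (negative = contraction); a missing
    ``border`` entry means the border strain ramps linearly between the
    wound and remote values.  ``density_reduction_by_zone_channel`` maps
    channel -> zone -> fractional fluorescence reduction in [0, 1].
    """

    modulus_by_zone: Optional[Mapping[str, float]] = None
    systolic_strain_by_zone: Optional[Mapping[str, float]] = None
    density_reduction_by_zone_channel: Optional[Mapping[str, Mapping[str, float]]] = None

    def __post_init__(self) -> None:
        if self.modulus_by_zone is not None:
            for z, e in self.modulus_by_zone.items():
                if e <= 0:
                    raise ParameterError(f"modulus for zone {z!r} must be > 0")
        if self.density_reduction_by_zone_channel is not None:
            for ch, per_zone in self.density_reduction_by_zone_channel.items():
                for z, r in per_zone.items():
                    if not (0.0 <= r <= 1.0):
                        raise ParameterError(
                            f"density reduction {ch}/{z} must lie in [0, 1]"
                        )


@dataclass(frozen=True)
class ForceProtocol:
    """Stepped electromagnet protocol: amperage per hold level."""

    amperages: Tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(9))
    step_duration_s: float = 5.0
    magnet_distance_mm: float = 3.0

    def __post_init__(self) -> None:
        amps = np.asarray(self.amperages, float)
        if amps.size == 0:
            raise ParameterError("protocol needs at least one amperage level")
        if np.any(np.diff(amps) < 0):
            raise ParameterError("amperages must be non-decreasing")
        if self.step_duration_s <= 0:
            raise ParameterError("step_duration_s must be positive")


# ---------------------------------------------------------------------------
# speckle texture


def tissue_mask(spec: SyntheticTissueSpec) -> np.ndarray:
    """Boolean mask of tissue pixels in the undeformed reference frame."""
    h, w = spec.shape
    r0, c0 = spec.tissue_origin_px
    th, tw = spec.tissue_shape_px
    m = np.zeros((h, w), bool)
    m[r0 : r0 + th, c0 : c0 + tw] = True
    return m


def speckle_threshold(spec: SyntheticTissueSpec) -> float:
    """Intensity above which a pixel counts as speckle-covered."""
    return spec.base_intensity + spec.speckle_amplitude / 2.0


def generate_speckle(spec: SyntheticTissueSpec) -> np.ndarray:
    """Render the noiseless speckle-textured reference frame (uint8).

    Speckles are Gaussian blobs combined by maximum, so coverage follows
    a Boolean disc model: the number of blobs is chosen so the expected
    fraction of tissue pixels brighter than ``speckle_threshold`` equals
    ``speckle_density``.  Blob centres are sampled in a rectangle padded
    by three blob sigmas so coverage is unbiased up to the tissue edge;
    background outside the tissue stays zero.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    th, tw = spec.tissue_shape_px
    r0, c0 = spec.tissue_origin_px
    sigma = spec.speckle_sigma_px

    field_ = np.zeros((th, tw), float)
    d = spec.speckle_density
    if d > 0 and sigma > 0:
        r_half = sigma * math.sqrt(2.0 * math.log(2.0))
        blob_area = math.pi * r_half**2
        pad = 3.0 * sigma
        area = (th + 2 * pad) * (tw + 2 * pad)
        if d >= 0.999:
            field_[:] = 1.0
        else:
            n_blobs = int(round(area * (-math.log1p(-d)) / blob_area))
            cy = rng.uniform(-pad, th + pad, n_blobs)
            cx = rng.uniform(-pad, tw + pad, n_blobs)
            half = int(math.ceil(3.0 * sigma))
            offs = np.arange(-half, half + 1)
            for y, x in zip(cy, cx):
                iy, ix = int(round(y)), int(round(x))
                ys = iy + offs
                xs = ix + offs
                sel_y = (ys >= 0) & (ys < th)
                sel_x = (xs >= 0) & (xs < tw)
                if not (sel_y.any() and sel_x.any()):
                    continue
                gy = np.exp(-((ys[sel_y] - y) ** 2) / (2 * sigma**2))
                gx = np.exp(-((xs[sel_x] - x) ** 2) / (2 * sigma**2))
                patch = gy[:, None] * gx[None, :]
                win = np.ix_(ys[sel_y], xs[sel_x])
                field_[win] = np.maximum(field_[win], patch)

    img = np.zeros((h, w), float)
    img[r0 : r0 + th, c0 : c0 + tw] = (
        spec.base_intensity + spec.speckle_amplitude * field_
    )
    return np.clip(img, 0, 255).astype(np.uint8)


def add_image_noise(
    frame: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive Gaussian noise (sd as fraction of the 8-bit range)."""
    if noise_sd <= 0:
        return np.asarray(frame, np.uint8).copy()
    noisy = np.asarray(frame, float) + rng.normal(0.0, noise_sd * 255.0, frame.shape)
    return np.clip(noisy, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# strain profiles and displacement


def zone_strain_profile(
    spec: SyntheticTissueSpec,
    zone_values: Mapping[str, float],
    x_mm: np.ndarray,
    transition_mm: float = 0.05,
) -> np.ndarray:
    """Axial strain at positions ``x_mm`` for prescribed per-zone values.

    The border zone straddles the wound edge (injury margin).  With an
    explicit border value the profile has three plateaus joined by
    linear transitions of total width ``transition_mm``; without one the
    strain ramps linearly across the whole border zone.
    """
    x = np.asarray(x_mm, float)
    d = np.abs(x - spec.wound_center_mm)
    wv = float(zone_values.get("wound", 0.0))
    rv = float(zone_values.get("remote", 0.0))
    hw = spec.wound_width_mm / 2.0
    bw = spec.border_width_mm
    b_in = hw - bw / 2.0
    b_out = hw + bw / 2.0
    if b_in <= 0:
        raise ParameterError("border zone wider than the wound")
    if "border" in zone_values:
        bv = float(zone_values["border"])
        t = min(transition_mm / 2.0, b_in / 2.0, bw / 2.0)
        xp = [b_in - t, b_in + t, b_out - t, b_out + t]
        fp = [wv, bv, bv, rv]
    else:
        xp = [b_in, b_out]
        fp = [wv, rv]
    return np.interp(d, xp, fp)


def displacement_from_strain(x_mm: np.ndarray, strain: np.ndarray) -> np.ndarray:
    """Axial displacement (mm) as the running integral of axial strain.

    The fixed end (x = 0) has zero displacement.
    """
    x = np.asarray(x_mm, float)
    e = np.asarray(strain, float)
    if x.shape != e.shape:
        raise ParameterError("positions and strain must have the same shape")
    return cumulative_trapezoid(e, x, initial=0.0)


def axial_displacement_profile(
    spec: SyntheticTissueSpec,
    zone_mech: ZoneMechanicsSpec,
    mode: str,
    load_value: float,
    n_samples: int = 4096,
    transition_mm: float = 0.05,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sampled (x_mm, u_mm) displacement profile along the long axis.

    ``mode='beat'`` scales the prescribed systolic zone strains by
    ``load_value`` (the beat amplitude); ``mode='ramp_step'`` sets the
    strain of zone z to ``load_value`` (a stress in kPa) divided by the
    zone modulus.
    """
    if mode == "beat":
        if zone_mech.systolic_strain_by_zone is None:
            raise ParameterError("beat mode requires systolic_strain_by_zone")
        zv = {z: load_value * s for z, s in zone_mech.systolic_strain_by_zone.items()}
    elif mode == "ramp_step":
        if zone_mech.modulus_by_zone is None:
            raise ParameterError("ramp_step mode requires modulus_by_zone")
        if load_value < 0:
            raise ParameterError("stress must be non-negative")
        zv = {z: load_value / e for z, e in zone_mech.modulus_by_zone.items()}
    else:
        raise ParameterError(f"unknown displacement mode {mode!r}")
    x = np.linspace(0.0, spec.length_mm, n_samples)
    e = zone_strain_profile(spec, zv, x, transition_mm)
    return x, displacement_from_strain(x, e)


# ---------------------------------------------------------------------------
# image warping


def warp_image(
    image: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    fill: float = 0.0,
    order: int = 3,
    n_iter: int = 10,
    warn_oob: bool = True,
) -> np.ndarray:
    """Apply a forward displacement field by inverse-mapped interpolation.

    ``u`` and ``v`` give the forward displacement (px) of the material
    point at each reference pixel along x (columns) and y (rows).  Each
    output pixel samples the reference at its pre-image, found by
    fixed-point inversion of ``X = x + u(x)`` (converges for the smooth,
    small-gradient fields used here).  Pixels whose pre-image falls
    outside the reference are filled with ``fill`` and a warning logged.
    """
    img = np.asarray(image, float)
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != img.shape or v.shape != img.shape:
        raise ParameterError("displacement field must cover the image domain")
    hh, ww = img.shape
    Y, X = np.mgrid[0:hh, 0:ww].astype(float)
    xp, yp = X - u, Y - v
    for _ in range(n_iter):
        us = map_coordinates(u, [yp, xp], order=1, mode="nearest")
        vs = map_coordinates(v, [yp, xp], order=1, mode="nearest")
        xp, yp = X - us, Y - vs
    oob = (xp < 0) | (xp > ww - 1) | (yp < 0) | (yp > hh - 1)
    out = map_coordinates(img, [yp, xp], order=order, mode="constant", cval=fill)
    if oob.any():
        log = logger.warning if warn_oob else logger.debug
        log(
            "warp samples %d px outside the reference; filled with background",
            int(oob.sum()),
        )
        out[oob] = fill
    return out


def _axial_field(
    spec: SyntheticTissueSpec, x_mm: np.ndarray, u_mm: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Expand a long-axis displacement profile to full-image (u, v) in px."""
    h, w = spec.shape
    cols = np.arange(w, dtype=float)
    xq = spec.x_mm(cols)
    u_cols = np.interp(xq, x_mm, u_mm) * spec.px_per_mm  # clamps at profile ends
    u = np.broadcast_to(u_cols, (h, w)).copy()
    v = np.zeros((h, w))
    return u, v


# ---------------------------------------------------------------------------
# sequence generators


@dataclass(frozen=True)
class RampSequence:
    """Frames plus protocol table for one stepped force ramp."""

    frames: np.ndarray  # (n_steps, H, W) uint8
    table: pd.DataFrame  # frame_index, amperage_A, force_mN, stress_kPa, time_s
    spec: SyntheticTissueSpec
    zone_mech: ZoneMechanicsSpec


def nominal_csa_mm2(
    spec: SyntheticTissueSpec,
    original_width_mm: float = 4.0,
    original_thickness_mm: float = 3.25,
) -> float:
    """Cross-sectional area implied by the compaction-scaled thickness model."""
    compaction = spec.width_mm / original_width_mm
    return spec.width_mm * compaction * original_thickness_mm


def generate_ramp_sequence(
    spec: SyntheticTissueSpec,
    zone_mech: ZoneMechanicsSpec,
    protocol: ForceProtocol,
    calibration,
    transition_mm: float = 0.05,
) -> RampSequence:
    """One frame per amperage level of a stepped electromagnet ramp.

    Frame i is the reference warped by the ramp-step displacement profile
    at stress(amperage_i) = force / nominal CSA; per-frame image noise is
    added independently (including the zero-amperage reference frame).
    """
    ref = generate_speckle(spec).astype(float)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF0]))
    csa = nominal_csa_mm2(spec)
    frames, rows = [], []
    for i, amp in enumerate(protocol.amperages):
        force = calibration.force(amp)
        stress = force / csa  # mN / mm^2 == kPa
        if stress == 0.0:
            warped = ref
        else:
            x_mm, u_mm = axial_displacement_profile(
                spec, zone_mech, "ramp_step", stress, transition_mm=transition_mm
            )
            u, v = _axial_field(spec, x_mm, u_mm)
            warped = warp_image(ref, u, v, warn_oob=False)
        frames.append(add_image_noise(warped, spec.noise_sd, rng))
        rows.append(
            {
                "frame_index": i,
                "amperage_A": amp,
                "force_mN": force,
                "stress_kPa": stress,
                "time_s": (i + 0.5) * protocol.step_duration_s,
            }
        )
    return RampSequence(
        frames=np.stack(frames), table=pd.DataFrame(rows), spec=spec, zone_mech=zone_mech
    )


@dataclass(frozen=True)
class BeatSequence:
    """Frames of one or more paced beat cycles with ground-truth indices."""

    frames: np.ndarray  # (n_frames, H, W) uint8
    times_s: np.ndarray
    true_systole_idx: int
    true_diastole_idx: int
    spec: SyntheticTissueSpec
    zone_mech: ZoneMechanicsSpec


def generate_beat_sequence(
    spec: SyntheticTissueSpec,
    zone_mech: ZoneMechanicsSpec,
    n_frames: int = 40,
    pacing_hz: float = 1.0,
    n_periods: float = 1.0,
    amplitude: float = 1.0,
    transition_mm: float = 0.05,
) -> BeatSequence:
    """Paced beat: displacement amplitude follows sin^2(pi f t).

    Frame 0 (amplitude zero) is diastole; the amplitude peaks mid-period.
    """
    if n_frames < 2:
        raise ParameterError("a beat sequence needs at least two frames")
    ref = generate_speckle(spec).astype(float)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB0]))
    times = np.linspace(0.0, n_periods / pacing_hz, n_frames, endpoint=False)
    amps = amplitude * np.sin(np.pi * pacing_hz * times) ** 2
    x_mm, u_mm = axial_displacement_profile(
        spec, zone_mech, "beat", 1.0, transition_mm=transition_mm
    )
    u1, v1 = _axial_field(spec, x_mm, u_mm)
    frames = []
    for a in amps:
        warped = ref if a == 0.0 else warp_image(ref, a * u1, a * v1, warn_oob=False)
        frames.append(add_image_noise(warped, spec.noise_sd, rng))
    first_period = amps[: max(2, int(round(n_frames / n_periods)))]
    return BeatSequence(
        frames=np.stack(frames),
        times_s=times,
        true_systole_idx=int(np.argmax(first_period)),
        true_diastole_idx=int(np.argmin(first_period)),
        spec=spec,
        zone_mech=zone_mech,
    )


def generate_beat_pair(
    spec: SyntheticTissueSpec,
    zone_mech: ZoneMechanicsSpec,
    amplitude: float = 1.0,
    transition_mm: float = 0.05,
) -> Tuple[np.ndarray, np.ndarray]:
    """(diastole, systole) frame pair at the prescribed peak strain."""
    ref = generate_speckle(spec).astype(float)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB1]))
    x_mm, u_mm = axial_displacement_profile(
        spec, zone_mech, "beat", amplitude, transition_mm=transition_mm
    )
    u, v = _axial_field(spec, x_mm, u_mm)
    dia = add_image_noise(ref, spec.noise_sd, rng)
    sys_ = add_image_noise(warp_image(ref, u, v, warn_oob=False), spec.noise_sd, rng)
    return dia, sys_


# ---------------------------------------------------------------------------
# fluorescence maps


def fluorescence_zone_map(spec: SyntheticTissueSpec) -> np.ndarray:
    """Per-column zone index (0 wound, 1 border, 2 remote) over the image width."""
    h, w = spec.shape
    x = spec.x_mm(np.arange(w))
    d = np.abs(x - spec.wound_center_mm)
    hw = spec.wound_width_mm / 2.0
    bw = spec.border_width_mm
    out = np.full(w, 2, int)
    out[d <= hw + bw] = 1
    out[d <= hw] = 0
    return out


def generate_fluorescence_maps(
    spec: SyntheticTissueSpec,
    zone_mech: ZoneMechanicsSpec,
    baseline_intensity: float = 200.0,
    edge_band_px: int = 10,
) -> Dict[str, np.ndarray]:
    """Multichannel fluorescence images with zonal density reductions.

    Within the tissue, intensity = baseline * (1 - reduction(zone)) plus
    Gaussian noise of sd ``spec.noise_sd * baseline``.  A band of
    ``edge_band_px`` columns at the fixed-end tissue edge keeps the full
    baseline in every channel so edge normalization stays well-posed.
    """
    reductions = zone_mech.density_reduction_by_zone_channel
    if reductions is None:
        reductions = {ch: {z: 0.0 for z in ZONES} for ch in CHANNELS}
    mask = tissue_mask(spec)
    zone_idx = fluorescence_zone_map(spec)
    zone_name = np.array(ZONES)[zone_idx]
    _, c0 = spec.tissue_origin_px
    cols = np.arange(spec.shape[1])
    edge = (cols >= c0) & (cols < c0 + edge_band_px)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xFA]))
    out: Dict[str, np.ndarray] = {}
    for ch, per_zone in reductions.items():
        factor = np.array([1.0 - per_zone.get(z, 0.0) for z in zone_name])
        factor[edge] = 1.0
        img = np.zeros(spec.shape, float)
        img += mask * (baseline_intensity * factor)[None, :]
        if spec.noise_sd > 0:
            img += mask * rng.normal(
                0.0, spec.noise_sd * baseline_intensity, spec.shape
            )
        out[ch] = np.clip(img, 0.0, None)
    return out
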