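"""Beat-cycle (systole vs diastole) strain profiles and regional summaries.

Diastole is the relaxed reference, so contraction yields negative axial
Green-Lagrange strain and passive stretching of the wound by the
surrounding contracting tissue yields positive strain.  The profile is
the per-column median Exx over the central 0.5 mm transverse band,
restricted to the central 90% of the long axis to avoid edge artefacts
from the mechanical restraints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

from .dic import DicParams, compute_strain, track_displacements
from .exceptions import AnalysisError, ParameterError
from .geometry import segment_tissue
from .partition import RegionPartition

logger = logging.getLogger(__name__)

ZONES = ("wound", "border", "remote")


@dataclass
class BeatStrainProfile:
    """Axial strain vs long-axis position between diastole and systole."""

    positions_mm: np.ndarray
    strain: np.ndarray
    zone: np.ndarray  # object array of zone labels (None outside subregions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position_mm": self.positions_mm, "strain": self.strain, "zone": self.zone}
        )


def _coarse_motion_metric(
    ref: np.ndarray, frm: np.ndarray, bbox: Tuple[int, int, int, int], tiles: int = 3
) -> float:
    """Mean tile-wise rigid displacement magnitude (px) vs the reference."""
    r0, r1, c0, c1 = bbox
    hs = np.linspace(r0, r1, tiles + 1).astype(int)
    ws = np.linspace(c0, c1, tiles + 1).astype(int)
    mags = []
    for i in range(tiles):
        for j in range(tiles):
            a = ref[hs[i] : hs[i + 1], ws[j] : ws[j + 1]]
            b = frm[hs[i] : hs[i + 1], ws[j] : ws[j + 1]]
            if min(a.shape) < 8:
                continue
            shift = phase_cross_correlation(a, b, upsample_factor=10)[0]
            mags.append(float(np.hypot(*shift)))
    return float(np.mean(mags)) if mags else 0.0


def select_beat_frames(
    frames: Sequence[np.ndarray],
    pacing_hz: float = 1.0,
    fps: float = 60.0,
    noise_floor_px: float = 0.1,
) -> Tuple[int, int]:
    """Automatic (systole_idx, diastole_idx) within the first pacing period.

    Diastole is the frame minimising, and systole the frame maximising,
    the mean tissue displacement magnitude relative to the first frame
    (estimated by coarse tile-wise phase correlation).  If no frame
    moves above ``noise_floor_px`` a warning is issued and the first and
    last frames are returned.
    """
    n = len(frames)
    if n < 2:
        raise ParameterError("need at least two frames")
    if pacing_hz <= 0 or fps <= 0:
        raise ParameterError("pacing_hz and fps must be positive")
    n_period = min(n, int(round(fps / pacing_hz)) + 1)
    ref = np.asarray(frames[0], float)
    mask = segment_tissue(ref)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    bbox = (rows[0], rows[-1] + 1, cols[0], cols[-1] + 1)
    metric = np.empty(n_period)
    metric[0] = 0.0
    for i in range(1, n_period):
        metric[i] = _coarse_motion_metric(ref, np.asarray(frames[i], float), bbox)
    if metric.max() < noise_floor_px:
        warnings.warn(
            "no tissue motion above the noise floor; returning first/last frame",
            stacklevel=2,
        )
        return n - 1, 0
    return int(np.argmax(metric)), int(np.argmin(metric))


def systolic_strain_profile(
    diastole_frame: np.ndarray,
    systole_frame: np.ndarray,
    params: Optional[DicParams] = None,
    px_per_mm: float = 50.0,
    band_mm: float = 0.5,
    central_fraction: float = 0.9,
    mask: Optional[np.ndarray] = None,
    partition: Optional[RegionPartition] = None,
    min_valid_fraction: float = 0.5,
) -> BeatStrainProfile:
    """Median axial strain per long-axis position between the two frames.

    Runs DIC from diastole to systole over the central transverse band
    (plus the strain-window margin), computes Green-Lagrange strains,
    and reports the per-grid-column median Exx over the band, restricted
    to the central ``central_fraction`` of the tissue long axis.
    Positions are mm from the fixed-end tissue edge.
    """
    params = params or DicParams()
    if px_per_mm <= 0:
        raise ParameterError("px_per_mm must be positive")
    dia = np.asarray(diastole_frame, float)
    if mask is None:
        mask = segment_tissue(dia)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    yc = (rows[0] + rows[-1]) / 2.0
    length_px = cols[-1] - cols[0] + 1
    trim = (1.0 - central_fraction) / 2.0 * length_px
    x_lo, x_hi = cols[0] + trim, cols[-1] - trim
    half_band = band_mm / 2.0 * px_per_mm

    region = np.zeros_like(mask)
    margin = params.strain_window_px
    r0 = int(max(0, yc - half_band - margin))
    r1 = int(min(mask.shape[0], yc + half_band + margin + 1))
    c0 = int(max(0, x_lo - margin))
    c1 = int(min(mask.shape[1], x_hi + margin + 1))
    region[r0:r1, c0:c1] = True
    region &= mask

    disp = track_displacements(dia, systole_frame, params, mask=region)
    if disp.valid.sum() == 0 or disp.valid_fraction() < 1e-6:
        raise AnalysisError("DIC produced no valid points")
    tracked = np.isfinite(disp.score)
    if tracked.any() and disp.valid.sum() / tracked.sum() < min_valid_fraction:
        raise AnalysisError(
            "DIC failed on more than half of the grid "
            f"({disp.valid.sum()}/{tracked.sum()} valid)"
        )
    strain = compute_strain(disp, params)

    in_band = np.abs(strain.y.astype(float) - yc) <= half_band
    in_x = (strain.x >= x_lo) & (strain.x <= x_hi)
    xs = strain.x[in_x]
    prof_pos, prof_val = [], []
    for k, x in zip(np.flatnonzero(in_x), xs):
        col_valid = strain.valid[in_band, k]
        if not col_valid.any():
            continue
        prof_pos.append((x - cols[0]) / px_per_mm)
        prof_val.append(float(np.median(strain.Exx[in_band, k][col_valid])))
    if not prof_pos:
        raise AnalysisError("no valid strain columns in the central band")
    positions = np.asarray(prof_pos)
    values = np.asarray(prof_val)
    if partition is not None:
        zone = np.array(
            [partition.zone_of_position(p) for p in positions], dtype=object
        )
    else:
        zone = np.full(positions.shape, None, dtype=object)
    return BeatStrainProfile(positions_mm=positions, strain=values, zone=zone)


def regional_systolic_strain(
    profile: BeatStrainProfile, partition: RegionPartition
) -> Dict[str, float]:
    """Mean profile strain over each zone's subregion positions.

    Positions falling in gaps between subregions are excluded; a zone
    with no profile positions is reported as NaN (missing).
    """
    zones = np.array(
        [partition.zone_of_position(p) for p in profile.positions_mm], dtype=object
    )
    out: Dict[str, float] = {}
    for z in ZONES:
        sel = zones == z
        out[z] = float(profile.strain[sel].mean()) if sel.any() else np.nan
    return out
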