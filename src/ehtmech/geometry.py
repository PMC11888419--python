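"""Tissue geometry: widths, compaction, thickness and cross-sectional area.

Widths are measured on a baseline unstretched frame at the axial middle
and the two ends, interpolated linearly from each end to the middle,
and converted to a compaction factor (width / original cast width of
4 mm).  Thickness is the compaction factor applied to the original gel
thickness (3.25 mm, the culture-well height), and the cross-sectional
area is width x thickness.  Because thickness is proportional to width,
CSA = width^2 * (original_thickness / original_width) holds exactly at
every position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk

from .exceptions import AnalysisError, ParameterError

logger = logging.getLogger(__name__)

ORIGINAL_WIDTH_MM = 4.0
ORIGINAL_THICKNESS_MM = 3.25


def segment_tissue(frame: np.ndarray) -> np.ndarray:
    """Binary tissue mask from a grayscale frame.

    Uses a three-class Otsu threshold (background | tissue matrix |
    speckle highlights) and keeps everything above the lower cut, then
    closes small gaps, selects the largest connected component and
    fills holes.  A plain two-class Otsu would split the speckles from
    the matrix rather than the tissue from the background.
    """
    f = np.asarray(frame, float)
    if not np.isfinite(f).any() or f.max() <= f.min():
        raise AnalysisError("frame has no contrast; cannot segment tissue")
    try:
        t = float(threshold_multiotsu(f, classes=3)[0])
    except ValueError:  # fewer than three grey levels present
        t = float(threshold_otsu(f))
    m = f > t
    if not m.any():
        raise AnalysisError("segmentation produced an empty mask")
    m = closing(m, disk(3))
    lab = label(m)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    m = lab == int(np.argmax(counts))
    return binary_fill_holes(m)


def measure_widths(
    frame: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    px_per_mm: float = 1.0,
) -> Tuple[float, Tuple[float, float]]:
    """Baseline widths (mm) at the axial middle and the two ends.

    Width at a column is the transverse extent of the mask there,
    median-filtered over a two-column neighbourhood for robustness to
    stray pixels.  Either a frame (segmented automatically) or an
    explicit mask may be given; manual measurements can bypass this
    entirely via :func:`interpolate_geometry`.
    """
    if px_per_mm <= 0:
        raise ParameterError("px_per_mm must be positive")
    if mask is None:
        if frame is None:
            raise ParameterError("either frame or mask is required")
        mask = segment_tissue(frame)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise AnalysisError("empty tissue mask")
    cols = np.flatnonzero(mask.any(axis=0))

    def width_at(col: int) -> float:
        vals = []
        for c in range(max(cols[0], col - 2), min(cols[-1], col + 2) + 1):
            rows = np.flatnonzero(mask[:, c])
            if rows.size:
                vals.append(rows[-1] - rows[0] + 1)
        if not vals:
            raise AnalysisError(f"no tissue pixels near column {col}")
        return float(np.median(vals)) / px_per_mm

    middle_col = int((cols[0] + cols[-1]) // 2)
    return width_at(middle_col), (width_at(int(cols[0])), width_at(int(cols[-1])))


@dataclass
class TissueGeometry:
    """Per-position widths, compaction, thickness and CSA along the long axis."""

    positions_mm: np.ndarray
    width_mm: np.ndarray
    compaction: np.ndarray
    thickness_mm: np.ndarray
    csa_mm2: np.ndarray
    original_width_mm: float = ORIGINAL_WIDTH_MM
    original_thickness_mm: float = ORIGINAL_THICKNESS_MM
    length_mm: float = 0.0
    anchors_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    anchor_widths_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def csa_at(self, x_mm) -> np.ndarray:
        """CSA (mm^2) at arbitrary positions via the width interpolant."""
        w = np.interp(np.asarray(x_mm, float), self.anchors_mm, self.anchor_widths_mm)
        return w**2 * self.original_thickness_mm / self.original_width_mm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_mm": self.positions_mm,
                "width_mm": self.width_mm,
                "compaction": self.compaction,
                "thickness_mm": self.thickness_mm,
                "csa_mm2": self.csa_mm2,
            }
        )


def interpolate_geometry(
    middle_width_mm: float,
    end_widths_mm: Tuple[float, float],
    positions_mm: np.ndarray,
    length_mm: float,
    original_width_mm: float = ORIGINAL_WIDTH_MM,
    original_thickness_mm: float = ORIGINAL_THICKNESS_MM,
) -> TissueGeometry:
    """Linear end-to-middle width interpolation and derived geometry.

    Widths vary linearly from each end anchor to the middle anchor (two
    independent segments, exact at the three measured positions).
    Compaction factors above one are permitted but flagged with a
    warning, since a gel wider than its cast is physically suspect.
    """
    e0, e1 = float(end_widths_mm[0]), float(end_widths_mm[1])
    if middle_width_mm <= 0 or e0 <= 0 or e1 <= 0:
        raise ParameterError("widths must be positive")
    if length_mm <= 0:
        raise ParameterError("length_mm must be positive")
    pos = np.atleast_1d(np.asarray(positions_mm, float))
    if np.any(np.diff(pos) <= 0):
        raise ParameterError("positions must be strictly increasing")
    if pos.min() < -1e-9 or pos.max() > length_mm + 1e-9:
        raise ParameterError("positions must lie within [0, length_mm]")
    anchors = (0.0, length_mm / 2.0, length_mm)
    anchor_w = (e0, float(middle_width_mm), e1)
    width = np.interp(pos, anchors, anchor_w)
    compaction = width / original_width_mm
    if np.any(compaction > 1.0 + 1e-9):
        logger.warning(
            "compaction factor exceeds 1 (max %.3f): tissue wider than cast",
            float(compaction.max()),
        )
    thickness = compaction * original_thickness_mm
    csa = width * thickness
    return TissueGeometry(
        positions_mm=pos,
        width_mm=width,
        compaction=compaction,
        thickness_mm=thickness,
        csa_mm2=csa,
        original_width_mm=original_width_mm,
        original_thickness_mm=original_thickness_mm,
        length_mm=length_mm,
        anchors_mm=anchors,
        anchor_widths_mm=anchor_w,
    )


def geometry_from_frame(
    frame: np.ndarray,
    px_per_mm: float,
    positions_mm: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
) -> TissueGeometry:
    """Measure widths on a baseline frame and build the geometry table."""
    if mask is None:
        mask = segment_tissue(frame)
    middle, ends = measure_widths(frame=frame, mask=mask, px_per_mm=px_per_mm)
    cols = np.flatnonzero(mask.any(axis=0))
    length_mm = (cols[-1] - cols[0] + 1) / px_per_mm
    if positions_mm is None:
        positions_mm = np.linspace(0.0, length_mm, 101)
    return interpolate_geometry(middle, ends, positions_mm, length_mm)
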