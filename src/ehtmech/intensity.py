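"""Fluorescence intensity traces, edge normalization, regional AUC.

Each channel image is collapsed to a long-axis trace (per-column mean
over the tissue mask), normalized to the mean of a 10-pixel band at the
tissue's outer edge, and integrated (trapezoid rule) over each zone's
positional extent to give a regional area under the curve in mm units.
Fold-change relative to the prewound AUC is (AUC_t - AUC_0) / AUC_0, so
the no-change null mean is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, ParameterError
from .partition import RegionPartition

ZONES = ("wound", "border", "remote")


@dataclass(frozen=True)
class IntensityTrace:
    """Long-axis intensity trace of one channel.

    Positions are pixels from the fixed-end tissue edge; column spacing
    is preserved even when empty mask columns are dropped.
    """

    positions_px: np.ndarray
    values: np.ndarray
    channel: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.positions_px.shape != self.values.shape:
            raise ParameterError("positions and values must have the same shape")

    def __len__(self) -> int:
        return int(self.positions_px.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_px": self.positions_px,
                "value": self.values,
                "channel": self.channel,
                "normalized": self.normalized,
            }
        )


def long_axis_trace(
    channel_image: np.ndarray, mask: np.ndarray, channel: str = ""
) -> IntensityTrace:
    """Per-column mean intensity over masked pixels.

    Columns with no masked pixels are dropped (their positions are
    simply absent from the trace).
    """
    img = np.asarray(channel_image, float)
    m = np.asarray(mask, bool)
    if img.shape != m.shape:
        raise ParameterError("image and mask must have the same shape")
    if not m.any():
        raise AnalysisError("empty tissue mask")
    counts = m.sum(axis=0)
    cols = np.flatnonzero(counts)
    sums = (img * m).sum(axis=0)[cols]
    vals = sums / counts[cols]
    return IntensityTrace(
        positions_px=(cols - cols[0]).astype(float), values=vals, channel=channel
    )


def normalize_to_edge(
    trace: IntensityTrace, edge_band_px: int = 10, mode: str = "fixed_end"
) -> IntensityTrace:
    """Divide the trace by the mean of its outer-edge band.

    ``mode='fixed_end'`` (default) uses the first ``edge_band_px``
    positions, following the convention that each sample is normalized
    to a band at its own outer edge; ``mode='both'`` averages the bands
    at both ends.  The band mean becomes exactly one.
    """
    if edge_band_px < 1:
        raise ParameterError("edge_band_px must be >= 1")
    if len(trace) < edge_band_px:
        raise ParameterError("trace shorter than the edge band")
    if mode == "fixed_end":
        ref = float(trace.values[:edge_band_px].mean())
    elif mode == "both":
        ref = float(
            0.5
            * (trace.values[:edge_band_px].mean() + trace.values[-edge_band_px:].mean())
        )
    else:
        raise ParameterError(f"unknown normalization mode {mode!r}")
    if ref <= 0:
        raise AnalysisError("edge-band mean is not positive; cannot normalize")
    return replace(trace, values=trace.values / ref, normalized=True)


def _interval_auc(x: np.ndarray, y: np.ndarray, a: float, b: float) -> Optional[float]:
    """Trapezoidal integral of the piecewise-linear trace over [a, b]."""
    lo, hi = max(a, float(x[0])), min(b, float(x[-1]))
    if hi <= lo:
        return None
    inner = (x > lo) & (x < hi)
    xs = np.concatenate([[lo], x[inner], [hi]])
    ys = np.concatenate([[np.interp(lo, x, y)], y[inner], [np.interp(hi, x, y)]])
    return float(np.trapezoid(ys, xs))


def regional_auc(
    trace: IntensityTrace, partition: RegionPartition, px_per_mm: float
) -> Dict[str, float]:
    """Area under the normalized trace over each zone's extent (mm units).

    Zone extents partially outside the trace are integrated over the
    overlap; a zone entirely outside the trace is reported as NaN.
    """
    if not trace.normalized:
        raise ParameterError("regional AUC is defined on the edge-normalized trace")
    if px_per_mm <= 0:
        raise ParameterError("px_per_mm must be positive")
    x = trace.positions_px / px_per_mm
    out: Dict[str, float] = {}
    for zone, intervals in partition.zone_extents.items():
        parts = [
            v
            for a, b in intervals
            if (v := _interval_auc(x, trace.values, a, b)) is not None
        ]
        out[zone] = float(np.sum(parts)) if parts else np.nan
    return out


def fold_change(
    auc_t: Mapping[str, float], auc_prewound: Mapping[str, float]
) -> Dict[str, float]:
    """Per-zone fold-change vs prewound: (AUC_t - AUC_0) / AUC_0."""
    out: Dict[str, float] = {}
    for zone, pre in auc_prewound.items():
        if zone not in auc_t:
            continue
        if not np.isfinite(pre) or pre <= 0:
            raise AnalysisError(f"prewound AUC for zone {zone!r} must be positive")
        out[zone] = (float(auc_t[zone]) - float(pre)) / float(pre)
    return out
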