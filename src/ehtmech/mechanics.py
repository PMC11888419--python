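"""Stress-strain mechanics of the stepped force ramp.

The electromagnet amperage ramp is converted to force through a
hardware calibration (user configuration; linear through the origin by
default), force to stress by dividing by the position-dependent
cross-sectional area (mN / mm^2 = kPa), and stress is paired with the
DIC-measured median axial strain of each analysis subregion at every
ramp step.  Each subregion's (strain, stress) series is averaged within
seven uniform-width bins along the strain axis and an ordinary
least-squares line gives the subregion modulus; zone moduli are the
means over the subregions carrying each label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dic import StrainField
from .exceptions import AnalysisError, ParameterError
from .geometry import TissueGeometry
from .partition import RegionPartition, Span

ZONES = ("wound", "border", "remote")


@dataclass(frozen=True)
class ForceCalibration:
    """Amperage-to-force map, F(I) = sum_k c_k I^k (no constant term).

    Coefficients are in mN/A, mN/A^2, ... so F(0) = 0 by construction.
    The default single coefficient gives the documented linear model
    F = 1.0 mN/A * I; real rigs supply their own coefficients, and all
    downstream results are covariant with this calibration.
    """

    coefficients: Tuple[float, ...] = (1.0,)
    distance_mm: float = 3.0
    model: str = "polynomial"

    def __post_init__(self) -> None:
        if len(self.coefficients) == 0:
            raise ParameterError("calibration needs at least one coefficient")
        grid = np.linspace(0.0, 0.8, 81)
        f = self._eval(grid)
        if np.any(np.diff(f) < -1e-12):
            raise ParameterError("force must be non-decreasing over 0-0.8 A")

    def _eval(self, amperage: np.ndarray) -> np.ndarray:
        amps = np.asarray(amperage, float)
        out = np.zeros_like(amps)
        for k, c in enumerate(self.coefficients, start=1):
            out += c * amps**k
        return out

    def force(self, amperage: float) -> float:
        """Force (mN) at the given amperage (A)."""
        if np.any(np.asarray(amperage) < 0):
            raise ParameterError("amperage must be non-negative")
        return float(self._eval(np.asarray(amperage, float)))


def force_from_amperage(amperage: float, cal: ForceCalibration) -> float:
    """Functional alias for :meth:`ForceCalibration.force`."""
    return cal.force(amperage)


def stress_profile(force_mN: float, geometry: TissueGeometry) -> np.ndarray:
    """Axial stress (kPa) at each geometry position: force / CSA."""
    if force_mN < 0:
        raise ParameterError("force must be non-negative")
    csa = np.asarray(geometry.csa_mm2, float)
    if np.any(csa <= 0):
        raise AnalysisError("cross-sectional area must be positive everywhere")
    return force_mN / csa


def subregion_strains(
    strain_fields: Sequence[StrainField],
    spans: Sequence[Span],
    px_per_mm: float,
    origin_x_px: float,
    center_y_px: float,
    band_mm: float = 0.5,
) -> pd.DataFrame:
    """Median axial strain per subregion and ramp step.

    For each strain field (one per ramp step) and each axial span, takes
    the median Exx over valid grid points inside the span and within the
    central ``band_mm`` transverse band about ``center_y_px``.  Gaps
    between subregions are excluded by construction.  Subregions with no
    valid points get NaN (flagged missing).
    """
    if px_per_mm <= 0:
        raise ParameterError("px_per_mm must be positive")
    rows = []
    half_band_px = band_mm / 2.0 * px_per_mm
    for step, fld in enumerate(strain_fields):
        x_mm = (fld.x.astype(float) - origin_x_px) / px_per_mm
        in_band = np.abs(fld.y.astype(float) - center_y_px) <= half_band_px
        for si, (a, b) in enumerate(spans):
            in_span = (x_mm >= a) & (x_mm < b)
            sel = fld.valid[np.ix_(in_band, in_span)]
            vals = fld.Exx[np.ix_(in_band, in_span)][sel]
            rows.append(
                {
                    "step": step,
                    "subregion": si,
                    "strain": float(np.median(vals)) if vals.size else np.nan,
                    "n_points": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ModulusFit:
    """Binned linear-regression modulus of one subregion."""

    modulus_kPa: float
    intercept_kPa: float
    r2: float
    n_bins_occupied: int
    bins: pd.DataFrame
    flag: Optional[str] = None


def fit_modulus(
    strains: np.ndarray, stresses: np.ndarray, n_bins: int = 7
) -> ModulusFit:
    """Seven-bin averaged stress-strain regression.

    Strains and stresses are averaged within ``n_bins`` uniform-width
    bins spanning the observed strain range, and ordinary least squares
    on the occupied bin means gives the modulus (slope, kPa).  Requires
    at least two occupied bins with distinct mean strains; otherwise the
    fit is flagged degenerate with a NaN modulus.
    """
    e = np.asarray(strains, float)
    s = np.asarray(stresses, float)
    if e.shape != s.shape:
        raise ParameterError("strain and stress arrays must match")
    ok = np.isfinite(e) & np.isfinite(s)
    e, s = e[ok], s[ok]
    empty = pd.DataFrame(columns=["bin", "mean_strain", "mean_stress", "n"])
    if e.size < 2 or np.ptp(e) <= 0:
        return ModulusFit(np.nan, np.nan, np.nan, 0, empty, flag="degenerate")
    edges = np.linspace(e.min(), e.max(), n_bins + 1)
    idx = np.clip(np.digitize(e, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            rows.append(
                {
                    "bin": b,
                    "mean_strain": float(e[sel].mean()),
                    "mean_stress": float(s[sel].mean()),
                    "n": int(sel.sum()),
                }
            )
    bins = pd.DataFrame(rows)
    if len(bins) < 2 or bins["mean_strain"].nunique() < 2:
        return ModulusFit(np.nan, np.nan, np.nan, len(bins), bins, flag="degenerate")
    res = sps.linregress(bins["mean_strain"], bins["mean_stress"])
    return ModulusFit(
        modulus_kPa=float(res.slope),
        intercept_kPa=float(res.intercept),
        r2=float(res.rvalue**2),
        n_bins_occupied=len(bins),
        bins=bins,
    )


def regional_moduli(
    subregion_fits: Mapping[int, ModulusFit], partition: RegionPartition
) -> Dict[str, float]:
    """Zone modulus = mean of its subregions' moduli (NaN if none defined)."""
    labels = partition.zone_of_subregion
    out: Dict[str, float] = {}
    for zone in ZONES:
        vals = [
            f.modulus_kPa
            for i, f in subregion_fits.items()
            if labels[i] == zone and np.isfinite(f.modulus_kPa)
        ]
        out[zone] = float(np.mean(vals)) if vals else np.nan
    return out


def build_series(
    sub_strains: pd.DataFrame,
    protocol: pd.DataFrame,
    geometry: TissueGeometry,
    spans: Sequence[Span],
) -> pd.DataFrame:
    """Per-subregion (amperage, force, stress, strain) series table.

    Stress uses the CSA at each subregion's centre position; by
    construction stress * CSA equals the applied force exactly.
    """
    centers = np.array([(a + b) / 2.0 for a, b in spans])
    csa = geometry.csa_at(centers)
    merged = sub_strains.merge(
        protocol[["frame_index", "amperage_A", "force_mN"]],
        left_on="step",
        right_on="frame_index",
        how="left",
    )
    merged["stress_kPa"] = merged["force_mN"] / csa[merged["subregion"].to_numpy()]
    return merged.drop(columns=["frame_index"])
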