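"""End-to-end analyses and the seeded synthetic studies that validate them.

Three analyses mirror the experimental workflow: the ramp-stiffness
study (stepped electromagnet force, DIC strain, regional modulus
regression), the systolic-strain study (diastole-to-systole strain
profile and zone means) and the intensity study (edge-normalized
fluorescence AUC fold-changes).  The replicate-study helpers generate
fully synthetic cohorts with known ground truth for parameter-recovery
validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import intensity as intensity_mod
from . import mechanics, synthetic, systolic
from .config import RunConfig
from .dic import DicParams, StrainField, compute_strain, track_displacements
from .exceptions import AnalysisError, ParameterError
from .geometry import TissueGeometry, geometry_from_frame, segment_tissue
from .io import read_frames, read_table, write_table, write_yaml
from .partition import RegionPartition, default_partition, positional_bins

logger = logging.getLogger(__name__)

ZONES = ("wound", "border", "remote")

DEFAULT_MODULI = {"wound": 30.0, "border": 20.0, "remote": 10.0}
DEFAULT_BEAT_STRAINS = {"wound": 0.04, "remote": -0.03}
CONTROL_BEAT_STRAINS = {"wound": -0.02, "border": -0.02, "remote": -0.02}
DEFAULT_REDUCTIONS = {"wound": 0.40, "border": 0.30, "remote": 0.075}
# linear force calibration used for the synthetic ramp studies (mN/A);
# chosen so the top 0.8 A step loads the remote zone to ~8% strain
STUDY_CALIBRATION_MN_PER_A = 13.0
# imaging scale of the synthetic studies; regional structure is at the
# 0.5 mm scale, so the DIC kernel (subset + strain window) must stay well
# below that, which needs >= ~100 px/mm as in the original recordings
STUDY_PX_PER_MM = 150.0
STUDY_MARGIN_PX = 40


def study_dic_params() -> DicParams:
    """DIC parameters matched to the synthetic-study imaging scale.

    At 150 px/mm a 12 px subset half-width plus a 10 px strain window
    gives an effective strain-smoothing kernel of ~0.15 mm half-width,
    below the 0.2 mm gaps separating the analysis subregions.  The small
    search radius relies on step-to-step initial-guess propagation.
    """
    return DicParams(subset_px=12, spacing_px=5, search_px=8, strain_window_px=10)


def child_seed(base_seed: int, *tags: int) -> int:
    """Deterministic sub-seed below 2**31 derived from a base seed."""
    ss = np.random.SeedSequence([int(base_seed), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# ramp stiffness analysis


@dataclass
class StiffnessResult:
    geometry: TissueGeometry
    partition: RegionPartition
    series: pd.DataFrame
    fits: Dict[int, mechanics.ModulusFit]
    zone_moduli: Dict[str, float]
    subregion_zones: List[str]


def _band_region_mask(
    mask: np.ndarray,
    yc: float,
    half_band_px: float,
    x_lo: float,
    x_hi: float,
    margin: int,
) -> np.ndarray:
    region = np.zeros_like(mask)
    r0 = int(max(0, yc - half_band_px - margin))
    r1 = int(min(mask.shape[0], yc + half_band_px + margin + 1))
    c0 = int(max(0, x_lo - margin))
    c1 = int(min(mask.shape[1], x_hi + margin + 1))
    region[r0:r1, c0:c1] = True
    return region & mask


def analyze_ramp(
    frames: np.ndarray,
    protocol: pd.DataFrame,
    px_per_mm: float,
    dic_params: Optional[DicParams] = None,
    partition: Optional[RegionPartition] = None,
    calibration: Optional[mechanics.ForceCalibration] = None,
    band_mm: float = 0.5,
    binning: str = "strain",
    n_bins: int = 7,
) -> StiffnessResult:
    """Regional moduli from a stepped-ramp frame sequence.

    Frame 0 (the zero-load reference) defines the tissue mask, geometry
    and the strain reference; every later frame is correlated against
    it.  ``binning='strain'`` (default) averages each subregion's ramp
    series within seven uniform strain-axis bins before the regression;
    ``binning='position'`` instead divides the analysis span into seven
    uniform positional bins, regressing each and averaging by zone.
    """
    params = dic_params or DicParams()
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ParameterError("need a (n_steps, H, W) stack with at least two frames")
    if "force_mN" not in protocol.columns:
        if calibration is None:
            raise ParameterError(
                "protocol has no force_mN column and no calibration was given"
            )
        protocol = protocol.copy()
        protocol["force_mN"] = [
            calibration.force(a) for a in protocol["amperage_A"]
        ]
    if "frame_index" not in protocol.columns:
        protocol = protocol.copy()
        protocol["frame_index"] = np.arange(len(protocol))
    if len(protocol) != frames.shape[0]:
        raise ParameterError("protocol table must have one row per frame")

    ref = np.asarray(frames[0], float)
    mask = segment_tissue(ref)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    origin_x = float(cols[0])
    yc = (rows[0] + rows[-1]) / 2.0
    length_mm = (cols[-1] - cols[0] + 1) / px_per_mm
    geometry = geometry_from_frame(ref, px_per_mm, mask=mask)
    if partition is None:
        partition = default_partition(length_mm / 2.0, length_mm)

    if binning == "strain":
        spans = partition.subregion_spans
        zone_labels = partition.zone_of_subregion
    elif binning == "position":
        pbins = positional_bins(partition, n_bins)
        spans = [s for s, _ in pbins]
        zone_labels = [z for _, z in pbins]
    else:
        raise ParameterError(f"unknown binning mode {binning!r}")

    half_band_px = band_mm / 2.0 * px_per_mm
    x_lo = origin_x + min(a for a, _ in spans) * px_per_mm
    x_hi = origin_x + max(b for _, b in spans) * px_per_mm
    region = _band_region_mask(
        mask, yc, half_band_px, x_lo, x_hi, params.strain_window_px
    )

    strain_fields: List[StrainField] = []
    prev = None  # propagate each step's field as the next step's search centre
    for i in range(1, frames.shape[0]):
        disp = track_displacements(
            ref, np.asarray(frames[i], float), params, region, init=prev
        )
        prev = (disp.u, disp.v)
        strain_fields.append(compute_strain(disp, params))

    sub = mechanics.subregion_strains(
        strain_fields, spans, px_per_mm, origin_x, yc, band_mm
    )
    sub["step"] += 1  # fields start at frame 1
    zero_rows = pd.DataFrame(
        {
            "step": 0,
            "subregion": np.arange(len(spans)),
            "strain": 0.0,  # frame 0 is its own strain reference
            "n_points": 0,
        }
    )
    sub = pd.concat([zero_rows, sub], ignore_index=True)
    series = mechanics.build_series(sub, protocol, geometry, spans)

    fits: Dict[int, mechanics.ModulusFit] = {}
    for si in range(len(spans)):
        rows_i = series[series["subregion"] == si]
        fits[si] = mechanics.fit_modulus(
            rows_i["strain"].to_numpy(), rows_i["stress_kPa"].to_numpy(), n_bins
        )
    zone_moduli: Dict[str, float] = {}
    for zone in ZONES:
        vals = [
            fits[i].modulus_kPa
            for i in range(len(spans))
            if zone_labels[i] == zone and np.isfinite(fits[i].modulus_kPa)
        ]
        zone_moduli[zone] = float(np.mean(vals)) if vals else np.nan
    return StiffnessResult(
        geometry=geometry,
        partition=partition,
        series=series,
        fits=fits,
        zone_moduli=zone_moduli,
        subregion_zones=list(zone_labels),
    )


# ---------------------------------------------------------------------------
# systolic analysis


@dataclass
class BeatResult:
    profile: systolic.BeatStrainProfile
    zone_strain: Dict[str, float]
    partition: RegionPartition
    systole_idx: Optional[int] = None
    diastole_idx: Optional[int] = None


def analyze_beat(
    diastole_frame: np.ndarray,
    systole_frame: np.ndarray,
    px_per_mm: float,
    dic_params: Optional[DicParams] = None,
    partition: Optional[RegionPartition] = None,
    band_mm: float = 0.5,
    central_fraction: float = 0.9,
) -> BeatResult:
    """Systolic strain profile and zone means for one diastole/systole pair."""
    mask = segment_tissue(np.asarray(diastole_frame, float))
    cols = np.flatnonzero(mask.any(axis=0))
    length_mm = (cols[-1] - cols[0] + 1) / px_per_mm
    if partition is None:
        partition = default_partition(length_mm / 2.0, length_mm)
    profile = systolic.systolic_strain_profile(
        diastole_frame,
        systole_frame,
        dic_params,
        px_per_mm,
        band_mm=band_mm,
        central_fraction=central_fraction,
        mask=mask,
        partition=partition,
    )
    zones = systolic.regional_systolic_strain(profile, partition)
    return BeatResult(profile=profile, zone_strain=zones, partition=partition)


def analyze_beat_sequence(
    frames: np.ndarray,
    px_per_mm: float,
    pacing_hz: float = 1.0,
    fps: float = 60.0,
    **kw,
) -> BeatResult:
    """Automatic frame selection followed by :func:`analyze_beat`."""
    sys_idx, dia_idx = systolic.select_beat_frames(frames, pacing_hz, fps)
    res = analyze_beat(frames[dia_idx], frames[sys_idx], px_per_mm, **kw)
    res.systole_idx = sys_idx
    res.diastole_idx = dia_idx
    return res


# ---------------------------------------------------------------------------
# intensity analysis


@dataclass
class IntensityResult:
    traces: Dict[str, intensity_mod.IntensityTrace]
    auc: pd.DataFrame  # rows: channel, columns: zones
    auc_prewound: pd.DataFrame
    fold_change: pd.DataFrame


def _fluor_mask(images: Mapping[str, np.ndarray]) -> np.ndarray:
    """Heuristic tissue mask: union of per-channel low-threshold masks."""
    from scipy.ndimage import binary_fill_holes
    from skimage.measure import label

    acc = None
    for img in images.values():
        arr = np.asarray(img, float)
        m = arr > 0.1 * arr.max()
        acc = m if acc is None else (acc | m)
    if acc is None or not acc.any():
        raise AnalysisError("could not derive a tissue mask from the channels")
    lab = label(acc)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return binary_fill_holes(lab == int(np.argmax(counts)))


def analyze_intensity(
    images: Mapping[str, np.ndarray],
    prewound_images: Mapping[str, np.ndarray],
    px_per_mm: float,
    partition: Optional[RegionPartition] = None,
    mask: Optional[np.ndarray] = None,
    prewound_mask: Optional[np.ndarray] = None,
    edge_band_px: int = 10,
    edge_mode: str = "fixed_end",
) -> IntensityResult:
    """Edge-normalized traces, regional AUCs and fold-changes vs prewound."""
    if mask is None:
        mask = _fluor_mask(images)
    if prewound_mask is None:
        prewound_mask = _fluor_mask(prewound_images)
    if partition is None:
        cols = np.flatnonzero(mask.any(axis=0))
        length_mm = (cols[-1] - cols[0] + 1) / px_per_mm
        partition = default_partition(length_mm / 2.0, length_mm)
    traces: Dict[str, intensity_mod.IntensityTrace] = {}
    auc_rows, pre_rows, fold_rows = [], [], []
    for ch in images:
        tr = intensity_mod.normalize_to_edge(
            intensity_mod.long_axis_trace(images[ch], mask, ch),
            edge_band_px,
            edge_mode,
        )
        traces[ch] = tr
        auc = intensity_mod.regional_auc(tr, partition, px_per_mm)
        pre_tr = intensity_mod.normalize_to_edge(
            intensity_mod.long_axis_trace(prewound_images[ch], prewound_mask, ch),
            edge_band_px,
            edge_mode,
        )
        pre = intensity_mod.regional_auc(pre_tr, partition, px_per_mm)
        fold = intensity_mod.fold_change(auc, pre)
        auc_rows.append({"channel": ch, **auc})
        pre_rows.append({"channel": ch, **pre})
        fold_rows.append({"channel": ch, **fold})
    return IntensityResult(
        traces=traces,
        auc=pd.DataFrame(auc_rows).set_index("channel"),
        auc_prewound=pd.DataFrame(pre_rows).set_index("channel"),
        fold_change=pd.DataFrame(fold_rows).set_index("channel"),
    )


# ---------------------------------------------------------------------------
# synthetic replicate studies


def ramp_recovery_study(
    seed: int = 0,
    noise_sd: float = 0.0,
    moduli: Optional[Mapping[str, float]] = None,
    px_per_mm: float = STUDY_PX_PER_MM,
    calibration_mn_per_a: float = STUDY_CALIBRATION_MN_PER_A,
    dic_params: Optional[DicParams] = None,
    binning: str = "strain",
) -> StiffnessResult:
    """Generate one synthetic ramp and recover the zone moduli end-to-end."""
    spec = synthetic.SyntheticTissueSpec(
        px_per_mm=px_per_mm, margin_px=STUDY_MARGIN_PX, noise_sd=noise_sd, seed=seed
    )
    if dic_params is None:
        dic_params = study_dic_params()
    mech = synthetic.ZoneMechanicsSpec(modulus_by_zone=dict(moduli or DEFAULT_MODULI))
    cal = mechanics.ForceCalibration(coefficients=(calibration_mn_per_a,))
    seq = synthetic.generate_ramp_sequence(spec, mech, synthetic.ForceProtocol(), cal)
    partition = default_partition(spec.wound_center_mm, spec.length_mm)
    return analyze_ramp(
        seq.frames,
        seq.table,
        px_per_mm,
        dic_params=dic_params,
        partition=partition,
        binning=binning,
    )


def systolic_replicates(
    n: int = 9,
    base_seed: int = 0,
    wounded: bool = True,
    noise_sd: float = 0.02,
    jitter: float = 0.1,
    px_per_mm: float = STUDY_PX_PER_MM,
    dic_params: Optional[DicParams] = None,
) -> pd.DataFrame:
    """Zone-mean systolic strains for a cohort of synthetic tissues.

    Each replicate gets an independent speckle texture, image noise and
    a per-zone relative jitter (sd ``jitter``) on the prescribed peak
    strains, emulating sample-to-sample biological variability.
    """
    target = DEFAULT_BEAT_STRAINS if wounded else CONTROL_BEAT_STRAINS
    if dic_params is None:
        dic_params = study_dic_params()
    rows = []
    for i in range(n):
        seed_i = child_seed(base_seed, 0x5E, i)
        rng = np.random.default_rng(child_seed(base_seed, 0x5F, i))
        strains = {
            z: v * (1.0 + jitter * rng.standard_normal()) for z, v in target.items()
        }
        spec = synthetic.SyntheticTissueSpec(
            px_per_mm=px_per_mm,
            margin_px=STUDY_MARGIN_PX,
            noise_sd=noise_sd,
            seed=seed_i,
        )
        mech = synthetic.ZoneMechanicsSpec(systolic_strain_by_zone=strains)
        dia, sys_ = synthetic.generate_beat_pair(spec, mech)
        partition = default_partition(spec.wound_center_mm, spec.length_mm)
        res = analyze_beat(
            dia, sys_, px_per_mm, dic_params=dic_params, partition=partition
        )
        rows.append({"sample": i, **res.zone_strain})
    return pd.DataFrame(rows).set_index("sample")


def intensity_replicates(
    n: int = 10,
    base_seed: int = 0,
    reductions: Optional[Mapping[str, float]] = None,
    noise_sd: float = 0.02,
    px_per_mm: float = 50.0,
    channels: Sequence[str] = ("fibroblast", "cardiomyocyte"),
    edge_band_px: int = 10,
) -> pd.DataFrame:
    """Recovered fold-changes for a cohort of synthetic fluorescence maps.

    Returns a long table (sample, channel, zone columns) of estimated
    fold-changes versus each sample's own prewound maps.
    """
    red = dict(reductions or DEFAULT_REDUCTIONS)
    per_channel = {ch: red for ch in channels}
    rows = []
    for i in range(n):
        seed_i = child_seed(base_seed, 0x1F, i)
        spec = synthetic.SyntheticTissueSpec(
            px_per_mm=px_per_mm, noise_sd=noise_sd, seed=seed_i
        )
        pre_spec = replace(spec, seed=child_seed(base_seed, 0x2F, i))
        mech = synthetic.ZoneMechanicsSpec(
            density_reduction_by_zone_channel=per_channel
        )
        pre_mech = synthetic.ZoneMechanicsSpec(
            density_reduction_by_zone_channel={
                ch: {z: 0.0 for z in ZONES} for ch in channels
            }
        )
        imgs = synthetic.generate_fluorescence_maps(
            spec, mech, edge_band_px=edge_band_px
        )
        pre_imgs = synthetic.generate_fluorescence_maps(
            pre_spec, pre_mech, edge_band_px=edge_band_px
        )
        mask = synthetic.tissue_mask(spec)
        partition = default_partition(spec.wound_center_mm, spec.length_mm)
        res = analyze_intensity(
            imgs,
            pre_imgs,
            px_per_mm,
            partition=partition,
            mask=mask,
            prewound_mask=mask,
            edge_band_px=edge_band_px,
        )
        for ch in channels:
            rows.append(
                {"sample": i, "channel": ch, **res.fold_change.loc[ch].to_dict()}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation study


def validate(seed: int = 0) -> Dict[str, float]:
    """Quick self-test asserting the module-level recovery properties.

    Runs reduced versions of the parameter-recovery checks on freshly
    generated synthetic data and returns the measured quantities
    together with an overall ``ok`` flag.
    """
    report: Dict[str, float] = {}
    spec = synthetic.SyntheticTissueSpec(seed=seed)
    a = synthetic.generate_speckle(spec)
    b = synthetic.generate_speckle(spec)
    report["speckle_deterministic"] = float(np.array_equal(a, b))

    # translation recovery
    from .dic import DicParams as _DP

    u = np.full(a.shape, 3.0)
    v = np.zeros(a.shape)
    shifted = synthetic.warp_image(a.astype(float), u, v)
    disp = track_displacements(a, shifted, _DP(search_px=8), synthetic.tissue_mask(spec))
    report["dic_translation_error_px"] = float(
        np.nanmax(np.abs(disp.u[disp.valid] - 3.0))
    )

    # geometry identity
    from .geometry import interpolate_geometry

    geo = interpolate_geometry(4.0, (4.0, 4.0), np.linspace(0, 4, 21), 4.0)
    report["csa_uncompacted_mm2"] = float(geo.csa_mm2[0])
    report["csa_identity_max_err"] = float(
        np.max(np.abs(geo.csa_mm2 - geo.width_mm**2 * 3.25 / 4.0))
    )

    # modulus recovery, noise-free
    res = ramp_recovery_study(seed=seed)
    for z in ZONES:
        report[f"modulus_{z}_kPa"] = res.zone_moduli[z]
    report["modulus_max_rel_err"] = float(
        max(
            abs(res.zone_moduli[z] - DEFAULT_MODULI[z]) / DEFAULT_MODULI[z]
            for z in ZONES
        )
    )

    # fold-change recovery, single replicate
    fc = intensity_replicates(n=1, base_seed=seed)
    report["fold_change_wound"] = float(fc["wound"].mean())
    report["fold_change_remote"] = float(fc["remote"].mean())

    ok = (
        report["speckle_deterministic"] == 1.0
        and report["dic_translation_error_px"] < 0.1
        and report["csa_identity_max_err"] < 1e-12
        and report["modulus_max_rel_err"] < 0.10
        and abs(report["fold_change_wound"] + 0.40) < 0.05
    )
    report["ok"] = float(ok)
    return report


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: RunConfig, study: str) -> Dict:
    """Run one of the end-to-end studies and write its output tables.

    Outputs are tidy CSVs with a YAML sidecar recording the full
    configuration and its hash; a run with the same configuration and
    seed produces byte-identical outputs.
    """
    out = Path(config.out_dir)
    meta = {"seed": config.seed, "config_hash": config.hash, "study": study}

    if study == "validate":
        report = validate(config.seed)
        write_table(
            pd.DataFrame([{"metric": k, "value": v} for k, v in report.items()]),
            out / "validate_report.csv",
            meta,
        )
        write_yaml(config.to_dict(), out / "run_config.yaml")
        if not report["ok"]:
            raise AnalysisError("validation study failed; see validate_report.csv")
        return report

    if study == "stiffness":
        config.require_paths("frames", "protocol")
        frames = read_frames(config.frames)
        protocol = read_table(config.protocol)
        partition = None
        if config.wound_center_mm is not None:
            cols_mask = segment_tissue(np.asarray(frames[0], float)).any(axis=0)
            cols = np.flatnonzero(cols_mask)
            length_mm = (cols[-1] - cols[0] + 1) / config.px_per_mm
            partition = default_partition(
                config.wound_center_mm, length_mm, **config.partition
            )
        res = analyze_ramp(
            frames,
            protocol,
            config.px_per_mm,
            dic_params=config.dic_params(),
            partition=partition,
            calibration=config.force_calibration(),
            band_mm=config.band_mm,
            binning=config.binning,
            n_bins=config.n_bins,
        )
        write_table(res.geometry.to_frame(), out / "geometry.csv", meta)
        write_table(res.series, out / "stress_strain.csv", meta)
        moduli = pd.DataFrame(
            [
                {
                    "subregion": i,
                    "zone": res.subregion_zones[i],
                    "modulus_kPa": f.modulus_kPa,
                    "r2": f.r2,
                    "n_bins_occupied": f.n_bins_occupied,
                    "flag": f.flag,
                }
                for i, f in res.fits.items()
            ]
        )
        write_table(moduli, out / "subregion_moduli.csv", meta)
        write_table(
            pd.DataFrame([res.zone_moduli]), out / "zone_moduli.csv", meta
        )
        write_yaml(config.to_dict(), out / "run_config.yaml")
        return {"zone_moduli": res.zone_moduli}

    if study == "systolic":
        config.require_paths("frames")
        frames = read_frames(config.frames)
        res = analyze_beat_sequence(
            frames,
            config.px_per_mm,
            pacing_hz=config.pacing_hz,
            fps=config.fps,
            dic_params=config.dic_params(),
            band_mm=config.band_mm,
            central_fraction=config.central_fraction,
        )
        write_table(res.profile.to_frame(), out / "strain_profile.csv", meta)
        write_table(
            pd.DataFrame(
                [
                    {
                        **res.zone_strain,
                        "systole_idx": res.systole_idx,
                        "diastole_idx": res.diastole_idx,
                    }
                ]
            ),
            out / "zone_strain.csv",
            meta,
        )
        write_yaml(config.to_dict(), out / "run_config.yaml")
        return {"zone_strain": res.zone_strain}

    if study == "intensity":
        config.require_paths("channels", "prewound_channels")
        images = {
            ch: read_frames(p)[0] for ch, p in (config.channels or {}).items()
        }
        pre = {
            ch: read_frames(p)[0]
            for ch, p in (config.prewound_channels or {}).items()
        }
        res = analyze_intensity(
            images,
            pre,
            config.px_per_mm,
            edge_band_px=config.edge_band_px,
            edge_mode=config.edge_mode,
        )
        trace_frames = [t.to_frame() for t in res.traces.values()]
        write_table(pd.concat(trace_frames, ignore_index=True), out / "traces.csv", meta)
        write_table(res.auc.reset_index(), out / "regional_auc.csv", meta)
        write_table(
            res.fold_change.reset_index(), out / "fold_change.csv", meta
        )
        write_yaml(config.to_dict(), out / "run_config.yaml")
        return {"fold_change": res.fold_change.to_dict()}

    raise ParameterError(f"unknown study {study!r}")
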