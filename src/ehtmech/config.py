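"""Run configuration for the end-to-end analyses."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

from .dic import DicParams
from .exceptions import ParameterError
from .io import config_hash, read_yaml
from .mechanics import ForceCalibration


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML.

    Paths are study-specific: ``frames``/``protocol`` for the stiffness
    ramp, ``frames`` for the systolic study, ``channels`` and
    ``prewound_channels`` (role -> image path) for the intensity study.
    The seed drives every source of randomness and is recorded, with
    the configuration hash, in the header of every output table.
    """

    frames: Optional[str] = None
    protocol: Optional[str] = None
    channels: Optional[Dict[str, str]] = None
    prewound_channels: Optional[Dict[str, str]] = None
    px_per_mm: float = 150.0
    pacing_hz: float = 1.0
    fps: float = 60.0
    wound_center_mm: Optional[float] = None
    band_mm: float = 0.5
    central_fraction: float = 0.9
    edge_band_px: int = 10
    edge_mode: str = "fixed_end"
    binning: str = "strain"
    n_bins: int = 7
    alpha: float = 0.05
    dic: Dict = field(default_factory=dict)
    calibration: Dict = field(default_factory=dict)
    partition: Dict = field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = read_yaml(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> Dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    def dic_params(self) -> DicParams:
        return DicParams(**self.dic)

    def force_calibration(self) -> ForceCalibration:
        cal = dict(self.calibration)
        if "coefficients" in cal:
            cal["coefficients"] = tuple(cal["coefficients"])
        return ForceCalibration(**cal)

    def require_paths(self, *names: str) -> None:
        """Fail before any computation if a study input is missing."""
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ParameterError(f"config field {name!r} is required")
            if isinstance(value, str) and not Path(value).exists():
                raise ParameterError(f"{name} path does not exist: {value}")
            if isinstance(value, dict):
                for role, p in value.items():
                    if not Path(p).exists():
                        raise ParameterError(
                            f"{name}[{role!r}] path does not exist: {p}"
                        )
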