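"""Configuration objects for the virtual environment and the BOLD simulator.

The defaults describe the passive-navigation task the pipeline is built to
analyze: a 160 x 160 virtual-meter (vm) room traversed at 15 vm/s with 50 deg/s
rotations, 112 translation segments balanced over 10-degree direction bins,
620 s runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Tuple

import yaml


@dataclass
class EnvironmentConfig:
    """Geometry and schedule of the passive-navigation task.

    Lengths are in virtual meters (vm), durations in seconds, angles in
    degrees.  ``coverage_cone_width`` is the FULL angular width of the
    forward coverage cone (+-width/2 about the heading).
    """

    room_side: float = 160.0
    translation_speed: float = 15.0
    rotation_speed: float = 50.0
    run_length: float = 620.0
    n_segments: int = 112
    bin_width: float = 10.0
    coverage_radius: float = 3.0
    coverage_cone_length: float = 8.0
    coverage_cone_width: float = 65.0
    min_rotation: float = 10.0
    max_rotation: float = 170.0
    segment_length_range: Tuple[float, float] = (25.0, 85.0)
    margin: float = 5.0

    def __post_init__(self) -> None:
        if self.room_side <= 0:
            raise ValueError("room_side must be positive")
        if abs(360.0 / self.bin_width - round(360.0 / self.bin_width)) > 1e-9:
            raise ValueError("bin_width must divide 360 degrees evenly")
        if not (0.0 < self.min_rotation <= self.max_rotation < 180.0):
            raise ValueError(
                "rotation limits must satisfy 0 < min_rotation <= max_rotation < 180"
            )
        lo, hi = self.segment_length_range
        if not (0.0 < lo <= hi):
            raise ValueError("segment_length_range must be 0 < min <= max")
        if self.n_segments < self.n_bins:
            raise ValueError("need at least one segment per direction bin")
        if 2.0 * self.margin >= self.room_side:
            raise ValueError("margin leaves no interior room")

    @property
    def n_bins(self) -> int:
        return int(round(360.0 / self.bin_width))


@dataclass
class SimulationConfig:
    """Generative model for one simulated BOLD run.

    Every voxel carries a k-fold directional modulation: during a translation
    with allocentric direction phi the neural signal is
    ``amplitude * cos(k * (phi - theta_v))`` where the voxel orientation
    theta_v is drawn around ``group_orientation`` with von Mises concentration
    ``orientation_concentration`` in k-fold angle space
    (``orientation_concentration=None`` plants theta_v = group_orientation
    exactly).  The neural boxcar is convolved with a canonical double-gamma
    HRF, then baseline, linear drift and AR(1) Gaussian noise are added.
    """

    fold: int = 6
    group_orientation: float = 15.0
    orientation_concentration: Optional[float] = 8.0
    modulation_amplitude: float = 0.5
    n_voxels: int = 48
    tr: float = 1.0
    baseline: float = 100.0
    drift_slope: float = 0.01
    noise_sd: float = 1.0
    ar1_coefficient: float = 0.3
    orientation_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("fold must be a positive integer")
        kappa = self.orientation_concentration
        if kappa is not None and kappa < 0:
            raise ValueError("orientation_concentration must be >= 0 (or None)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not abs(self.ar1_coefficient) < 1:
            raise ValueError("|ar1_coefficient| must be < 1 for stationarity")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")

    @property
    def period(self) -> float:
        """Fundamental angular domain width, 360/k degrees."""
        return 360.0 / self.fold


def _from_mapping(cls, mapping):
    known = {f for f in cls.__dataclass_fields__}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    if "segment_length_range" in kwargs:
        kwargs["segment_length_range"] = tuple(kwargs["segment_length_range"])
    return cls(**kwargs)


def load_config(path, cls=EnvironmentConfig):
    """Read a YAML/JSON mapping into a config dataclass."""
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh) or {}
    return _from_mapping(cls, mapping)


def dump_config(cfg, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_serializable(asdict(cfg)), fh, sort_keys=False)


def _serializable(obj):
    if isinstance(obj, dict):
        return {k: _serializable(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_serializable(v) for v in obj]
    return obj
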