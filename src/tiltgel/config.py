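"""Structured configuration for the gel-scan analysis pipeline.

All tunable parameters of the acquisition geometry, simulator, detection
and profiling stages live in small validated dataclasses.  A full
:class:`PipelineConfig` round-trips losslessly through YAML so that one
config file is the artifact of record for a run.

Conventions honored by every module: 0-based pixel indices, half-open
intervals, and a projected axis that increases with migration distance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "OpticsConfig",
    "NoiseConfig",
    "LaneGeometry",
    "BandSpec",
    "ImpuritySpec",
    "CropSpec",
    "DetectionConfig",
    "BinningConfig",
    "PCAConfig",
    "LaneConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
]


class ParameterError(ValueError):
    """A configuration value violates its documented constraint."""


@dataclass
class OpticsConfig:
    """Acquisition geometry of the tilted light-sheet scan.

    Defaults are the instrument settings of the profiling system this
    package models: optical slices tilted 33.8 degrees from the gel
    plane, a 10.73 um stage step along the electrophoresis axis, 0.8 um
    pixels and 512 x 512 16-bit frames.
    """

    tilt_deg: float = 33.8
    step_um: float = 10.73
    pixel_um: float = 0.8
    frame_shape: tuple[int, int] = (512, 512)
    #: detectable thickness of the illuminated slice; the instrument's
    #: section spacing (~6 um) is comparable to it.
    slab_thickness_um: float = 6.0
    #: Gaussian spot scale of a rendered single molecule, in pixels.
    psf_sigma_px: float = 0.5
    bit_depth_max: int = 65535

    def __post_init__(self) -> None:
        if not 0.0 < self.tilt_deg < 90.0:
            raise ParameterError(f"tilt_deg must lie in (0, 90), got {self.tilt_deg}")
        for name in ("step_um", "pixel_um", "slab_thickness_um", "psf_sigma_px"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        self.frame_shape = tuple(int(v) for v in self.frame_shape)  # type: ignore[assignment]
        if len(self.frame_shape) != 2 or any(v <= 0 for v in self.frame_shape):
            raise ParameterError(f"frame_shape must be two positive ints, got {self.frame_shape}")


@dataclass
class NoiseConfig:
    """EM-CCD-style camera noise: Poisson(signal + background) shot noise
    plus Gaussian read noise, then integer quantization."""

    background: float = 100.0
    read_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.background < 0 or self.read_sd < 0:
            raise ParameterError("noise parameters must be non-negative")


@dataclass
class LaneGeometry:
    """Layout of one simulated lane inside the camera frame.

    The lane's migration origin (the bead pellet position) is stage
    position 0 by definition; ``interface_*_px`` give the row of the
    gel/glass interface in the first and last frame (the line drifts
    linearly between them, emulating slow sample movement).
    """

    n_frames: int = 150
    lane_width_um: float = 200.0
    #: molecules are suspended in the gel between these depths (um above
    #: the glass); the imaged crop accommodates depths up to ~60 um.
    depth_min_um: float = 5.0
    depth_max_um: float = 45.0
    width_offset_px: int = 100
    interface_start_px: float = 8.0
    interface_end_px: float = 12.0
    interface_intensity: float = 30000.0
    #: the bright interface scatter sits on the glass side of the
    #: gel/glass boundary, this many rows above the gel window.
    line_clearance_px: float = 5.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.lane_width_um <= 0:
            raise ParameterError("lane_width_um must be > 0")
        if not 0 <= self.depth_min_um < self.depth_max_um:
            raise ParameterError("depth range must satisfy 0 <= min < max")


@dataclass
class BandSpec:
    """One electrophoretic band of labeled molecules.

    ``center_um``/``width_um`` are the mean and SD of a Gaussian along
    the migration axis; the number of molecules is Poisson with mean
    ``expected_count``; peak brightness is Normal(mean, sd) clipped > 0.
    """

    center_um: float
    width_um: float
    expected_count: float
    brightness_mean: float = 6000.0
    brightness_sd: float = 1000.0

    def __post_init__(self) -> None:
        if self.center_um < 0:
            raise ParameterError("center_um must be >= 0")
        if self.width_um <= 0:
            raise ParameterError("width_um must be > 0")
        if self.expected_count < 0:
            raise ParameterError(f"expected_count must be >= 0, got {self.expected_count}")


@dataclass
class ImpuritySpec:
    """Bright, oversized artifacts (aggregates, bubbles, dust).

    Ranges are drawn uniformly; the defaults violate both downstream
    filter rules (intensity > 15000 and diameter > 2 px) so every
    injected impurity must be removed by the spot filters.
    """

    count: int = 5
    intensity_range: tuple[float, float] = (20000.0, 40000.0)
    diameter_range: tuple[float, float] = (2.5, 4.0)

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ParameterError("count must be >= 0")
        for name in ("intensity_range", "diameter_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ParameterError(f"{name} must be ordered (low, high)")


@dataclass
class CropSpec:
    """Gel-region crop window applied to every frame.

    The vertical offset is interpolated linearly between the interface
    heights measured at the first and last frame.
    """

    height_px: int = 150
    width_px: int = 312
    start_height_px: float = 0.0
    end_height_px: float = 0.0
    width_offset_px: int = 0
    allowed_widths: tuple[int, ...] = (312, 412)

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ParameterError("crop dimensions must be positive")
        if self.allowed_widths and self.width_px not in self.allowed_widths:
            raise ParameterError(
                f"width_px={self.width_px} not in allowed set {self.allowed_widths}"
            )


@dataclass
class DetectionConfig:
    """Blob detection and impurity-filter parameters.

    One DetectionConfig applies to all lanes of a gel scan (the
    detection threshold is a per-scan choice, never per-lane).  The
    default ``log_threshold`` was calibrated on simulated scans; for
    real data it should be set by inspecting overlays.
    """

    min_sigma_px: float = 0.4
    max_sigma_px: float = 1.5
    n_sigma_steps: int = 10
    log_threshold: float = 150.0
    overlap: float = 0.5
    intensity_max: float = 15000.0
    diameter_max_px: float = 2.0

    def __post_init__(self) -> None:
        if self.min_sigma_px <= 0 or self.min_sigma_px > self.max_sigma_px:
            raise ParameterError("need 0 < min_sigma_px <= max_sigma_px")
        if self.n_sigma_steps < 1:
            raise ParameterError("n_sigma_steps must be >= 1")
        if self.log_threshold < 0:
            raise ParameterError("log_threshold must be >= 0")

    def sigma_ladder(self) -> "list[float]":
        import numpy as np

        return list(np.linspace(self.min_sigma_px, self.max_sigma_px, self.n_sigma_steps))


@dataclass
class BinningConfig:
    """Migration-profile binning and smoothing.

    20-px bins are 16 um at the default 0.8 um/px; smoothing is a
    5-bin centered moving average.
    """

    bin_width_px: int = 20
    smooth_window: int = 5
    n_bins: int | None = None
    #: "auto" finds the trailing edge of the full-length antibody peak,
    #: "manual" uses cutoff_um verbatim, "none" keeps every bin.
    cutoff_mode: str = "auto"
    cutoff_um: float | None = None
    search_window_um: tuple[float, float] = (2500.0, 4500.0)
    cutoff_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.bin_width_px < 1:
            raise ParameterError("bin_width_px must be >= 1")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ParameterError("smooth_window must be an odd positive integer")
        if self.cutoff_mode not in ("auto", "manual", "none"):
            raise ParameterError(f"unknown cutoff_mode {self.cutoff_mode!r}")
        if self.cutoff_mode == "manual" and self.cutoff_um is None:
            raise ParameterError("manual cutoff_mode requires cutoff_um")


@dataclass
class PCAConfig:
    n_components: int = 3

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ParameterError("n_components must be >= 1")


@dataclass
class LaneConfig:
    """One lane of a scan: where its frames live and how to crop them."""

    lane_id: str
    path: str
    crop: CropSpec = field(default_factory=CropSpec)
    condition_label: str = ""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    lanes: list[LaneConfig] = field(default_factory=list)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    pca: PCAConfig = field(default_factory=PCAConfig)
    shift_px: int = 11
    use_geometric_shift: bool = False
    background_radius_px: int = 25
    out_dir: str = "tiltgel_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return _asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _from_dict(cls, data)


def _asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_asdict(v) for v in obj]
    if isinstance(obj, list):
        return [_asdict(v) for v in obj]
    return obj


def _from_dict(cls: type, data: Any) -> Any:
    if not dataclasses.is_dataclass(cls):
        return data
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        ftype = f.type if isinstance(f.type, str) else getattr(f.type, "__name__", "")
        if f.name == "lanes":
            value = [_from_dict(LaneConfig, v) for v in value]
        elif f.name == "crop":
            value = _from_dict(CropSpec, value)
        elif f.name in ("optics", "detection", "binning", "pca"):
            sub = {"optics": OpticsConfig, "detection": DetectionConfig,
                   "binning": BinningConfig, "pca": PCAConfig}[f.name]
            value = _from_dict(sub, value)
        elif isinstance(value, list) and ("tuple" in str(ftype) or f.name in
                                          ("frame_shape", "intensity_range", "diameter_range",
                                           "allowed_widths", "search_window_um")):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialize a pipeline configuration to YAML (lossless round-trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
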