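"""Acquisition geometry, timing schedule, and the flying-focal-spot source model.

The scanner sweeps an X-ray source on a circular arc above a stationary
flat-panel detector while pulsing a configurable number of projections.
Coordinate frame: x = tube-travel direction, y = chest-wall-to-nipple,
z = height above the breast support table; the detector lies in the plane
z = 0 with its center at the origin.  Millimeters throughout; angles are
degrees at the API and radians internally.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "FocalSpotModel",
    "AcquisitionGeometry",
    "ScheduleSummary",
    "make_geometry",
    "acquisition_schedule",
    "source_position",
    "magnification",
    "MODE_DEFAULTS",
]

#: Published acquisition-mode parameter sets (fast / moderate_fast).
MODE_DEFAULTS = {
    "fast": dict(
        n_projections=25,
        angular_range_deg=50.0,
        acquisition_time_s=4.8,
        pulse_length_ms=40.0,
        readout_time_ms=150.0,
    ),
    "moderate_fast": dict(
        n_projections=25,
        angular_range_deg=50.0,
        acquisition_time_s=8.1,
        pulse_length_ms=68.0,
        readout_time_ms=150.0,
    ),
}

_COMMON_DEFAULTS = dict(
    source_to_detector_mm=650.0,
    rotation_center_height_mm=0.0,
    detector_pixel_pitch_mm=0.085,
    detector_shape=(128, 256),
)


@dataclass(frozen=True)
class FocalSpotModel:
    """Finite focal spot with optional flying-focal-spot (FFS) deflection.

    With FFS enabled, the spot is deflected along the anode track during
    each pulse so that the effective source position is stationary with
    respect to breast and detector.  The deflected spot size shrinks
    linearly with the deflection angle (coefficient 0 by default).
    """

    nominal_size_mm: float = 0.3
    ffs_enabled: bool = False
    deflection_shrink_coeff: float = 0.0

    def __post_init__(self) -> None:
        if self.nominal_size_mm <= 0:
            raise ConfigurationError("focal_spot.nominal_size_mm must be > 0")
        if self.deflection_shrink_coeff < 0:
            raise ConfigurationError("focal_spot.deflection_shrink_coeff must be >= 0")

    def effective_size_mm(self, deflection_deg: float) -> float:
        """Spot extent in the travel direction at a given deflection angle."""
        s = self.nominal_size_mm * (1.0 - self.deflection_shrink_coeff * abs(deflection_deg))
        return max(s, 0.0)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """One scan mode: trajectory, detector, timing and focal-spot model."""

    n_projections: int = 25
    angular_range_deg: float = 50.0
    acquisition_time_s: float = 4.8
    pulse_length_ms: float = 40.0
    readout_time_ms: float = 150.0
    source_to_detector_mm: float = 650.0
    rotation_center_height_mm: float = 0.0
    detector_pixel_pitch_mm: float = 0.085
    detector_shape: tuple = (128, 256)
    focal_spot: FocalSpotModel = field(default_factory=FocalSpotModel)
    mode_name: str = "fast"

    def __post_init__(self) -> None:
        if self.n_projections < 1:
            raise ConfigurationError("n_projections must be >= 1")
        if not (0.0 < self.angular_range_deg < 180.0):
            raise ConfigurationError("angular_range_deg must lie in (0, 180)")
        if self.acquisition_time_s <= 0:
            raise ConfigurationError("acquisition_time_s must be > 0")
        frame_period_ms = 1000.0 * self.acquisition_time_s / max(self.n_projections - 1, 1)
        if self.pulse_length_ms > frame_period_ms:
            raise ConfigurationError(
                "pulse_length_ms exceeds the per-frame time budget "
                f"({self.pulse_length_ms} > {frame_period_ms:.3f} ms)"
            )
        if self.detector_pixel_pitch_mm <= 0:
            raise ConfigurationError("detector_pixel_pitch_mm must be > 0")
        if self.rotation_center_height_mm < 0:
            raise ConfigurationError("rotation_center_height_mm must be >= 0")
        if self.source_to_detector_mm <= self.rotation_center_height_mm:
            raise ConfigurationError(
                "source_to_detector_mm must exceed rotation_center_height_mm"
            )
        if self.pulse_length_ms + self.readout_time_ms > frame_period_ms:
            warnings.warn(
                "pulse + readout exceed the frame period; timing is tight",
                stacklevel=2,
            )

    @property
    def arc_radius_mm(self) -> float:
        return self.source_to_detector_mm - self.rotation_center_height_mm

    @property
    def angular_speed_deg_s(self) -> float:
        return self.angular_range_deg / self.acquisition_time_s

    def to_json(self) -> str:
        d = asdict(self)
        d["detector_shape"] = list(self.detector_shape)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AcquisitionGeometry":
        return make_geometry(json.loads(text))


@dataclass(frozen=True)
class ScheduleSummary:
    """Derived per-view timing/angle schedule for one geometry."""

    frames_per_second: float
    angular_speed_deg_s: float
    angular_spacing_deg: float
    view_center_times_s: np.ndarray
    view_center_angles_deg: np.ndarray


def make_geometry(config: dict | None = None) -> AcquisitionGeometry:
    """Build a validated :class:`AcquisitionGeometry` from a plain mapping.

    Missing values are filled from the fast-mode defaults (or from the
    ``mode_name`` requested in the config); unknown keys are rejected.
    """
    config = dict(config or {})
    mode = config.pop("mode_name", "fast")
    if mode not in MODE_DEFAULTS:
        raise ConfigurationError(
            f"mode_name must be one of {sorted(MODE_DEFAULTS)}, got {mode!r}"
        )
    values = dict(MODE_DEFAULTS[mode])
    values.update(_COMMON_DEFAULTS)
    values["focal_spot"] = FocalSpotModel()
    known = set(values)
    unknown = set(config) - known
    if unknown:
        raise ConfigurationError(f"unknown geometry keys: {sorted(unknown)}")
    fs = config.pop("focal_spot", None)
    values.update(config)
    if fs is not None:
        values["focal_spot"] = fs if isinstance(fs, FocalSpotModel) else FocalSpotModel(**fs)
    if "detector_shape" in values:
        values["detector_shape"] = tuple(int(v) for v in values["detector_shape"])
    try:
        return AcquisitionGeometry(mode_name=mode, **values)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigurationError(str(exc)) from exc


def acquisition_schedule(geom: AcquisitionGeometry) -> ScheduleSummary:
    """Per-view center times and gantry angles, plus summary rates.

    Views are pulsed at evenly spaced times starting at 0 and the gantry
    angles span [-theta/2, +theta/2] symmetrically; a single-projection
    scan degenerates to one view at 0 deg with zero rates.
    """
    n = geom.n_projections
    if n == 1:
        return ScheduleSummary(
            frames_per_second=0.0,
            angular_speed_deg_s=0.0,
            angular_spacing_deg=0.0,
            view_center_times_s=np.array([0.0]),
            view_center_angles_deg=np.array([0.0]),
        )
    half = geom.angular_range_deg / 2.0
    angles = np.linspace(-half, half, n)
    times = np.linspace(0.0, geom.acquisition_time_s, n)
    return ScheduleSummary(
        frames_per_second=(n - 1) / geom.acquisition_time_s,
        angular_speed_deg_s=geom.angular_speed_deg_s,
        angular_spacing_deg=geom.angular_range_deg / (n - 1),
        view_center_times_s=times,
        view_center_angles_deg=angles,
    )


def view_angle_deg(geom: AcquisitionGeometry, view_index: int, tau: float = 0.0) -> float:
    """Instantaneous gantry angle of a view at in-pulse offset ``tau``.

    ``tau`` is a fraction of the pulse window in [-0.5, +0.5].  With FFS
    enabled the focal-spot deflection exactly cancels the gantry motion
    within the pulse, so the effective angle is constant over tau.
    """
    if not (0 <= view_index < geom.n_projections):
        raise DomainError(f"view_index {view_index} out of range")
    if not (-0.5 <= tau <= 0.5):
        raise DomainError("tau must lie in [-0.5, 0.5]")
    sched = acquisition_schedule(geom)
    angle = float(sched.view_center_angles_deg[view_index])
    if geom.focal_spot.ffs_enabled or geom.n_projections == 1:
        return angle
    return angle + geom.angular_speed_deg_s * tau * (geom.pulse_length_ms / 1000.0)


def source_position(
    geom: AcquisitionGeometry, view_index: int, tau: float = 0.0
) -> np.ndarray:
    """3-D focal-spot position (mm) for a view at in-pulse offset ``tau``.

    The source travels on a circular arc of radius SID - rotation_center
    about the rotation center; the arc lies in the x-z plane (y = 0).
    """
    angle = math.radians(view_angle_deg(geom, view_index, tau))
    r = geom.arc_radius_mm
    zc = geom.rotation_center_height_mm
    return np.array([r * math.sin(angle), 0.0, zc + r * math.cos(angle)])


def magnification(geom: AcquisitionGeometry, height_mm: float) -> float:
    """Central-view geometric magnification M(h) = SID / (SID - h)."""
    sid = geom.source_to_detector_mm
    if not (0.0 <= height_mm < sid):
        raise DomainError(f"height_mm must lie in [0, SID={sid}), got {height_mm}")
    return sid / (sid - height_mm)
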