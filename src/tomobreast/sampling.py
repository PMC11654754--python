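"""k-space fill analysis and the native-slice-thickness relation.

A limited-angle sweep of theta degrees samples only a wedge of Fourier
orientations.  For an in-plane frequency f the available z-frequency
extent is F_z = f * tan(theta/2), and the native slice thickness —
the finest slice separation at which adjacent slices carry distinct
information at that frequency — is d(f) = 1 / (2 * f * tan(theta/2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "SamplingSpec",
    "native_slice_thickness",
    "z_frequency_coverage",
    "kspace_mask",
]


@dataclass(frozen=True)
class SamplingSpec:
    angular_range_deg: float
    n_projections: int
    in_plane_frequency_lpmm: float
    native_slice_thickness_mm: float
    z_frequency_extent_lpmm: float


def _check(f_lpmm: float, theta_deg: float) -> None:
    if f_lpmm <= 0:
        raise DomainError("in-plane frequency must be > 0 (d diverges as f -> 0)")
    if not (0.0 < theta_deg < 180.0):
        raise DomainError("angular range must lie in (0, 180) degrees")


def native_slice_thickness(f_lpmm: float, theta_deg: float) -> float:
    """d(f, theta) = 1 / (2 f tan(theta/2)) in mm; decreasing in f and theta."""
    _check(f_lpmm, theta_deg)
    return 1.0 / (2.0 * f_lpmm * math.tan(math.radians(theta_deg) / 2.0))


def z_frequency_coverage(f_lpmm: float, theta_deg: float) -> float:
    """F_z(f, theta) = f tan(theta/2) in lp/mm; satisfies F_z = 1/(2 d) exactly."""
    _check(f_lpmm, theta_deg)
    return f_lpmm * math.tan(math.radians(theta_deg) / 2.0)


def sampling_spec(f_lpmm: float, theta_deg: float, n_projections: int) -> SamplingSpec:
    return SamplingSpec(
        angular_range_deg=theta_deg,
        n_projections=n_projections,
        in_plane_frequency_lpmm=f_lpmm,
        native_slice_thickness_mm=native_slice_thickness(f_lpmm, theta_deg),
        z_frequency_extent_lpmm=z_frequency_coverage(f_lpmm, theta_deg),
    )


def kspace_mask(
    theta_deg: float,
    n_projections: int,
    grid: tuple[int, int] = (512, 512),
    f_max_lpmm: float = 5.0,
    line_half_width_cells: float = 0.5,
) -> np.ndarray:
    """Binary map of the Fourier cells sampled by the projection set.

    Each projection contributes a central-slice line through the origin of
    the (f_x, f_z) plane at its view angle; a cell is marked when its
    center lies within ``line_half_width_cells`` cells of any such line.
    This is a QC/pedagogical artifact; the reconstructor does not use it.
    """
    if not (0.0 < theta_deg < 180.0):
        raise DomainError("angular range must lie in (0, 180) degrees")
    if n_projections < 1:
        raise DomainError("n_projections must be >= 1")
    n_fx, n_fz = grid
    if n_fx < 3 or n_fz < 3:
        raise DomainError("grid dims must be >= 3")
    fx = np.linspace(-f_max_lpmm, f_max_lpmm, n_fx)
    fz = np.linspace(-f_max_lpmm, f_max_lpmm, n_fz)
    FX, FZ = np.meshgrid(fx, fz, indexing="ij")
    cell = 2.0 * f_max_lpmm / (min(n_fx, n_fz) - 1)
    tol = line_half_width_cells * cell
    if n_projections == 1:
        angles = np.array([0.0])
    else:
        half = theta_deg / 2.0
        angles = np.linspace(-half, half, n_projections)
    mask = np.zeros(grid, dtype=bool)
    for a in np.radians(angles):
        # distance of each cell center from the line through the origin
        # tilted by the view angle (line direction perpendicular to the ray)
        dist = np.abs(FZ * math.cos(a) - FX * math.sin(a))
        mask |= dist <= tol
    return mask
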