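"""Canonical desk-scale experiments reused by the CLI, the test suite, and
the acceptance report: wire eMTF simulations, the reference clip phantom,
and the microcalcification-cluster phantom.  All knobs default to sizes
that run in seconds-to-minutes on one CPU; everything is seeded.
"""

from __future__ import annotations

import numpy as np

from .artifact_reduction import masked_backproject, remove_objects, segment_objects
from .geometry import AcquisitionGeometry, FocalSpotModel, make_geometry
from .metrics import MTFCurve, artifact_metrics, emtf_from_wire
from .phantoms import AIR, InsertSpec, VoxelPhantom, add_insert, build_slab_phantom
from .projector import add_counting_noise, forward_project, to_line_integrals
from .reconstruction import backproject_perspective, ramp_filter

__all__ = [
    "wire_phantom",
    "simulate_wire_emtf",
    "clip_phantom_experiment",
    "calc_cluster_experiment",
]


def wire_phantom(
    height_mm: float,
    tilt_deg: float = 3.0,
    wire_material: str = "Rh",
    diameter_mm: float = 0.025,
    x_extent_mm: float = 3.0,
    y_extent_mm: float = 8.0,
) -> VoxelPhantom:
    """Thin tilted wire in a single air layer at the stated height.

    In-plane voxels are far sub-pixel (0.02 mm along travel) so the wire
    approximates a line stimulus for LSF measurement.
    """
    dx, dy, dz = 0.02, 0.1, 0.1
    nx = int(x_extent_mm / dx)
    ny = int(y_extent_mm / dy)
    ids = np.zeros((nx, ny, 1), np.uint8)
    ph = VoxelPhantom(
        material_ids=ids,
        materials=(AIR,),
        voxel_size_mm=(dx, dy, dz),
        origin_mm=(-(nx - 1) / 2.0 * dx, -(ny - 1) / 2.0 * dy, height_mm),
        thickness_mm=dz,
    )
    return add_insert(
        ph,
        InsertSpec(
            kind="wire",
            position_mm=(0.0, 0.0, height_mm),
            material=wire_material,
            tilt_deg=tilt_deg,
            diameter_mm=diameter_mm,
        ),
    )


def wire_geometry(
    ffs: bool,
    height_mm: float,
    mode: str = "fast",
    rows: int = 64,
    n_projections: int | None = None,
    focal_spot_mm: float = 0.3,
) -> AcquisitionGeometry:
    """Geometry whose detector is wide enough to catch the wire shadow
    parallax at the given height in every view."""
    base = make_geometry({"mode_name": mode})
    sid = base.source_to_detector_mm
    half_sweep = np.radians(base.angular_range_deg / 2.0)
    max_shift = sid * np.sin(half_sweep) * height_mm / (sid - height_mm)
    cols = int(2 * (max_shift + 6.0) / base.detector_pixel_pitch_mm)
    cfg = {
        "mode_name": mode,
        "detector_shape": (rows, cols),
        "focal_spot": FocalSpotModel(nominal_size_mm=focal_spot_mm, ffs_enabled=ffs),
    }
    if n_projections is not None:
        cfg["n_projections"] = n_projections
    return make_geometry(cfg)


def simulate_wire_emtf(
    height_mm: float,
    ffs: bool,
    stationary: bool = False,
    tilt_deg: float = 3.0,
    n_time_samples: int = 15,
    n_aperture_samples: int = 5,
    rows: int = 64,
) -> MTFCurve:
    """Forward-project a tilted wire and measure the effective MTF.

    ``stationary=True`` emulates a single-shot FFDM-like exposure (one
    projection, no tube motion) for the FFS-vs-stationary comparison.
    """
    geom = wire_geometry(
        ffs=ffs,
        height_mm=height_mm,
        rows=rows,
        n_projections=1 if stationary else None,
    )
    ph = wire_phantom(height_mm, tilt_deg=tilt_deg)
    stack = forward_project(
        ph,
        geom,
        n_spot_samples=1,
        n_time_samples=n_time_samples,
        n_aperture_samples=n_aperture_samples,
        step_mm=ph.voxel_size_mm[2],
    )
    return emtf_from_wire(stack, geom, wire_height_mm=height_mm, wire_tilt_deg=tilt_deg)


def clip_phantom_experiment(
    seed: int = 0,
    thickness_mm: float = 30.0,
    clip_height_mm: float = 15.0,
    detector_shape=(96, 208),
    dilation_px: int = 3,
    noise_gain: float | None = None,
    return_intermediates: bool = False,
):
    """Reference clip phantom: paired reconstruction with/without artifact
    reduction plus the artifact metrics record."""
    geom = make_geometry(
        {"detector_shape": detector_shape, "focal_spot": FocalSpotModel(ffs_enabled=True)}
    )
    # slab wide enough that no tissue/air edge enters any view's FOV
    ph = build_slab_phantom(
        thickness_mm=thickness_mm,
        glandularity=0.3,
        shape=(184, 44, 20),
        voxel_size_mm=(0.25, 0.25, 1.5),
        texture_beta=3.0,
        seed=seed,
    )
    clip = InsertSpec(
        kind="clip",
        position_mm=(0.0, 0.0, clip_height_mm),
        size_mm=(3.0, 1.0, 1.0),
        material="Rh",
        density_scale=0.35,
    )
    ph = add_insert(ph, clip)
    stack = forward_project(ph, geom, n_spot_samples=1, n_time_samples=1, step_mm=0.75)
    if noise_gain:
        stack = add_counting_noise(stack, noise_gain, seed + 1)
    log_stack = to_line_integrals(stack)
    masks = segment_objects(log_stack, struct_radius_px=8, k_threshold=8.0,
                            min_size_px=5, dilation_px=dilation_px)
    removed = remove_objects(log_stack, masks)
    fp = ramp_filter(log_stack, "hann", removed_stack=removed)
    z_planes = np.arange(2.0, thickness_mm - 1.0, 2.0)
    vol_base = backproject_perspective(fp, geom, z_planes)
    vol_ar = masked_backproject(fp, masks, geom, z_planes)
    record = artifact_metrics(vol_ar, vol_base, clip)
    if return_intermediates:
        return vol_ar, vol_base, record, dict(
            geom=geom, phantom=ph, clip=clip, stack=stack, log_stack=log_stack,
            masks=masks, fp=fp, z_planes=z_planes,
        )
    return vol_ar, vol_base, record


def calc_cluster_experiment(
    seed: int = 0,
    thickness_mm: float = 30.0,
    calc_height_mm: float = 15.0,
    n_calcs: int = 4,
    detector_shape=(96, 224),
):
    """Microcalcification cluster in a textured slab: projections, the
    perspective reconstruction, and the insert positions (for the
    perspective-coordinate and synthetic-mammogram position checks)."""
    geom = make_geometry(
        {"detector_shape": detector_shape, "focal_spot": FocalSpotModel(ffs_enabled=True)}
    )
    ph = build_slab_phantom(
        thickness_mm=thickness_mm,
        glandularity=0.3,
        shape=(184, 44, 20),
        voxel_size_mm=(0.25, 0.25, 1.5),
        texture_beta=3.0,
        seed=seed,
    )
    positions = [(-3.0 + 2.0 * k, (-1.0) ** k * 1.5, calc_height_mm) for k in range(n_calcs)]
    for pos in positions:
        ph = add_insert(
            ph,
            InsertSpec(kind="microcalc_cluster", position_mm=pos, count=1,
                       spacing_mm=0.0, size_mm=(0.4,), density_scale=8.0),
        )
    stack = forward_project(ph, geom, n_spot_samples=1, n_time_samples=1, step_mm=0.75)
    log_stack = to_line_integrals(stack)
    fp = ramp_filter(log_stack, "hann")
    z_planes = np.arange(2.0, thickness_mm - 1.0, 2.0)
    vol = backproject_perspective(fp, geom, z_planes)
    return dict(geom=geom, phantom=ph, stack=stack, log_stack=log_stack,
                vol=vol, positions=positions, z_planes=z_planes)
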