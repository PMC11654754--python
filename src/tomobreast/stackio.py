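"""Multi-page TIFF + JSON-sidecar serialization for projection stacks,
reconstruction volumes, phantoms, and object masks."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from dataclasses import asdict

from . import __version__
from .errors import ConfigurationError
from .geometry import AcquisitionGeometry, make_geometry
from .phantoms import InsertSpec, VoxelPhantom
from .projector import ProjectionStack
from .reconstruction import ReconVolume

__all__ = ["write_stack", "read_stack", "sidecar_path"]


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _geometry_dict(geom: AcquisitionGeometry) -> dict:
    return json.loads(geom.to_json())


def write_stack(path, obj) -> Path:
    """Write a ProjectionStack or ReconVolume as TIFF pages + JSON sidecar.

    Pixel data round-trips bit-exactly (the array dtype is preserved);
    metadata is lossless via the sidecar.
    """
    path = Path(path)
    if isinstance(obj, ProjectionStack):
        data = obj.images
        meta = {
            "kind": "projection_stack",
            "version": __version__,
            "geometry": _geometry_dict(obj.geometry),
            "view_angles_deg": obj.view_angles_deg.tolist(),
            "view_times_s": obj.view_times_s.tolist(),
            "air_reference": obj.air_reference,
            "is_log_normalized": obj.is_log_normalized,
            "seed_record": obj.seed_record,
            "dtype": str(data.dtype),
        }
    elif isinstance(obj, ReconVolume):
        data = obj.slices
        meta = {
            "kind": "recon_volume",
            "version": __version__,
            "geometry": _geometry_dict(obj.geometry),
            "coordinate_system": obj.coordinate_system,
            "slice_heights_mm": np.asarray(obj.slice_heights_mm).tolist(),
            "slice_thickness_mm": obj.slice_thickness_mm,
            "slice_spacing_mm": obj.slice_spacing_mm,
            "pixel_pitch_mm": obj.pixel_pitch_mm,
            "dtype": str(data.dtype),
        }
    elif isinstance(obj, VoxelPhantom):
        data = obj.material_ids
        meta = {
            "kind": "voxel_phantom",
            "version": __version__,
            "materials": list(obj.materials),
            "voxel_size_mm": list(obj.voxel_size_mm),
            "origin_mm": list(obj.origin_mm),
            "thickness_mm": obj.thickness_mm,
            "seed": obj.seed,
            "inserts": [asdict(i) for i in obj.inserts],
            "has_density_scale": obj.density_scale is not None,
            "dtype": str(data.dtype),
        }
        if obj.density_scale is not None:
            tifffile.imwrite(Path(str(path) + ".density.tif"),
                             np.asarray(obj.density_scale, np.float32),
                             photometric="minisblack")
    else:
        raise ConfigurationError(f"cannot serialize object of type {type(obj).__name__}")
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path):
    """Read back whatever :func:`write_stack` wrote."""
    path = Path(path)
    sc = sidecar_path(path)
    if not sc.exists():
        raise ConfigurationError(
            f"missing sidecar: expected metadata file {sc} next to {path}"
        )
    meta = json.loads(sc.read_text())
    if meta.get("version") != __version__:
        warnings.warn(
            f"stack written by version {meta.get('version')}, "
            f"reading with {__version__}",
            stacklevel=2,
        )
    data = tifffile.imread(path)
    if meta["kind"] == "voxel_phantom":
        density = None
        if meta.get("has_density_scale"):
            density = tifffile.imread(Path(str(path) + ".density.tif"))
        return VoxelPhantom(
            material_ids=np.asarray(data),
            materials=tuple(meta["materials"]),
            voxel_size_mm=tuple(meta["voxel_size_mm"]),
            origin_mm=tuple(meta["origin_mm"]),
            thickness_mm=meta["thickness_mm"],
            density_scale=density,
            seed=meta.get("seed"),
            inserts=tuple(
                InsertSpec(**{**i, "position_mm": tuple(i["position_mm"]),
                              "size_mm": tuple(i["size_mm"])})
                for i in meta.get("inserts", [])
            ),
        )
    geom = make_geometry(
        {k: v for k, v in meta["geometry"].items()}
        | {"detector_shape": tuple(meta["geometry"]["detector_shape"])}
    )
    if meta["kind"] == "projection_stack":
        return ProjectionStack(
            images=np.asarray(data),
            view_angles_deg=np.asarray(meta["view_angles_deg"]),
            view_times_s=np.asarray(meta["view_times_s"]),
            geometry=geom,
            air_reference=meta["air_reference"],
            is_log_normalized=meta["is_log_normalized"],
            seed_record=meta["seed_record"],
        )
    if meta["kind"] == "recon_volume":
        return ReconVolume(
            slices=np.asarray(data),
            coordinate_system=meta["coordinate_system"],
            slice_heights_mm=np.asarray(meta["slice_heights_mm"]),
            slice_thickness_mm=meta["slice_thickness_mm"],
            slice_spacing_mm=meta["slice_spacing_mm"],
            geometry=geom,
            pixel_pitch_mm=meta.get("pixel_pitch_mm"),
        )
    raise ConfigurationError(f"unknown stack kind {meta['kind']!r} in {sc}")
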