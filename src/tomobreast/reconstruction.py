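"""Ramp-filtered backprojection in the perspective coordinate system,
Cartesian resampling, and contrast-preserving slab merging.

Perspective coordinates: voxel (z, r, c) sits where the central-view ray
through detector pixel (r, c) pierces height z, so a structure keeps its
in-plane index across slices and no inter-slice resampling ever happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DomainError
from .geometry import AcquisitionGeometry, source_position
from .projector import ProjectionStack, detector_pixel_coords

__all__ = [
    "FilteredProjections",
    "ReconVolume",
    "ramp_filter",
    "backproject_perspective",
    "resample_cartesian",
    "merge_slabs",
    "reconstruct",
]

_WINDOWS = ("none", "hann", "hamming")


@dataclass
class FilteredProjections:
    oP: np.ndarray  # ramp-filtered original projections
    rP: np.ndarray | None  # ramp-filtered object-removed projections
    filter_window: str
    view_angles_deg: np.ndarray
    geometry: AcquisitionGeometry


@dataclass
class ReconVolume:
    slices: np.ndarray  # (n_z, rows, cols)
    coordinate_system: str  # perspective | cartesian
    slice_heights_mm: np.ndarray
    slice_thickness_mm: float
    slice_spacing_mm: float
    geometry: AcquisitionGeometry
    pixel_pitch_mm: float | None = None  # in-plane pitch (cartesian only)

    def __post_init__(self) -> None:
        if self.coordinate_system not in ("perspective", "cartesian"):
            raise DomainError(f"unknown coordinate system {self.coordinate_system!r}")
        h = np.asarray(self.slice_heights_mm, float)
        if h.size > 1 and np.any(np.diff(h) <= 0):
            raise DomainError("slice heights must be strictly increasing")

    def copy_with(self, **kw) -> "ReconVolume":
        return replace(self, **kw)


def _ramp_kernel(n_pad: int, window: str) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_pad)
    ramp = np.abs(freqs)
    if window == "hann":
        ramp *= 0.5 * (1.0 + np.cos(np.pi * freqs / freqs.max()))
    elif window == "hamming":
        ramp *= 0.54 + 0.46 * np.cos(np.pi * freqs / freqs.max())
    elif window != "none":
        raise DomainError(f"unknown filter window {window!r}; use one of {_WINDOWS}")
    return ramp


def _apply_ramp(images: np.ndarray, window: str) -> np.ndarray:
    n = images.shape[-1]
    n_pad = 2 * int(2 ** np.ceil(np.log2(max(n, 2))))
    # edge-replicate into the pad region: zero-padding a projection with a
    # nonzero baseline rings at the detector borders
    left = (n_pad - n) // 2
    padded = np.pad(images, [(0, 0)] * (images.ndim - 1) + [(left, n_pad - n - left)],
                    mode="edge")
    ramp = _ramp_kernel(n_pad, window)
    spec = np.fft.rfft(padded, axis=-1)
    out = np.fft.irfft(spec * ramp, n=n_pad, axis=-1)
    return np.ascontiguousarray(out[..., left: left + n])


def ramp_filter(
    stack: ProjectionStack,
    window: str = "hann",
    removed_stack: ProjectionStack | None = None,
) -> FilteredProjections:
    """Row-wise |f| filtering along the tube-travel direction (detector cols).

    The zero-frequency response is exactly 0 and the operator is linear;
    projections are zero-padded to twice the next power of two to keep
    wraparound below test tolerances.  ``removed_stack``, when given, is
    filtered identically into the rP channel for artifact reduction.
    """
    if not stack.is_log_normalized:
        raise DomainError("ramp_filter expects a log-normalized stack")
    oP = _apply_ramp(stack.images, window)
    rP = None
    if removed_stack is not None:
        if removed_stack.images.shape != stack.images.shape:
            raise DomainError("removed stack shape mismatch")
        rP = _apply_ramp(removed_stack.images, window)
    return FilteredProjections(
        oP=oP,
        rP=rP,
        filter_window=window,
        view_angles_deg=stack.view_angles_deg.copy(),
        geometry=stack.geometry,
    )


def _perspective_points(geom: AcquisitionGeometry, z: float):
    """World (x, y) where each central-view ray pierces height z."""
    px, py = detector_pixel_coords(geom)
    s0 = source_position(geom, (geom.n_projections - 1) // 2, 0.0)
    # central view sits at angle 0 -> source at (0, 0, SID); keep general:
    frac = (s0[2] - z) / s0[2]
    x = s0[0] + (px - s0[0]) * frac
    y = s0[1] + (py - s0[1]) * frac
    return x, y


def _detector_coords(geom: AcquisitionGeometry, source, X, Y, z):
    """Fractional detector pixel coords where rays source->(X, Y, z) hit z=0."""
    sx, sy, sz = source
    if sz <= z:
        raise DomainError("source below reconstruction plane")
    t = sz / (sz - z)
    u = sx + (X - sx) * t
    v = sy + (Y - sy) * t
    pitch = geom.detector_pixel_pitch_mm
    rows, cols = geom.detector_shape
    c = u / pitch + (cols - 1) / 2.0
    r = v / pitch + (rows - 1) / 2.0
    return r, c


def backproject_perspective(
    fp: FilteredProjections,
    geom: AcquisitionGeometry | None = None,
    z_planes_mm=(10.0,),
    masks: np.ndarray | None = None,
    core_masks: np.ndarray | None = None,
    slice_thickness_mm: float = 2.0,
    reinsert_threshold: float = 0.85,
) -> ReconVolume:
    """Mean-over-views backprojection onto central-ray sample positions.

    For every voxel and view the filtered projection is sampled with
    bilinear interpolation where the view's ray through the voxel hits the
    detector; views whose sample falls off-detector are excluded and the
    mean renormalized.  With ``masks`` (and fp.rP) given, samples landing
    inside a view's object mask are read from rP instead of oP — except
    for voxels whose samples hit the object's un-dilated shadow core
    (``core_masks``) in at least ``reinsert_threshold`` of their views:
    those are the segmented object itself (its shadow is consistent across
    angles) and keep the original data so the object stays visible in its
    focus slice.
    """
    geom = geom or fp.geometry
    z_planes = np.asarray(sorted(z_planes_mm), float)
    if np.any(z_planes <= 0) or np.any(z_planes >= geom.source_to_detector_mm):
        raise DomainError("z planes must lie in (0, SID)")
    if masks is not None and fp.rP is None:
        raise DomainError("masks given but fp.rP missing")
    rows, cols = geom.detector_shape
    n_views = fp.oP.shape[0]
    out = np.zeros((len(z_planes), rows, cols))
    for iz, z in enumerate(z_planes):
        xs, ys = _perspective_points(geom, z)
        X, Y = np.meshgrid(xs, ys)  # (rows, cols); X varies along cols
        view_coords = []
        view_inside = []
        hits = []
        core_hits = []
        for v in range(n_views):
            src = source_position(geom, v, 0.0)
            r, c = _detector_coords(geom, src, X, Y, z)
            eps = 1e-9  # boundary tolerance: central rays land exactly on edges
            inside = (r >= -eps) & (r <= rows - 1 + eps) & (c >= -eps) & (c <= cols - 1 + eps)
            # clip: scipy returns cval for coordinates even marginally outside
            coords = np.stack([
                np.clip(r.ravel(), 0, rows - 1), np.clip(c.ravel(), 0, cols - 1)
            ])
            view_coords.append(coords)
            view_inside.append(inside)
            if masks is not None:
                def _hit(m):
                    return map_coordinates(
                        m.astype(np.float64), coords, order=0, mode="constant", cval=0.0
                    ).reshape(rows, cols) > 0.5
                hits.append(_hit(masks[v]))
                core_hits.append(_hit(core_masks[v]) if core_masks is not None else hits[-1])
        if masks is not None:
            hits = np.asarray(hits)
            n_inside = np.maximum(np.sum(view_inside, axis=0), 1)
            core_frac = np.asarray(core_hits).sum(axis=0) / n_inside
            is_object = core_frac >= reinsert_threshold
        acc = np.zeros((rows, cols))
        wsum = np.zeros((rows, cols))
        for v in range(n_views):
            coords, inside = view_coords[v], view_inside[v]
            samp = map_coordinates(fp.oP[v], coords, order=1, mode="constant", cval=0.0)
            samp = samp.reshape(rows, cols)
            if masks is not None:
                use_rp = hits[v] & ~is_object
                if np.any(use_rp):
                    samp_r = map_coordinates(
                        fp.rP[v], coords, order=1, mode="constant", cval=0.0
                    ).reshape(rows, cols)
                    samp = np.where(use_rp, samp_r, samp)
            acc += np.where(inside, samp, 0.0)
            wsum += inside
        with np.errstate(invalid="ignore"):
            out[iz] = np.where(wsum > 0, acc / np.maximum(wsum, 1), 0.0)
    spacing = float(np.min(np.diff(z_planes))) if len(z_planes) > 1 else slice_thickness_mm
    return ReconVolume(
        slices=out,
        coordinate_system="perspective",
        slice_heights_mm=z_planes,
        slice_thickness_mm=slice_thickness_mm,
        slice_spacing_mm=spacing,
        geometry=geom,
    )


def resample_cartesian(vol: ReconVolume) -> ReconVolume:
    """Map every slice onto the fixed detector-pitch (x, y) grid.

    The Cartesian grid equals the detector pixel grid at z = 0, so the
    detector-plane slice maps identically; higher slices are bilinearly
    interpolated from their (demagnified) perspective sample positions.
    """
    if vol.coordinate_system != "cartesian" and vol.coordinate_system != "perspective":
        raise DomainError("unknown coordinate system")
    if vol.coordinate_system == "cartesian":
        return vol
    geom = vol.geometry
    rows, cols = geom.detector_shape
    pitch = geom.detector_pixel_pitch_mm
    gx = (np.arange(cols) - (cols - 1) / 2.0) * pitch
    gy = (np.arange(rows) - (rows - 1) / 2.0) * pitch
    GX, GY = np.meshgrid(gx, gy)  # (rows, cols)
    out = np.empty_like(vol.slices)
    for iz, z in enumerate(vol.slice_heights_mm):
        xs, ys = _perspective_points(geom, z)
        # invert the (monotone, affine) perspective map per axis
        ci = np.interp(GX, xs, np.arange(cols))
        ri = np.interp(GY, ys, np.arange(rows))
        out[iz] = map_coordinates(
            vol.slices[iz], np.stack([ri.ravel(), ci.ravel()]), order=1, mode="nearest"
        ).reshape(rows, cols)
    return vol.copy_with(slices=out, coordinate_system="cartesian", pixel_pitch_mm=pitch)


def merge_slabs(
    vol: ReconVolume,
    out_thickness_mm: float,
    mode: str = "contrast_preserving",
    lambda_blend: float = 0.5,
) -> ReconVolume:
    """Merge native slices into thicker slabs.

    ``contrast_preserving`` blends the slab mean with the constituent value
    of largest absolute deviation from that mean, weight ``lambda_blend``;
    ``mean`` is the plain average.  Small high-contrast details survive
    slabbing this way instead of being diluted by the average.
    """
    if mode not in ("contrast_preserving", "mean"):
        raise DomainError(f"unknown slab mode {mode!r}")
    if out_thickness_mm < vol.slice_spacing_mm:
        raise DomainError("slab thickness below slice spacing")
    per_slab = max(int(round(out_thickness_mm / vol.slice_spacing_mm)), 1)
    n_z = vol.slices.shape[0]
    starts = range(0, n_z, per_slab)
    slabs, heights = [], []
    for s in starts:
        block = vol.slices[s: s + per_slab]
        mean = block.mean(axis=0)
        if mode == "mean" or block.shape[0] == 1:
            slab = mean if mode == "mean" else block[0]
        else:
            dev = block - mean[None]
            pick = np.argmax(np.abs(dev), axis=0)
            extremum = np.take_along_axis(block, pick[None], axis=0)[0]
            slab = (1.0 - lambda_blend) * mean + lambda_blend * extremum
        slabs.append(slab)
        heights.append(float(np.mean(vol.slice_heights_mm[s: s + per_slab])))
    return vol.copy_with(
        slices=np.stack(slabs),
        slice_heights_mm=np.asarray(heights),
        slice_thickness_mm=float(out_thickness_mm),
        slice_spacing_mm=float(out_thickness_mm),
    )


def reconstruct(
    stack: ProjectionStack,
    z_planes_mm,
    window: str = "hann",
    slice_thickness_mm: float = 2.0,
    coords: str = "perspective",
) -> ReconVolume:
    """Convenience pipeline: log-normalize -> ramp filter -> backproject."""
    from .projector import to_line_integrals

    fp = ramp_filter(to_line_integrals(stack), window)
    vol = backproject_perspective(fp, stack.geometry, z_planes_mm,
                                  slice_thickness_mm=slice_thickness_mm)
    if coords == "cartesian":
        vol = resample_cartesian(vol)
    return vol
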