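"""Seeded synthetic phantoms: textured breast slabs, microcalcification
clusters, metal clips, tilted wires, aluminum sheets, and 1-D layer stacks.

All generators are pure functions of (configuration, seed): calling them
twice with the same arguments returns bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, LookupErrorTB
from .materials import list_materials

__all__ = [
    "VoxelPhantom",
    "InsertSpec",
    "build_slab_phantom",
    "add_insert",
    "one_d_stack",
    "power_law_field",
]

AIR = "air"  # sentinel material id 0; attenuation treated as zero


@dataclass(frozen=True)
class VoxelPhantom:
    """Material-id voxel grid plus an optional per-voxel density multiplier.

    ``material_ids`` indexes into ``materials`` (id 0 is always air).
    Grid axes are (x, y, z) with z spanning [origin_z, origin_z+thickness].
    """

    material_ids: np.ndarray  # (nx, ny, nz) uint8
    materials: tuple  # id -> material name
    voxel_size_mm: tuple  # (dx, dy, dz)
    origin_mm: tuple  # world position of voxel (0, 0, 0) center
    thickness_mm: float
    density_scale: np.ndarray | None = None
    seed: int | None = None
    inserts: tuple = ()

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_mm):
            raise DomainError("voxel_size_mm components must be > 0")
        nz = self.material_ids.shape[2]
        extent = nz * self.voxel_size_mm[2]
        if extent < self.thickness_mm - 1e-6:
            raise DomainError(
                f"grid z-extent {extent:.3f} mm smaller than thickness {self.thickness_mm} mm"
            )
        for name in self.materials:
            if name != AIR and name not in list_materials():
                raise LookupErrorTB(f"unknown phantom material {name!r}")

    @property
    def shape(self):
        return self.material_ids.shape

    def material_id(self, name: str) -> int:
        return self.materials.index(name)

    def with_material(self, name: str) -> tuple["VoxelPhantom", int]:
        """Return (phantom, id) with ``name`` present in the material list."""
        if name in self.materials:
            return self, self.materials.index(name)
        return replace(self, materials=self.materials + (name,)), len(self.materials)

    def voxel_index(self, position_mm) -> tuple[int, int, int]:
        """Nearest voxel index of a world position (mm)."""
        idx = []
        for axis in range(3):
            i = round((position_mm[axis] - self.origin_mm[axis]) / self.voxel_size_mm[axis])
            idx.append(int(i))
        return tuple(idx)


@dataclass(frozen=True)
class InsertSpec:
    kind: str  # microcalc_cluster | clip | wire | al_sheet
    position_mm: tuple
    size_mm: tuple = ()
    material: str = "calcium"
    count: int = 5
    spacing_mm: float = 2.0
    tilt_deg: float = 3.0
    diameter_mm: float = 0.025
    density_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("microcalc_cluster", "clip", "wire", "al_sheet"):
            raise DomainError(f"unknown insert kind {self.kind!r}")
        if self.kind == "wire" and not (0.5 < self.tilt_deg < 10.0):
            raise DomainError("wire tilt must lie in (0.5, 10) degrees")


def power_law_field(shape, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Isotropic zero-mean Gaussian field with power spectrum ~ 1/f^beta."""
    white = rng.standard_normal(shape)
    if beta == 0:
        return white
    freqs = np.meshgrid(*[np.fft.fftfreq(n) for n in shape], indexing="ij")
    radius = np.sqrt(sum(f**2 for f in freqs))
    radius[(0,) * len(shape)] = np.min(radius[radius > 0])
    amplitude = radius ** (-beta / 2.0)
    spec = np.fft.fftn(white) * amplitude
    out = np.fft.ifftn(spec).real
    return (out - out.mean()) / out.std()


def build_slab_phantom(
    thickness_mm: float = 60.0,
    glandularity: float = 0.5,
    shape=(64, 64, 24),
    voxel_size_mm=(0.5, 0.5, 2.5),
    texture_beta: float = 3.0,
    seed: int = 0,
) -> VoxelPhantom:
    """Compressed-breast slab with power-law glandular/adipose texture.

    The mixing field is isotropic 1/f^beta noise thresholded at the exact
    empirical quantile, so the voxel glandular fraction equals the request
    up to the granularity of the grid.
    """
    if not (20.0 <= thickness_mm <= 90.0):
        raise DomainError("thickness must lie in [20, 90] mm")
    if texture_beta < 0:
        raise DomainError("texture_beta must be >= 0")
    nz_needed = int(np.ceil(thickness_mm / voxel_size_mm[2] - 1e-9))
    if shape[2] < nz_needed:
        raise DomainError(
            f"shape z-dim {shape[2]} too small for {thickness_mm} mm slab "
            f"at dz={voxel_size_mm[2]} (needs >= {nz_needed})"
        )
    shape = (shape[0], shape[1], nz_needed)
    rng = np.random.default_rng(seed)
    fld = power_law_field(shape, texture_beta, rng)
    if glandularity <= 0:
        gland = np.zeros(shape, dtype=bool)
    elif glandularity >= 1:
        gland = np.ones(shape, dtype=bool)
    else:
        thr = np.quantile(fld, 1.0 - glandularity)
        gland = fld > thr
    ids = np.where(gland, 2, 1).astype(np.uint8)
    return VoxelPhantom(
        material_ids=ids,
        materials=(AIR, "adipose", "glandular"),
        voxel_size_mm=tuple(voxel_size_mm),
        origin_mm=(
            -(shape[0] - 1) / 2.0 * voxel_size_mm[0],
            -(shape[1] - 1) / 2.0 * voxel_size_mm[1],
            voxel_size_mm[2] / 2.0,
        ),
        thickness_mm=thickness_mm,
        seed=seed,
    )


def _bounds_check(phantom: VoxelPhantom, idx, what: str) -> None:
    shape = phantom.shape
    over = [
        f"axis {ax}: index {idx[ax]} outside [0, {shape[ax] - 1}]"
        for ax in range(3)
        if not (0 <= idx[ax] < shape[ax])
    ]
    if over:
        raise DomainError(f"{what} out of phantom bounds: " + "; ".join(over))


def add_insert(phantom: VoxelPhantom, spec: InsertSpec) -> VoxelPhantom:
    """Return a new phantom with the insert's voxels set to its material."""
    phantom, mat_id = phantom.with_material(spec.material)
    ids = phantom.material_ids.copy()
    dens = (
        phantom.density_scale.copy()
        if phantom.density_scale is not None
        else np.ones_like(ids, dtype=np.float32)
    )
    dx, dy, dz = phantom.voxel_size_mm

    if spec.kind == "microcalc_cluster":
        if spec.count > 0:
            rng = np.random.default_rng(abs(hash((phantom.seed, "calc", spec.position_mm))) % 2**32)
            for k in range(spec.count):
                offs = rng.uniform(-spec.spacing_mm, spec.spacing_mm, size=3)
                offs[2] *= 0.2  # keep the cluster roughly in-plane
                center = np.asarray(spec.position_mm) + offs
                diam = rng.uniform(0.2, 0.5) if not spec.size_mm else spec.size_mm[0]
                idx = phantom.voxel_index(center)
                _bounds_check(phantom, idx, f"microcalc {k}")
                ids[idx] = mat_id
                # sub-voxel sphere: encode partial volume in the density scale
                vol_ratio = (np.pi / 6.0 * diam**3) / (dx * dy * dz)
                dens[idx] = spec.density_scale * min(vol_ratio, 1.0) if vol_ratio < 1 else spec.density_scale
    elif spec.kind == "clip":
        size = spec.size_mm or (3.0, 1.0, 1.0)
        lo = phantom.voxel_index(np.asarray(spec.position_mm) - np.asarray(size) / 2.0)
        hi = phantom.voxel_index(np.asarray(spec.position_mm) + np.asarray(size) / 2.0)
        _bounds_check(phantom, lo, "clip")
        _bounds_check(phantom, hi, "clip")
        ids[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1] = mat_id
        dens[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1] = spec.density_scale
    elif spec.kind == "wire":
        # thin cylinder along y, tilted in-plane by tilt_deg toward x,
        # at constant height; sub-voxel diameter is represented by a
        # partial-volume density multiplier on the nearest voxel column.
        tilt = np.radians(spec.tilt_deg)
        kz = int(round((spec.position_mm[2] - phantom.origin_mm[2]) / dz))
        if not (0 <= kz < phantom.shape[2]):
            raise DomainError(f"wire height {spec.position_mm[2]} mm outside phantom z-range")
        area_ratio = (np.pi / 4.0 * spec.diameter_mm**2) / (dx * dz)
        for j in range(phantom.shape[1]):
            y = phantom.origin_mm[1] + j * dy
            x = spec.position_mm[0] + np.tan(tilt) * (y - spec.position_mm[1])
            i = round((x - phantom.origin_mm[0]) / dx)
            if 0 <= i < phantom.shape[0]:
                ids[i, j, kz] = mat_id
                dens[i, j, kz] = spec.density_scale * min(area_ratio, 1.0)
    elif spec.kind == "al_sheet":
        thickness = spec.size_mm[0] if spec.size_mm else 0.5
        kz = int(round((spec.position_mm[2] - phantom.origin_mm[2]) / dz))
        _bounds_check(phantom, (0, 0, kz), "al_sheet")
        ids[:, :, kz] = mat_id
        dens[:, :, kz] = spec.density_scale * min(thickness / dz, 1.0)

    return replace(
        phantom,
        material_ids=ids,
        density_scale=dens,
        inserts=phantom.inserts + (spec,),
    )


def one_d_stack(layers) -> list[tuple[str, float]]:
    """Validated (material, thickness_mm) sequence for the 1-D CNR model."""
    layers = list(layers)
    if not layers:
        raise DomainError("empty layer stack")
    out = []
    for mat, t in layers:
        if mat not in list_materials():
            raise LookupErrorTB(f"unknown material {mat!r}")
        if t < 0:
            raise DomainError("layer thickness must be >= 0")
        out.append((mat, float(t)))
    return out
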