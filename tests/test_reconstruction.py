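import math

import numpy as np
import pytest

from tomobreast.errors import DomainError
from tomobreast.geometry import FocalSpotModel, make_geometry
from tomobreast.projector import ProjectionStack, forward_project, to_line_integrals
from tomobreast.phantoms import AIR, VoxelPhantom
from tomobreast.reconstruction import (
    FilteredProjections,
    backproject_perspective,
    merge_slabs,
    ramp_filter,
    resample_cartesian,
)


def _log_stack(geom, images=None):
    n = geom.n_projections
    rows, cols = geom.detector_shape
    if images is None:
        images = np.zeros((n, rows, cols))
    from tomobreast.geometry import acquisition_schedule

    sched = acquisition_schedule(geom)
    return ProjectionStack(
        images=images,
        view_angles_deg=sched.view_center_angles_deg,
        view_times_s=sched.view_center_times_s,
        geometry=geom,
        is_log_normalized=True,
    )


@pytest.fixture()
def geom7():
    return make_geometry({"n_projections": 7, "detector_shape": (12, 16),
                          "pulse_length_ms": 40.0,
                          "focal_spot": FocalSpotModel(ffs_enabled=True)})


class TestRampFilter:
    def test_constant_maps_to_zero(self, geom7):
        st = _log_stack(geom7, np.full((7, 12, 16), 3.7))
        fp = ramp_filter(st, "hann")
        np.testing.assert_allclose(fp.oP, 0.0, atol=1e-6)

    def test_impulse_matches_direct_dft_kernel(self, geom7):
        # independent oracle: evaluate the padded ramp response by naive
        # DFT summation for an impulse in the middle of a row
        n = 16
        images = np.zeros((7, 12, n))
        images[0, 6, 8] = 1.0
        fp = ramp_filter(_log_stack(geom7, images), window="none")
        n_pad = 2 * int(2 ** math.ceil(math.log2(n)))
        left = (n_pad - n) // 2
        freqs = np.fft.rfftfreq(n_pad)
        expected = np.zeros(n)
        for j in range(n):
            acc = 0.0
            for k, f in enumerate(freqs):
                weight = 1.0 if k in (0, len(freqs) - 1) else 2.0
                acc += weight * f * math.cos(2 * math.pi * f * ((j + left) - (8 + left)))
            expected[j] = acc / n_pad
        np.testing.assert_allclose(fp.oP[0, 6], expected, atol=1e-10)

    def test_linearity(self, geom7):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((7, 12, 16))
        b = rng.standard_normal((7, 12, 16))
        fa = ramp_filter(_log_stack(geom7, a), "hamming").oP
        fb = ramp_filter(_log_stack(geom7, b), "hamming").oP
        fab = ramp_filter(_log_stack(geom7, a + b), "hamming").oP
        np.testing.assert_allclose(fab, fa + fb, atol=1e-12)

    def test_requires_log_normalized(self, geom7):
        st = _log_stack(geom7)
        st.is_log_normalized = False
        with pytest.raises(DomainError):
            ramp_filter(st)

    def test_unknown_window(self, geom7):
        with pytest.raises(DomainError, match="window"):
            ramp_filter(_log_stack(geom7), window="blackman")


def brute_force_backproject(fp, geom, z_planes):
    """Independent per-voxel, per-view geometric oracle (pure python)."""
    rows, cols = geom.detector_shape
    pitch = geom.detector_pixel_pitch_mm
    sid = geom.source_to_detector_mm
    n_views = fp.oP.shape[0]
    half = geom.angular_range_deg / 2.0
    angles = (np.linspace(-half, half, n_views) if n_views > 1 else np.array([0.0]))
    radius = sid - geom.rotation_center_height_mm
    out = np.zeros((len(z_planes), rows, cols))
    for iz, z in enumerate(sorted(z_planes)):
        for r in range(rows):
            for c in range(cols):
                # voxel = central ray of pixel (r, c) at height z
                px = (c - (cols - 1) / 2.0) * pitch
                py = (r - (rows - 1) / 2.0) * pitch
                x = px * (1.0 - z / sid)
                y = py * (1.0 - z / sid)
                acc, wsum = 0.0, 0
                for v, a in enumerate(np.radians(angles)):
                    sx = radius * math.sin(a)
                    sz = geom.rotation_center_height_mm + radius * math.cos(a)
                    t = sz / (sz - z)
                    u = sx + (x - sx) * t
                    w = 0.0 + (y - 0.0) * t
                    ci = u / pitch + (cols - 1) / 2.0
                    ri = w / pitch + (rows - 1) / 2.0
                    # documented boundary convention: eps-inclusive, clipped
                    if not (-1e-9 <= ri <= rows - 1 + 1e-9 and -1e-9 <= ci <= cols - 1 + 1e-9):
                        continue
                    ri = min(max(ri, 0.0), rows - 1.0)
                    ci = min(max(ci, 0.0), cols - 1.0)
                    r0, c0 = int(math.floor(ri)), int(math.floor(ci))
                    r1, c1 = min(r0 + 1, rows - 1), min(c0 + 1, cols - 1)
                    fr, fc = ri - r0, ci - c0
                    val = (
                        fp.oP[v, r0, c0] * (1 - fr) * (1 - fc)
                        + fp.oP[v, r1, c0] * fr * (1 - fc)
                        + fp.oP[v, r0, c1] * (1 - fr) * fc
                        + fp.oP[v, r1, c1] * fr * fc
                    )
                    acc += val
                    wsum += 1
                out[iz, r, c] = acc / wsum if wsum else 0.0
    return out


class TestBackprojectPerspective:
    def test_matches_brute_force_oracle(self, geom7):
        rng = np.random.default_rng(5)
        images = rng.standard_normal((7, 12, 16))
        fp = ramp_filter(_log_stack(geom7, images), "hann")
        z_planes = [5.0, 17.0, 31.0, 44.0]
        vol = backproject_perspective(fp, geom7, z_planes)
        oracle = brute_force_backproject(fp, geom7, z_planes)
        rng_span = oracle.max() - oracle.min()
        assert np.max(np.abs(vol.slices - oracle)) < 1e-6 * rng_span

    def test_single_view_at_detector_plane_is_identity(self):
        geom = make_geometry({"n_projections": 1, "detector_shape": (12, 16)})
        rng = np.random.default_rng(1)
        images = rng.standard_normal((1, 12, 16))
        fp = ramp_filter(_log_stack(geom, images), "hann")
        vol = backproject_perspective(fp, geom, [1e-9])
        np.testing.assert_allclose(vol.slices[0], fp.oP[0], atol=1e-9)

    def test_z_plane_domain(self, geom7):
        fp = ramp_filter(_log_stack(geom7), "hann")
        with pytest.raises(DomainError):
            backproject_perspective(fp, geom7, [-1.0])
        with pytest.raises(DomainError):
            backproject_perspective(fp, geom7, [700.0])


class TestResampleCartesian:
    def _vol(self, geom, z, fill):
        fp = FilteredProjections(
            oP=np.zeros((geom.n_projections, *geom.detector_shape)),
            rP=None, filter_window="hann",
            view_angles_deg=np.zeros(geom.n_projections), geometry=geom,
        )
        vol = backproject_perspective(fp, geom, [z])
        vol.slices[0] = fill
        return vol

    def test_detector_plane_identity(self, geom7):
        rng = np.random.default_rng(2)
        field = rng.standard_normal(geom7.detector_shape)
        vol = self._vol(geom7, 1e-9, field)
        out = resample_cartesian(vol)
        np.testing.assert_allclose(out.slices[0], field, atol=1e-9)
        assert out.coordinate_system == "cartesian"

    def test_uniform_stays_uniform(self, geom7):
        vol = self._vol(geom7, 40.0, np.full(geom7.detector_shape, 2.5))
        out = resample_cartesian(vol)
        np.testing.assert_allclose(out.slices[0], 2.5, atol=1e-12)

    def test_quadratic_field_against_analytic_map(self):
        geom = make_geometry({"detector_shape": (64, 96),
                              "focal_spot": FocalSpotModel(ffs_enabled=True)})
        z = 60.0
        sid = geom.source_to_detector_mm
        pitch = geom.detector_pixel_pitch_mm
        rows, cols = geom.detector_shape

        def f(x, y):
            return 0.3 * x**2 + 0.1 * y**2 - 0.2 * x * y + x + 2.0

        px = (np.arange(cols) - (cols - 1) / 2.0) * pitch
        py = (np.arange(rows) - (rows - 1) / 2.0) * pitch
        xs, ys = px * (1 - z / sid), py * (1 - z / sid)
        persp = f(xs[None, :], ys[:, None])
        vol = self._vol(geom, z, persp)
        out = resample_cartesian(vol)
        # interior of the Cartesian grid covered by the perspective samples
        inner_c = np.nonzero((px >= xs.min()) & (px <= xs.max()))[0]
        inner_r = np.nonzero((py >= ys.min()) & (py <= ys.max()))[0]
        expected = f(px[None, inner_c], py[inner_r, None])
        got = out.slices[0][np.ix_(inner_r, inner_c)]
        span = expected.max() - expected.min()
        assert np.max(np.abs(got - expected)) < 1e-3 * span

    def test_round_trip_smooth_field(self, geom7):
        z = 30.0
        rows, cols = geom7.detector_shape
        smooth = np.outer(np.linspace(0, 1, rows) ** 2, np.linspace(1, 2, cols))
        vol = self._vol(geom7, z, smooth)
        cart = resample_cartesian(vol)
        assert cart.pixel_pitch_mm == geom7.detector_pixel_pitch_mm


class TestMergeSlabs:
    def _vol(self, n_z=8, seed=0):
        geom = make_geometry({"n_projections": 1, "detector_shape": (8, 10)})
        rng = np.random.default_rng(seed)
        from tomobreast.reconstruction import ReconVolume

        return ReconVolume(
            slices=rng.standard_normal((n_z, 8, 10)),
            coordinate_system="perspective",
            slice_heights_mm=np.arange(1.0, n_z + 1.0),
            slice_thickness_mm=1.0,
            slice_spacing_mm=1.0,
            geometry=geom,
        )

    def test_lambda_zero_is_mean(self):
        vol = self._vol()
        merged = merge_slabs(vol, 2.0, mode="contrast_preserving", lambda_blend=0.0)
        expected = vol.slices.reshape(4, 2, 8, 10).mean(axis=1)
        np.testing.assert_allclose(merged.slices, expected, atol=1e-12)

    def test_single_slice_slab_unchanged(self):
        vol = self._vol(n_z=3)
        merged = merge_slabs(vol, 1.0, lambda_blend=0.7)
        np.testing.assert_allclose(merged.slices, vol.slices)

    def test_contrast_preserving_beats_mean_on_peak(self):
        vol = self._vol(seed=3)
        vol.slices *= 0.05
        vol.slices[3, 4, 5] = 1.0  # a calc-like spike in one native slice
        cp = merge_slabs(vol, 4.0, mode="contrast_preserving", lambda_blend=0.5)
        mn = merge_slabs(vol, 4.0, mode="mean")
        background = np.median(cp.slices[0])
        assert cp.slices[0, 4, 5] - background > mn.slices[0, 4, 5] - np.median(mn.slices[0])

    def test_unknown_mode(self):
        with pytest.raises(DomainError):
            merge_slabs(self._vol(), 2.0, mode="max")

    def test_too_thin_slab(self):
        with pytest.raises(DomainError):
            merge_slabs(self._vol(), 0.5)


def test_perspective_volume_metadata():
    geom = make_geometry({"n_projections": 3, "detector_shape": (8, 10),
                          "pulse_length_ms": 40.0})
    images = np.zeros((3, 8, 10))
    fp = ramp_filter(_log_stack(geom, images), "hann")
    vol = backproject_perspective(fp, geom, [2.0, 4.0, 6.0], slice_thickness_mm=2.0)
    assert vol.coordinate_system == "perspective"
    assert vol.slice_spacing_mm == 2.0
    np.testing.assert_array_equal(vol.slice_heights_mm, [2.0, 4.0, 6.0])
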