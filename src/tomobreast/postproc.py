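"""Post-processing: baseline equalization, multifrequency "flavoring" with
dark-overshoot suppression, physics-constrained denoising, and a
simplified synthetic-mammogram (SM) generator.

The denoiser's contribution implemented here is the plausibility clamp:
whatever estimator proposes the per-pixel noise, the amount actually
subtracted is hard-limited to ``clamp_k`` multiples of the physical
quantum-noise sigma sqrt(value / gain).  The default estimator is a
classical variance-stabilized fine-band soft-threshold; any callable with
the same signature can be plugged in instead (trained models out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DomainError
from .projector import ProjectionStack
from .reconstruction import ReconVolume

__all__ = [
    "FlavorConfig",
    "NoiseModel",
    "equalize_baseline",
    "multiband_enhance",
    "constrained_denoise",
    "synthesize_sm",
    "band_decompose",
]


@dataclass(frozen=True)
class FlavorConfig:
    n_bands: int = 4
    band_gains: tuple = (1.0, 1.0, 1.0, 1.0)
    overshoot_clamp: float | None = None  # None disables clamping
    base_sigma_px: float = 1.0
    edge_percentile: float = 99.0

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise DomainError("n_bands must be >= 2")
        if len(self.band_gains) != self.n_bands:
            raise DomainError("band_gains length must equal n_bands")
        if any(g <= 0 for g in self.band_gains):
            raise DomainError("band gains must be > 0")
        if self.overshoot_clamp is not None and not (0.0 <= self.overshoot_clamp <= 1.0):
            raise DomainError("overshoot_clamp must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    gain: float  # photons per signal unit
    clamp_k: float = 2.0
    denoiser: str = "vst_soft_threshold"

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise DomainError("gain must be > 0")
        if self.clamp_k < 0:
            raise DomainError("clamp_k must be >= 0")


def equalize_baseline(
    vol: ReconVolume, breast_mask: np.ndarray, baseline_sigma_mm: float = 20.0
) -> ReconVolume:
    """Remove slow thickness/density gray-level trends inside the breast.

    A heavy Gaussian low-pass (computed with normalized convolution so the
    breast border does not bleed) is subtracted per slice and the masked
    mean restored; pixels outside the mask are untouched bit-wise.
    """
    if baseline_sigma_mm <= 0:
        raise DomainError("baseline_sigma_mm must be > 0")
    mask = np.asarray(breast_mask, bool)
    if mask.ndim == 2:
        mask = np.broadcast_to(mask, vol.slices.shape)
    if not mask.any():
        raise DomainError("empty breast mask")
    pitch = vol.pixel_pitch_mm or vol.geometry.detector_pixel_pitch_mm
    sigma_px = baseline_sigma_mm / pitch
    out = vol.slices.copy()
    for iz in range(out.shape[0]):
        m = mask[iz].astype(np.float64)
        if not m.any():
            continue
        img = out[iz]
        num = ndimage.gaussian_filter(img * m, sigma_px)
        den = ndimage.gaussian_filter(m, sigma_px)
        with np.errstate(invalid="ignore", divide="ignore"):
            baseline = np.where(den > 1e-12, num / den, 0.0)
        inside = m > 0
        mean_in = img[inside].mean()
        corrected = img - baseline + mean_in
        out[iz] = np.where(inside, corrected, img)
    return vol.copy_with(slices=out)


def band_decompose(image: np.ndarray, n_bands: int, base_sigma_px: float = 1.0):
    """Octave difference-of-Gaussian bands plus residual; sums exactly back."""
    sigmas = [base_sigma_px * 2.0**b for b in range(n_bands)]
    prev = image
    bands = []
    for s in sigmas:
        low = ndimage.gaussian_filter(image, s)
        bands.append(prev - low)
        prev = low
    return bands, prev  # fine -> coarse bands, residual


def multiband_enhance(vol: ReconVolume, cfg: FlavorConfig) -> ReconVolume:
    """Per-band gains with optional dark-overshoot suppression.

    With all gains 1 and clamping disabled the pyramid reconstructs the
    input exactly.  When clamping is on, negative excursions of the two
    finest bands adjacent to high-contrast edges are scaled down to
    ``overshoot_clamp`` of their unclamped value.
    """
    out = np.empty_like(vol.slices)
    for iz in range(vol.slices.shape[0]):
        img = vol.slices[iz]
        bands, residual = band_decompose(img, cfg.n_bands, cfg.base_sigma_px)
        if cfg.overshoot_clamp is not None:
            grad = ndimage.gaussian_gradient_magnitude(img, cfg.base_sigma_px)
            thr = np.percentile(grad, cfg.edge_percentile)
            near_edge = ndimage.binary_dilation(grad >= thr, iterations=2)
            for b in range(min(2, cfg.n_bands)):
                band = bands[b]
                clampzone = near_edge & (band < 0)
                band[clampzone] *= cfg.overshoot_clamp
        acc = residual.copy()
        for g, band in zip(cfg.band_gains, bands):
            acc += g * band
        out[iz] = acc
    return vol.copy_with(slices=out)


def _anscombe(v: np.ndarray) -> np.ndarray:
    return 2.0 * np.sqrt(np.clip(v, 0.0, None) + 3.0 / 8.0)


def _inv_anscombe(a: np.ndarray) -> np.ndarray:
    return np.clip((a / 2.0) ** 2 - 3.0 / 8.0, 0.0, None)


def _vst_soft_threshold_estimator(
    counts: np.ndarray, sigma_px: float = 1.0, threshold: float = 1.5
) -> np.ndarray:
    """Default noise estimator in photon-count units (no trained weights).

    Works in the Anscombe domain where Poisson noise has unit variance:
    the fine band (image minus Gaussian low-pass) is soft-thresholded and
    the removed part, mapped back, is the noise estimate.
    """
    a = _anscombe(counts)
    low = ndimage.gaussian_filter(a, sigma_px)
    fine = a - low
    shrunk = np.sign(fine) * np.maximum(np.abs(fine) - threshold, 0.0)
    denoised_a = low + shrunk
    return counts - _inv_anscombe(denoised_a)


_ESTIMATORS = {"vst_soft_threshold": _vst_soft_threshold_estimator}


def constrained_denoise(
    stack: ProjectionStack, nm: NoiseModel, estimator=None
) -> ProjectionStack:
    """Subtract a noise estimate clamped to the physical Poisson bound.

    For every pixel the subtracted amount obeys |n| <= clamp_k * sigma_phys
    with sigma_phys = sqrt(value / gain); clamp_k = 0 therefore returns the
    input unchanged, whatever the estimator proposes.
    """
    if stack.is_log_normalized:
        raise DomainError("denoise operates on intensity-domain stacks")
    if np.any(stack.images < 0):
        raise DomainError("negative intensities")
    fn = estimator or _ESTIMATORS[nm.denoiser]
    out = np.empty_like(stack.images)
    for v in range(stack.n_views):
        value = stack.images[v]
        counts = value * nm.gain
        n_hat = fn(counts) / nm.gain  # back to signal units
        sigma_phys = np.sqrt(value / nm.gain)
        bound = nm.clamp_k * sigma_phys
        out[v] = value - np.clip(n_hat, -bound, bound)
    rec = dict(stack.seed_record)
    rec["denoise_clamp_k"] = nm.clamp_k
    return stack.copy_with(images=out, seed_record=rec)


def synthesize_sm(
    stack: ProjectionStack,
    vol: ReconVolume,
    k_central: int = 2,
    detail_weight: float = 0.5,
    detail_sigma_px: float = 1.0,
) -> np.ndarray:
    """Simplified synthetic mammogram from denoised projections + DBT stack.

    Background: weighted mean of the 2k+1 central projections (triangular
    weights) in the attenuation domain, which share in-plane indexing with
    the perspective volume.  Detail: per-pixel signed extremum across
    slices of each slice's fine band, alpha-blended on top.  A stand-in
    for the proprietary product algorithm; only property-level claims are
    made of it.
    """
    if vol.coordinate_system != "perspective":
        raise DomainError("synthesize_sm requires a perspective-coordinate volume")
    if stack.is_log_normalized:
        imgs = stack.images
    else:
        imgs = -np.log(np.clip(stack.images, 1e-9 * stack.air_reference, None)
                       / stack.air_reference)
    n = stack.n_views
    center = (n - 1) // 2
    lo, hi = max(0, center - k_central), min(n - 1, center + k_central)
    idx = np.arange(lo, hi + 1)
    w = (k_central + 1.0) - np.abs(idx - center)
    w = w / w.sum()
    background = np.tensordot(w, imgs[lo: hi + 1], axes=(0, 0))
    if detail_weight == 0.0:
        return background
    fine = np.empty_like(vol.slices)
    for iz in range(vol.slices.shape[0]):
        sl = vol.slices[iz]
        fine[iz] = sl - ndimage.gaussian_filter(sl, detail_sigma_px)
    pick = np.argmax(np.abs(fine), axis=0)
    detail = np.take_along_axis(fine, pick[None], axis=0)[0]
    return background + detail_weight * detail
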