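"""Image variants: Laplacian-of-Gaussian bandpass and wavelet approximation.

The LoG response is built by convolving with an analytically sampled
``grad^2 G`` kernel assembled from its three separable terms
(g''(x)g(y)g(z) + permutations).  The second-derivative 1D kernel is
re-centred to zero sum so a constant image maps exactly to zero (a bandpass
must kill DC); the correction is orders of magnitude below the kernel values.
Sigma is interpreted in mm and converted per-axis by the voxel spacing.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from ..datatypes import CTVolume
from .manifest import WAVELET_BASIS

__all__ = ["log_filter", "wavelet_approx", "image_variants"]

_TRUNCATE = 4.5  # kernel half-width in units of sigma


def _log_kernels_1d(sigma_vox: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Gaussian g and its analytic second derivative g'' (zero-sum)."""
    radius = max(1, int(np.ceil(_TRUNCATE * sigma_vox)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x ** 2) / (2.0 * sigma_vox ** 2)) / (np.sqrt(2.0 * np.pi) * sigma_vox)
    g2 = (x ** 2 / sigma_vox ** 4 - 1.0 / sigma_vox ** 2) * g
    g2 -= g2.sum() / g2.size  # exact DC rejection
    return g, g2


def log_filter(volume: CTVolume, sigma_mm: float) -> CTVolume:
    """Laplacian-of-Gaussian response at physical scale ``sigma_mm``."""
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    out = np.zeros_like(volume.values)
    kernels = [_log_kernels_1d(sigma_mm / s) for s in volume.spacing]
    for second_axis in range(3):
        term = volume.values
        for axis in range(3):
            g, g2 = kernels[axis]
            k = g2 if axis == second_axis else g
            term = ndimage.correlate1d(term, k, axis=axis, mode="nearest")
        out += term
    return CTVolume(out, volume.spacing, volume.origin)


def wavelet_approx(volume: CTVolume, basis: str = WAVELET_BASIS) -> CTVolume:
    """One-level 3D DWT approximation (low-pass) sub-band, reconstructed on
    the original grid with the detail sub-bands zeroed."""
    coeffs = pywt.dwtn(volume.values, basis, mode="symmetric")
    zeroed = {k: (v if k == "aaa" else np.zeros_like(v)) for k, v in coeffs.items()}
    rec = pywt.idwtn(zeroed, basis, mode="symmetric")
    rec = rec[tuple(slice(0, s) for s in volume.shape)]
    return CTVolume(rec, volume.spacing, volume.origin)


def image_variants(volume: CTVolume, log_sigmas_mm=(1.0, 1.5, 2.0, 2.5)) -> dict[str, CTVolume]:
    """The 6 image variants of the texture catalog, keyed by manifest name."""
    variants = {"original": volume, "wavelet_approx": wavelet_approx(volume)}
    for s in log_sigmas_mm:
        variants[f"log_sigma_{s:.1f}"] = log_filter(volume, s)
    return variants
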