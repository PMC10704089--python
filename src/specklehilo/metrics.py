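"""Image-quality and contrast metrics for validating reconstructions.

PSNR = 10 log10(peakval^2 / MSE) quantifies agreement with a ground-truth
reference (computed over the full stack as a single MSE for volumes);
because HiLo output units are arbitrary relative to the reference, the test
image is by default rescaled by a least-squares scalar fit before the MSE.
SSIM is the standard structural similarity index (scikit-image).  Speckle
contrast is std/mean in a region; SBR is the ratio of the mean intensity in
a signal mask to the mean in its circular surround annulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = ["MetricReport", "psnr", "ssim", "speckle_contrast", "sbr"]


@dataclass(frozen=True)
class MetricReport:
    """One computed metric value with optional provenance."""

    name: str
    value: float
    roi: Optional[str] = None
    reference: Optional[str] = None


def psnr(
    test: np.ndarray,
    reference: np.ndarray,
    peakval: Optional[float] = None,
    normalize: bool = True,
) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images.

    `peakval` defaults to the reference maximum.  With `normalize` the test
    image is first scaled by the least-squares factor <t, r>/<t, t> so
    arbitrary reconstruction units do not dominate the MSE; pass
    ``normalize=False`` to compare absolute values.
    """
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape:
        raise ValueError(f"test shape {test.shape} != reference shape {reference.shape}")
    if peakval is None:
        peakval = float(reference.max())
    if not peakval > 0:
        raise ValueError("peakval must be > 0")
    if normalize:
        tt = float(np.sum(test * test))
        if tt > 0:
            test = test * (float(np.sum(test * reference)) / tt)
    mse = float(np.mean((test - reference) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peakval**2 / mse)


def ssim(test: np.ndarray, reference: np.ndarray) -> float:
    """Structural similarity index in [-1, 1]; 1 for identical images."""
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape:
        raise ValueError(f"test shape {test.shape} != reference shape {reference.shape}")
    data_range = float(max(test.max(), reference.max()) - min(test.min(), reference.min()))
    if data_range == 0.0:
        return 1.0
    return float(structural_similarity(test, reference, data_range=data_range))


def speckle_contrast(image: np.ndarray, roi: Optional[np.ndarray] = None) -> float:
    """std/mean of the image within the (optional) boolean ROI."""
    image = np.asarray(image, dtype=float)
    values = image[np.asarray(roi, dtype=bool)] if roi is not None else image.ravel()
    if values.size == 0:
        raise ValueError("ROI selects no pixels")
    mean = float(values.mean())
    if mean <= 0:
        raise ValueError("contrast undefined for non-positive mean intensity")
    return float(values.std() / mean)


def sbr(image: np.ndarray, signal_mask: np.ndarray, background_radius_px: float) -> float:
    """Signal-to-background ratio: mean inside the mask over mean in its surround.

    The background region is the circular dilation of the signal mask by
    `background_radius_px`, excluding the mask itself.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(signal_mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("signal_mask shape must match image shape")
    if not mask.any():
        raise ValueError("signal mask is empty")
    r = int(np.ceil(background_radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    structure = (yy**2 + xx**2) <= background_radius_px**2
    surround = ndimage.binary_dilation(mask, structure=structure) & ~mask
    if not surround.any():
        raise ValueError("background annulus is empty")
    return float(image[mask].mean() / image[surround].mean())
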