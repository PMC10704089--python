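"""Frequency-domain filters for HiLo reconstruction.

HiLo separates an image into complementary low-pass and high-pass bands and
extracts sectioning information from speckle fluctuations isolated by a
zero-DC band-pass "wavelet" filter.  All transfer functions here live on the
normalized-frequency grid of a given image shape, where the sampling rate is
1 and the Nyquist frequency is |kappa| = 1/2.  Transfer arrays are stored in
the standard unshifted FFT sample layout (DC at index [0, 0]) so they can be
multiplied directly against ``numpy.fft.fft2`` output; the sample set is
identical to a centered grid.

The wavelet is a difference of Gaussians,

    W(kappa) = exp(-pi^2 kappa^2 sigma_w^2) - exp(-2 pi^2 kappa^2 sigma_w^2),

whose spatial-domain counterpart is

    W(rho) = exp(-rho^2/sigma_w^2)/(pi sigma_w^2)
             - exp(-rho^2/(2 sigma_w^2))/(2 pi sigma_w^2).

W(0) = 0, so the filter removes the local mean, and its global maximum is
exactly 1/4, attained at kappa = sqrt(ln 2)/(pi sigma_w) for every sigma_w.
sigma_w is conventionally set so the wavelet width is about one speckle
grain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaveletSpec",
    "FilterBank",
    "wavelet_transfer",
    "wavelet_peak_frequency",
    "make_wavelet",
    "make_wavelet_spatial",
    "make_lp_hp",
    "apply_filter",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Width parameter of the difference-of-Gaussians wavelet.

    Parameters
    ----------
    sigma_w : float
        Wavelet width in pixels.  The positive spatial lobe has a FWHM of
        about 1.67 * sigma_w; choose sigma_w so this matches the speckle
        grain size (slightly larger at low signal levels).
    """

    sigma_w: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_w) or self.sigma_w <= 0:
            raise ValueError(f"sigma_w must be a positive finite number, got {self.sigma_w!r}")

    @property
    def peak_frequency(self) -> float:
        """Normalized frequency at which the transfer function peaks (value 1/4)."""
        return wavelet_peak_frequency(self.sigma_w)


def wavelet_peak_frequency(sigma_w: float) -> float:
    """Frequency of the wavelet transfer-function maximum, sqrt(ln 2)/(pi sigma_w)."""
    return float(np.sqrt(np.log(2.0)) / (np.pi * sigma_w))


def wavelet_transfer(kappa, sigma_w: float):
    """Evaluate the band-pass transfer function W at normalized frequency kappa."""
    if sigma_w <= 0:
        raise ValueError("sigma_w must be positive")
    k2 = np.square(kappa)
    a = (np.pi * sigma_w) ** 2
    return np.exp(-a * k2) - np.exp(-2.0 * a * k2)


def _radial_frequency_grid(shape: tuple[int, int]) -> np.ndarray:
    """|kappa| on the unshifted FFT grid of `shape` (cycles per pixel, Nyquist 1/2)."""
    if len(shape) != 2 or shape[0] <= 0 or shape[1] <= 0:
        raise ValueError(f"shape must be two positive extents, got {shape!r}")
    ky = np.fft.fftfreq(shape[0])
    kx = np.fft.fftfreq(shape[1])
    return np.hypot(ky[:, None], kx[None, :])


def make_wavelet(shape: tuple[int, int], spec: WaveletSpec) -> np.ndarray:
    """Band-pass wavelet transfer function on the frequency grid of `shape`.

    W is real, non-negative for |kappa| <= 1/2, and exactly 0 at DC.
    """
    kk = _radial_frequency_grid(shape)
    return wavelet_transfer(kk, spec.sigma_w)


def make_wavelet_spatial(spec: WaveletSpec, radius_grid) -> np.ndarray:
    """Spatial-domain wavelet kernel evaluated at radii `radius_grid` (pixels).

    The two Gaussians are individually unit-normalized in 2D, so the kernel
    integrates to zero over the plane.  A warning is issued if the grid does
    not reach at least 4 sigma_w from the origin (documented truncation).
    """
    rho = np.asarray(radius_grid, dtype=float)
    if rho.size and np.max(np.abs(rho)) < 4.0 * spec.sigma_w:
        warnings.warn(
            "radius_grid does not cover +/- 4 sigma_w; the sampled kernel is "
            "truncated and its discrete integral will deviate from zero",
            stacklevel=2,
        )
    s2 = spec.sigma_w**2
    r2 = np.square(rho)
    return np.exp(-r2 / s2) / (np.pi * s2) - np.exp(-r2 / (2.0 * s2)) / (2.0 * np.pi * s2)


def make_lp_hp(shape: tuple[int, int], cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Complementary Gaussian low-pass / high-pass pair with crossover `cutoff`.

    LP(kappa) = exp(-kappa^2 / (2 cutoff^2)): unity at DC, exp(-1/2) at the
    cutoff frequency.  HP is formed as 1 - LP, so LP + HP == 1 holds exactly
    at every sample.
    """
    if not (0.0 < cutoff <= 0.5):
        raise ValueError(f"cutoff must lie in (0, 1/2], got {cutoff!r}")
    kk = _radial_frequency_grid(shape)
    lowpass = np.exp(-np.square(kk) / (2.0 * cutoff**2))
    highpass = 1.0 - lowpass
    return lowpass, highpass


@dataclass(frozen=True)
class FilterBank:
    """Wavelet band-pass plus complementary LP/HP pair on a shared frequency grid.

    Attributes
    ----------
    shape : tuple of int
        Image dimensions the transfer functions were built for.
    wavelet, lowpass, highpass : ndarray
        Real transfer functions in unshifted FFT layout.
    cutoff : float
        Normalized LP/HP crossover frequency.
    sigma_w : float
        Wavelet width used to build `wavelet`.
    """

    shape: tuple[int, int]
    wavelet: np.ndarray
    lowpass: np.ndarray
    highpass: np.ndarray
    cutoff: float
    sigma_w: float

    @classmethod
    def build(cls, shape, spec: WaveletSpec, cutoff="auto") -> "FilterBank":
        """Build all three transfer functions for an image of `shape`.

        With ``cutoff="auto"`` the LP/HP crossover is placed at the wavelet
        peak frequency sqrt(ln 2)/(pi sigma_w), tying the Hi/Lo split to the
        scale at which speckle contrast is measured.
        """
        shape = (int(shape[0]), int(shape[1]))
        if cutoff == "auto":
            cutoff = min(spec.peak_frequency, 0.5)
        cutoff = float(cutoff)
        lowpass, highpass = make_lp_hp(shape, cutoff)
        return cls(
            shape=shape,
            wavelet=make_wavelet(shape, spec),
            lowpass=lowpass,
            highpass=highpass,
            cutoff=cutoff,
            sigma_w=spec.sigma_w,
        )


def apply_filter(image: np.ndarray, transfer: np.ndarray) -> np.ndarray:
    """Apply a frequency-domain transfer function to a real image.

    Returns Re(IFFT(FFT(image) * transfer)).  Linear, shape preserving,
    circular boundary conditions (mirror-pad upstream if wrap-around matters).
    """
    image = np.asarray(image, dtype=float)
    if image.shape != transfer.shape:
        raise ValueError(f"image shape {image.shape} does not match transfer shape {transfer.shape}")
    return np.real(np.fft.ifft2(np.fft.fft2(image) * transfer))
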