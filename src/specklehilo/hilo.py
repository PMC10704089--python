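"""Core HiLo reconstruction: speckle contrast, Lo/Hi channels, fusion.

A HiLo image pair consists of a uniform-illumination frame Iu and a
speckle-illumination frame Is of the same scene.  In-focus structure keeps
the speckle modulation; defocused background washes it out.  The local
contrast of the wavelet-filtered difference image dI = Is - Iu,

    C(rho) = sigma[W * dI](rho) / <Iu>(rho),

therefore acts as a depth-discriminating weight.  The weighted image
Icu = C * Iu estimates the in-focus contribution; its low-pass part is fused
with the inherently sectioned high-pass part of Iu,

    IHiLo = eta * LP[Icu] + HP[Iu],

with eta chosen so the spectrum is seamless across the LP/HP crossover.
Optionally both channels are denoised first with guided non-local means:
Icu -> Icu~ and Iu -> Iu~ (similarity always measured in Iu).

Shot and readout noise bias the measured local variance of W * dI; the bias
is estimated from the camera model (gain g in ADU/e-, readout sigma_r in e-)
as [g*(<Is> + <Iu>) + 2*(g*sigma_r)^2] * T, where T is the fraction of white
noise power transmitted into the local variance estimator (wavelet power
minus the part absorbed by the local-mean window), and subtracted before the
square root.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .filters import FilterBank, WaveletSpec, apply_filter
from .nlm import NLMParams, guided_denoise_channels

__all__ = [
    "CameraModel",
    "ImagePair",
    "HiLoParams",
    "ContrastMap",
    "HiLoResult",
    "difference_image",
    "local_contrast",
    "weighted_infocus",
    "lo_component",
    "hi_component",
    "estimate_eta",
    "fuse",
    "reconstruct",
    "reconstruct_full",
    "reconstruct_variants",
]

_GAIN_UNITS = ("adu_per_e", "e_per_adu")


@dataclass(frozen=True)
class CameraModel:
    """Camera conversion gain and readout noise.

    Attributes
    ----------
    gain : float
        Conversion gain stored in ADU per photoelectron.
    read_noise_e : float
        Readout noise standard deviation in electrons (rms).
    offset_adu : float
        Constant dark level already present in raw frames; subtracted by
        the pipeline before reconstruction if nonzero.
    """

    gain: float
    read_noise_e: float = 0.0
    offset_adu: float = 0.0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("gain must be > 0")
        if self.read_noise_e < 0:
            raise ValueError("read_noise_e must be >= 0")

    @classmethod
    def from_gain(cls, value: float, units: str, read_noise_e: float = 0.0, offset_adu: float = 0.0) -> "CameraModel":
        """Build from a gain quoted either as ADU/e- or e-/ADU.

        Vendors quote both conventions (e.g. 2.5 ADU/e- or 0.46 e-/ADU);
        the explicit unit tag avoids silent reciprocal mistakes.
        """
        if units not in _GAIN_UNITS:
            raise ValueError(f"units must be one of {_GAIN_UNITS}, got {units!r}")
        if not value > 0:
            raise ValueError("gain must be > 0")
        gain = value if units == "adu_per_e" else 1.0 / value
        return cls(gain=gain, read_noise_e=read_noise_e, offset_adu=offset_adu)


@dataclass(frozen=True)
class ImagePair:
    """Co-registered uniform (Iu) and speckle (Is) frames in ADU.

    The unit of HiLo reconstruction.  Values must be non-negative (dark
    level already subtracted).  `camera` may be None for ideal noise-free
    data, in which case no noise-bias subtraction is performed.
    """

    uniform: np.ndarray
    speckle: np.ndarray
    camera: Optional[CameraModel] = None

    def __post_init__(self) -> None:
        uniform = np.asarray(self.uniform, dtype=float)
        speckle = np.asarray(self.speckle, dtype=float)
        if uniform.ndim != 2:
            raise ValueError("images must be 2D")
        if uniform.shape != speckle.shape:
            raise ValueError(f"uniform shape {uniform.shape} != speckle shape {speckle.shape}")
        if np.any(uniform < 0) or np.any(speckle < 0):
            raise ValueError("image values must be >= 0 (subtract the dark level first)")
        object.__setattr__(self, "uniform", uniform)
        object.__setattr__(self, "speckle", speckle)

    @property
    def shape(self) -> tuple[int, int]:
        return self.uniform.shape


@dataclass(frozen=True)
class HiLoParams:
    """Tunable parameters of the HiLo reconstruction.

    Parameters
    ----------
    wavelet : WaveletSpec
        Width of the contrast wavelet; match to the speckle grain.
    cutoff : float or "auto"
        Normalized LP/HP crossover frequency; "auto" uses the wavelet peak
        frequency.
    eta : float or "auto"
        Lo/Hi scaling factor; "auto" estimates it spectrally.
    local_stat_sigma : float or None
        Gaussian window width (pixels) for the local mean/variance in the
        contrast map; None uses 1/(2 pi cutoff), the Lo-band scale.
    clip_negative : bool
        Clip negative values of the fused image to 0.
    padding : "mirror" or "none"
        Mirror-pad the raw pair before FFT filtering to suppress wrap-around
        artifacts (cropped afterwards).
    """

    wavelet: WaveletSpec = WaveletSpec(2.0)
    cutoff: Union[float, str] = "auto"
    eta: Union[float, str] = "auto"
    local_stat_sigma: Optional[float] = None
    clip_negative: bool = True
    padding: str = "mirror"

    def __post_init__(self) -> None:
        if self.cutoff != "auto" and not (0 < float(self.cutoff) <= 0.5):
            raise ValueError("cutoff must be in (0, 1/2] or 'auto'")
        if self.eta != "auto" and not float(self.eta) > 0:
            raise ValueError("eta must be > 0 or 'auto'")
        if self.local_stat_sigma is not None and not self.local_stat_sigma > 0:
            raise ValueError("local_stat_sigma must be > 0 or None")
        if self.padding not in ("mirror", "none"):
            raise ValueError("padding must be 'mirror' or 'none'")


@dataclass(frozen=True)
class ContrastMap:
    """Local speckle-contrast weighting map C(rho).

    `values` is the non-negative contrast (bias-corrected standard deviation
    over local mean).  `variance` keeps the *signed* bias-corrected local
    variance before clipping, which is the quantity whose expectation
    vanishes on pure camera noise; it is exposed for noise diagnostics.
    """

    values: np.ndarray
    variance: np.ndarray


@dataclass(frozen=True)
class HiLoResult:
    """Full output of a HiLo reconstruction, intermediates included."""

    hilo: np.ndarray
    ilo: np.ndarray
    ihi: np.ndarray
    eta: float
    contrast: ContrastMap
    icu: np.ndarray
    icu_denoised: Optional[np.ndarray] = None
    iu_denoised: Optional[np.ndarray] = None


def difference_image(pair: ImagePair) -> np.ndarray:
    """dI = Is - Iu (may be negative)."""
    return pair.speckle - pair.uniform


def _gaussian_local(a: np.ndarray, sigma: float) -> np.ndarray:
    # 'wrap' keeps the statistics exactly circular, matching FFT filtering;
    # reconstruct() mirror-pads upstream so real borders are handled there.
    return ndimage.gaussian_filter(a, sigma, mode="wrap")


def _gaussian_transfer_sq(n: int, sigma: float) -> np.ndarray:
    """|DFT|^2 of the truncated discrete Gaussian kernel along one axis of length n."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    emb = np.zeros(n)
    for j, w in zip(range(-radius, radius + 1), k):
        emb[j % n] += w
    return np.abs(np.fft.fft(emb)) ** 2


def _noise_power_factor(bank: FilterBank, sigma: float) -> float:
    """White-noise variance transmission of the local-variance estimator.

    For unit-variance white noise filtered by W, the estimator
    V = G*F^2 - (G*F)^2 has expectation mean(W^2) - mean(W^2 G^2): the
    local-mean window G absorbs the noise power it can represent.  G here is
    the exact discrete transfer of the truncated Gaussian kernel.
    """
    gy2 = _gaussian_transfer_sq(bank.shape[0], sigma)
    gx2 = _gaussian_transfer_sq(bank.shape[1], sigma)
    w2 = bank.wavelet**2
    g2 = gy2[:, None] * gx2[None, :]
    return float(np.mean(w2 * (1.0 - g2)))


def _default_stat_sigma(params: HiLoParams, bank: FilterBank) -> float:
    if params.local_stat_sigma is not None:
        return params.local_stat_sigma
    return 1.0 / (2.0 * np.pi * bank.cutoff)


def _local_contrast_arrays(
    uniform: np.ndarray,
    speckle: np.ndarray,
    camera: Optional[CameraModel],
    bank: FilterBank,
    sigma: float,
) -> ContrastMap:
    if not np.any(uniform > 0):
        raise ValueError("uniform image is identically zero; no signal to normalize contrast by")
    filtered = apply_filter(speckle - uniform, bank.wavelet)
    mean_u = _gaussian_local(uniform, sigma)
    variance = _gaussian_local(filtered**2, sigma) - _gaussian_local(filtered, sigma) ** 2
    if camera is not None:
        mean_s = _gaussian_local(speckle, sigma)
        g = camera.gain
        white = g * (mean_s + mean_u) + 2.0 * (g * camera.read_noise_e) ** 2
        variance = variance - white * _noise_power_factor(bank, sigma)
    floor = max(np.finfo(float).tiny, 1e-6 * float(np.mean(uniform)))
    values = np.sqrt(np.clip(variance, 0.0, None)) / np.maximum(mean_u, floor)
    return ContrastMap(values=values, variance=variance)


def local_contrast(pair: ImagePair, params: HiLoParams, bank: FilterBank) -> ContrastMap:
    """Bias-corrected local speckle contrast C = sigma[W * dI] / <Iu>.

    Local moments use a Gaussian window of width `local_stat_sigma`; the
    shot/readout noise contribution predicted by the camera model (if any)
    is subtracted from the local variance, negatives are clipped to zero
    before the square root, and the local mean of Iu in the denominator is
    floored at a small positive epsilon.
    """
    if bank.shape != pair.shape:
        raise ValueError(f"filter bank shape {bank.shape} != pair shape {pair.shape}")
    sigma = _default_stat_sigma(params, bank)
    return _local_contrast_arrays(pair.uniform, pair.speckle, pair.camera, bank, sigma)


def weighted_infocus(pair: ImagePair, contrast: ContrastMap) -> np.ndarray:
    """Icu = C * Iu, the contrast-weighted in-focus estimate."""
    values = np.asarray(contrast.values, dtype=float)
    if values.shape != pair.shape:
        raise ValueError(f"contrast shape {values.shape} != pair shape {pair.shape}")
    return values * pair.uniform


def lo_component(icu: np.ndarray, bank: FilterBank) -> np.ndarray:
    """ILo = LP[Icu] (eta-free)."""
    return apply_filter(icu, bank.lowpass)


def hi_component(iu: np.ndarray, bank: FilterBank) -> np.ndarray:
    """IHi = HP[Iu]; zero mean, inherently optically sectioned."""
    return apply_filter(iu, bank.highpass)


def estimate_eta(ilo: np.ndarray, ihi: np.ndarray, bank: FilterBank) -> float:
    """Empirical Lo/Hi scaling factor from spectral matching at the crossover.

    Within the annulus 0.75*kc <= |kappa| <= 4/3*kc the amplitude spectra of
    IHi and ILo are each compensated by their own transfer function (HP, LP)
    to estimate the underlying object spectrum each channel saw; eta is the
    ratio of the band means, which makes eta * ILo + IHi spectrally seamless
    and returns exactly 1 when the channels are kappa-matched.
    """
    if ilo.shape != bank.shape or ihi.shape != bank.shape:
        raise ValueError("component shapes do not match the filter bank")
    ky = np.fft.fftfreq(bank.shape[0])
    kx = np.fft.fftfreq(bank.shape[1])
    kk = np.hypot(ky[:, None], kx[None, :])
    band = (kk >= 0.75 * bank.cutoff) & (kk <= (4.0 / 3.0) * bank.cutoff)
    if not np.any(band):
        raise ValueError("no frequency samples in the crossover band; supply eta manually")
    a_hi = np.abs(np.fft.fft2(ihi))[band] / bank.highpass[band]
    a_lo = np.abs(np.fft.fft2(ilo))[band] / bank.lowpass[band]
    denom = float(np.mean(a_lo))
    numer = float(np.mean(a_hi))
    if denom <= 0 or numer <= 0 or not np.isfinite(denom) or not np.isfinite(numer):
        raise ValueError("zero spectral power in the crossover band; supply eta manually")
    return numer / denom


def fuse(ilo: np.ndarray, ihi: np.ndarray, eta: float, clip_negative: bool = False) -> np.ndarray:
    """IHiLo = eta * ILo + IHi, optionally clipped at zero."""
    if ilo.shape != ihi.shape:
        raise ValueError(f"ILo shape {ilo.shape} != IHi shape {ihi.shape}")
    if not eta > 0:
        raise ValueError("eta must be > 0")
    out = eta * ilo + ihi
    return np.clip(out, 0.0, None) if clip_negative else out


_VARIANTS = ("basic", "nlm_lo", "nlm_hi", "nlm_both")


def _pad_width(params: HiLoParams, bank_cutoff: float, stat_sigma: float, shape) -> int:
    if params.padding == "none":
        return 0
    support = max(4.0 * params.wavelet.sigma_w, 4.0 / (2.0 * np.pi * bank_cutoff), 4.0 * stat_sigma)
    return int(min(np.ceil(support), min(shape) - 1))


def reconstruct_variants(
    pair: ImagePair,
    params: HiLoParams = HiLoParams(),
    nlm: Optional[NLMParams] = None,
    which: tuple[str, ...] = ("basic",),
    contrast: Optional[np.ndarray] = None,
) -> dict[str, HiLoResult]:
    """Run several denoising variants of one reconstruction, sharing work.

    `which` selects from "basic" (no NLM), "nlm_lo" (Icu denoised),
    "nlm_hi" (Iu denoised) and "nlm_both".  The contrast map, filters and
    NLM patch similarities are computed once; this is the natural entry
    point for channel-ablation comparisons.  `contrast` optionally overrides
    the computed contrast map (scalar or full array).
    """
    for v in which:
        if v not in _VARIANTS:
            raise ValueError(f"unknown variant {v!r}; choose from {_VARIANTS}")
    need_lo = any(v in ("nlm_lo", "nlm_both") for v in which)
    need_hi = any(v in ("nlm_hi", "nlm_both") for v in which)
    if (need_lo or need_hi) and nlm is None:
        raise ValueError("NLM variants requested but nlm parameters are None")

    # Probe bank to resolve 'auto' cutoff, then pad and rebuild at full size.
    probe = FilterBank.build(pair.shape, params.wavelet, params.cutoff)
    stat_sigma = _default_stat_sigma(params, probe)
    pad = _pad_width(params, probe.cutoff, stat_sigma, pair.shape)
    iu = np.pad(pair.uniform, pad, mode="reflect") if pad else pair.uniform
    is_ = np.pad(pair.speckle, pad, mode="reflect") if pad else pair.speckle
    bank = FilterBank.build(iu.shape, params.wavelet, probe.cutoff)

    if contrast is None:
        cmap = _local_contrast_arrays(iu, is_, pair.camera, bank, stat_sigma)
    else:
        values = np.broadcast_to(np.asarray(contrast, dtype=float), pair.shape)
        values = np.pad(values, pad, mode="reflect") if pad else values
        cmap = ContrastMap(values=values, variance=np.square(values))
    icu = cmap.values * iu

    denoised: dict[str, np.ndarray] = {}
    if need_lo or need_hi:
        targets: dict[str, tuple[np.ndarray, float]] = {}
        if need_lo:
            targets["lo"] = (icu, nlm.h_lo)
        if need_hi:
            targets["hi"] = (iu, nlm.h_hi)
        denoised = guided_denoise_channels(iu, targets, nlm.patch_halfwidth, nlm.search_halfwidth)

    def crop(a: np.ndarray) -> np.ndarray:
        return a[pad : a.shape[0] - pad, pad : a.shape[1] - pad] if pad else a

    results: dict[str, HiLoResult] = {}
    for v in which:
        icu_v = denoised["lo"] if v in ("nlm_lo", "nlm_both") else icu
        iu_v = denoised["hi"] if v in ("nlm_hi", "nlm_both") else iu
        ilo = apply_filter(icu_v, bank.lowpass)
        ihi = apply_filter(iu_v, bank.highpass)
        eta = float(params.eta) if params.eta != "auto" else estimate_eta(ilo, ihi, bank)
        out = fuse(ilo, ihi, eta, clip_negative=params.clip_negative)
        results[v] = HiLoResult(
            hilo=crop(out),
            ilo=crop(ilo),
            ihi=crop(ihi),
            eta=eta,
            contrast=ContrastMap(values=crop(cmap.values), variance=crop(cmap.variance)),
            icu=crop(icu),
            icu_denoised=crop(denoised["lo"]) if "lo" in denoised else None,
            iu_denoised=crop(denoised["hi"]) if "hi" in denoised else None,
        )
    return results


def _variant_for(nlm: Optional[NLMParams]) -> str:
    if nlm is None:
        return "basic"
    return {"lo": "nlm_lo", "hi": "nlm_hi", "both": "nlm_both"}[nlm.channels]


def reconstruct_full(
    pair: ImagePair,
    params: HiLoParams = HiLoParams(),
    nlm: Optional[NLMParams] = None,
    contrast: Optional[np.ndarray] = None,
) -> HiLoResult:
    """Reconstruct one pair, returning the fused image and all intermediates."""
    variant = _variant_for(nlm)
    return reconstruct_variants(pair, params, nlm, which=(variant,), contrast=contrast)[variant]


def reconstruct(
    pair: ImagePair,
    params: HiLoParams = HiLoParams(),
    nlm: Optional[NLMParams] = None,
    contrast: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Optically sectioned HiLo image from a uniform/speckle pair.

    With `nlm` given, Icu and/or Iu are NLM-denoised (per `nlm.channels`)
    before the LP/HP split.  Deterministic given its inputs.
    """
    return reconstruct_full(pair, params, nlm, contrast=contrast).hilo
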