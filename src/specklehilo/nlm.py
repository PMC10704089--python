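"""Guided non-local-means denoising with Poisson patch similarity.

Residual speckle noise in the contrast-weighted image Icu is suppressed by
averaging pixels whose surrounding patches look alike in the *uniform*
illumination image Iu (the guide), which carries the same structure but no
speckle.  Patch similarity is the generalized likelihood ratio (GLR) for two
Poisson observations,

    LG(I1, I2) = (I1+I2)^(I1+I2) / (2^(I1+I2) * I1^I1 * I2^I2),

with the convention 0^0 = 1.  LG = 1 iff I1 = I2 and lies in (0, 1)
otherwise.  Patch log-likelihood is the sum of log LG over a (2N+1)^2 patch;
weights are w = exp(L/h) with a filtering parameter h, and the denoised
value is the w-weighted average of the target over a (2Ny+1)^2 search
window (self pixel included, weight exactly 1).

The same weights can be applied to two targets with different h (the Lo
channel target Icu and the Hi channel target Iu); `guided_denoise_channels`
shares the patch-similarity computation across channels.

Everything is computed in log space; intensities need not be integers (the
GLR is evaluated with real-valued exponents, x*ln x with 0*ln 0 := 0), but
note the statistic is calibrated for Poisson-scale counts: multiplying the
guide by c multiplies L by c, so h absorbs the camera gain / intensity scale.

`nlm_denoise` is a vectorized implementation; `nlm_denoise_reference` is a
literal per-pixel loop transcription used as the correctness oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "NLMParams",
    "GuidedDenoiseRequest",
    "glr_pixel",
    "log_glr",
    "patch_log_likelihood",
    "nlm_weights",
    "nlm_denoise",
    "nlm_denoise_reference",
    "guided_denoise_channels",
]

_CHANNELS = ("lo", "hi", "both")


@dataclass(frozen=True)
class NLMParams:
    """Patch/search geometry and filtering strengths for guided NLM.

    Parameters
    ----------
    patch_halfwidth : int
        N; patches are (2N+1) x (2N+1) pixels.  Default 1 (3x3), about one
        speckle grain per patch.
    search_halfwidth : int
        Ny; search windows are (2Ny+1) x (2Ny+1) pixels.  Default 10 (21x21),
        mid-range: larger windows average more uncorrelated speckle at higher
        cost.
    h_lo : float
        Filtering parameter h for the Lo-channel target Icu.  Larger h
        averages more aggressively.  Typical 5-20 on photoelectron-scale
        intensities.
    h_hi : float
        Filtering parameter h' for the Hi-channel target Iu; kept small
        (typical 0.4-0.6 on unit-gain photon counts) so resolution is
        preserved.
    channels : str
        Which channels receive denoising inside the reconstruction
        pipeline: "lo", "hi" or "both".
    """

    patch_halfwidth: int = 1
    search_halfwidth: int = 10
    h_lo: float = 10.0
    h_hi: float = 0.5
    channels: str = "both"

    def __post_init__(self) -> None:
        if self.patch_halfwidth < 0:
            raise ValueError("patch_halfwidth must be >= 0")
        if self.search_halfwidth < self.patch_halfwidth:
            raise ValueError("search_halfwidth must be >= patch_halfwidth")
        if not (self.h_lo > 0 and self.h_hi > 0):
            raise ValueError("filtering parameters h_lo and h_hi must be > 0")
        if self.channels not in _CHANNELS:
            raise ValueError(f"channels must be one of {_CHANNELS}, got {self.channels!r}")


@dataclass(frozen=True)
class GuidedDenoiseRequest:
    """One guided-denoise job: similarity from `guide`, averaging of `target`.

    `channel` selects which filtering parameter of `params` applies:
    "lo" -> h_lo (target is typically Icu), "hi" -> h_hi (target Iu).
    """

    guide: np.ndarray
    target: np.ndarray
    params: NLMParams
    channel: str = "lo"

    def __post_init__(self) -> None:
        guide = np.asarray(self.guide, dtype=float)
        target = np.asarray(self.target, dtype=float)
        if guide.ndim != 2:
            raise ValueError("guide must be a 2D array")
        if guide.shape != target.shape:
            raise ValueError(f"guide shape {guide.shape} != target shape {target.shape}")
        if np.any(guide < 0):
            raise ValueError("guide values must be non-negative (Poisson-like counts)")
        if self.channel not in ("lo", "hi"):
            raise ValueError("channel must be 'lo' or 'hi'")
        object.__setattr__(self, "guide", guide)
        object.__setattr__(self, "target", target)

    @property
    def h(self) -> float:
        return self.params.h_lo if self.channel == "lo" else self.params.h_hi


def log_glr(i1, i2):
    """log LG for non-negative intensities; elementwise on arrays.

    Uses the rearrangement log LG = -[i1*log(2*i1/s) + i2*log(2*i2/s)] with
    s = i1 + i2, which is exactly 0 in floating point when i1 == i2 and
    handles the 0^0 = 1 convention via 0*log(...) := 0.
    """
    a = np.asarray(i1, dtype=float)
    b = np.asarray(i2, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("intensities must be non-negative")
    out = _log_glr_arrays(a, b)
    if np.isscalar(i1) and np.isscalar(i2):
        return float(out)
    return out


def _log_glr_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise log LG; inputs assumed validated non-negative floats."""
    s = a + b
    safe = np.where(s > 0, s, 1.0)
    ra = np.where(a > 0, (2.0 * a) / safe, 1.0)
    rb = np.where(b > 0, (2.0 * b) / safe, 1.0)
    return -(a * np.log(ra) + b * np.log(rb))


def glr_pixel(i1, i2):
    """Pixel-wise generalized likelihood ratio LG in (0, 1]; 1 iff i1 == i2."""
    out = np.exp(log_glr(i1, i2))
    if np.isscalar(i1) and np.isscalar(i2):
        return float(out)
    return out


def _pad(a: np.ndarray, width: int) -> np.ndarray:
    return np.pad(a, width, mode="reflect") if width else np.asarray(a, dtype=float)


def patch_log_likelihood(guide: np.ndarray, x1, x2, patch_halfwidth: int) -> float:
    """Sum of log LG over all (2N+1)^2 patch offsets around pixels x1 and x2.

    Coordinates are (row, col) into the unpadded guide; the guide is
    mirror-padded by N so border patches are complete.  The result is <= 0,
    symmetric in (x1, x2), and 0 iff the two patches are identical.
    """
    guide = np.asarray(guide, dtype=float)
    n = int(patch_halfwidth)
    h, w = guide.shape
    for (y, x) in (x1, x2):
        if not (0 <= y < h and 0 <= x < w):
            raise IndexError(f"coordinate {(y, x)} outside image of shape {guide.shape}")
    gp = _pad(guide, n)
    total = 0.0
    for dy in range(-n, n + 1):
        for dx in range(-n, n + 1):
            a = gp[n + x1[0] + dy, n + x1[1] + dx]
            b = gp[n + x2[0] + dy, n + x2[1] + dx]
            total += float(_log_glr_arrays(np.float64(a), np.float64(b)))
    return total


def nlm_weights(guide: np.ndarray, x1, params: NLMParams, h: float) -> np.ndarray:
    """Weight field w = exp(L/h) over the search window centered on x1.

    Returns a (2Ny+1, 2Ny+1) array indexed by window offset; the center
    entry (self weight) is exactly 1.
    """
    if not h > 0:
        raise ValueError("filtering parameter h must be > 0")
    guide = np.asarray(guide, dtype=float)
    n, ny = params.patch_halfwidth, params.search_halfwidth
    pad = n + ny
    gp = _pad(guide, pad)
    y0, x0 = pad + x1[0], pad + x1[1]
    if not (0 <= x1[0] < guide.shape[0] and 0 <= x1[1] < guide.shape[1]):
        raise IndexError(f"coordinate {tuple(x1)} outside image of shape {guide.shape}")
    out = np.empty((2 * ny + 1, 2 * ny + 1))
    ref = gp[y0 - n : y0 + n + 1, x0 - n : x0 + n + 1]
    for dy in range(-ny, ny + 1):
        for dx in range(-ny, ny + 1):
            cand = gp[y0 + dy - n : y0 + dy + n + 1, x0 + dx - n : x0 + dx + n + 1]
            out[dy + ny, dx + ny] = math.exp(float(np.sum(_log_glr_arrays(ref, cand))) / h)
    return out


def guided_denoise_channels(
    guide: np.ndarray,
    targets: dict[str, tuple[np.ndarray, float]],
    patch_halfwidth: int,
    search_halfwidth: int,
) -> dict[str, np.ndarray]:
    """Denoise several targets with shared patch similarities from one guide.

    `targets` maps a channel name to (target_array, h).  The patch
    log-likelihood maps are computed once per search offset and reused for
    every channel, which is how the Lo (h) and Hi (h') channels of HiLo can
    be denoised for little more than the cost of one.
    """
    guide = np.asarray(guide, dtype=float)
    if np.any(guide < 0):
        raise ValueError("guide values must be non-negative")
    n, ny = int(patch_halfwidth), int(search_halfwidth)
    if ny < n or n < 0:
        raise ValueError("need search_halfwidth >= patch_halfwidth >= 0")
    hh, ww = guide.shape
    pad = n + ny
    gp = _pad(guide, pad)
    names = list(targets)
    tps = {}
    for name in names:
        target, h = targets[name]
        target = np.asarray(target, dtype=float)
        if target.shape != guide.shape:
            raise ValueError(f"target {name!r} shape {target.shape} != guide shape {guide.shape}")
        if not h > 0:
            raise ValueError(f"h for channel {name!r} must be > 0")
        tps[name] = _pad(target, ny)
    nums = {name: np.zeros((hh, ww)) for name in names}
    dens = {name: np.zeros((hh, ww)) for name in names}
    # Loop order (search offsets outer, patch offsets inner, both row-major)
    # matches the reference kernel so partial sums accumulate identically.
    for dy in range(-ny, ny + 1):
        for dx in range(-ny, ny + 1):
            L = np.zeros((hh, ww))
            for py in range(-n, n + 1):
                for px in range(-n, n + 1):
                    a = gp[pad + py : pad + py + hh, pad + px : pad + px + ww]
                    b = gp[pad + py + dy : pad + py + dy + hh, pad + px + dx : pad + px + dx + ww]
                    L += _log_glr_arrays(a, b)
            for name in names:
                h = targets[name][1]
                w = np.exp(L / h)
                t = tps[name][ny + dy : ny + dy + hh, ny + dx : ny + dx + ww]
                nums[name] += w * t
                dens[name] += w
    return {name: nums[name] / dens[name] for name in names}


def nlm_denoise(req: GuidedDenoiseRequest) -> np.ndarray:
    """Guided NLM weighted average of `req.target` over the search window.

    Output values are convex combinations of target values within each
    pixel's window, so they never leave the local [min, max] range.
    """
    out = guided_denoise_channels(
        req.guide,
        {req.channel: (req.target, req.h)},
        req.params.patch_halfwidth,
        req.params.search_halfwidth,
    )
    return out[req.channel]


@njit(cache=False)
def _log_glr_scalar(a: float, b: float) -> float:
    s = a + b
    if s <= 0.0:
        return 0.0
    la = a * math.log((2.0 * a) / s) if a > 0.0 else 0.0
    lb = b * math.log((2.0 * b) / s) if b > 0.0 else 0.0
    return -(la + lb)


@njit(cache=False)
def _reference_kernel(gp, tp, hh, ww, n, ny, h):
    pad = n + ny
    out = np.empty((hh, ww))
    for y in range(hh):
        for x in range(ww):
            num = 0.0
            den = 0.0
            for dy in range(-ny, ny + 1):
                for dx in range(-ny, ny + 1):
                    L = 0.0
                    for py in range(-n, n + 1):
                        for px in range(-n, n + 1):
                            a = gp[pad + y + py, pad + x + px]
                            b = gp[pad + y + py + dy, pad + x + px + dx]
                            L += _log_glr_scalar(a, b)
                    w = math.exp(L / h)
                    num += w * tp[ny + y + dy, ny + x + dx]
                    den += w
            out[y, x] = num / den
    return out


def nlm_denoise_reference(req: GuidedDenoiseRequest) -> np.ndarray:
    """Literal quadruple-loop guided NLM; the testing oracle for nlm_denoise.

    Iterates pixels, search offsets and patch offsets exactly as written in
    the defining sums, with no vectorization tricks.  Compiled with numba
    for tractable runtimes; the arithmetic is the plain transcription.
    """
    n, ny = req.params.patch_halfwidth, req.params.search_halfwidth
    gp = _pad(req.guide, n + ny)
    tp = _pad(req.target, ny)
    hh, ww = req.guide.shape
    return _reference_kernel(gp, tp, hh, ww, n, ny, float(req.h))
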