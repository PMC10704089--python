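"""Forward simulator of widefield uniform/speckle image pairs.

Generates ground-truth-paired synthetic data for exercising and validating
the HiLo reconstruction: a 3D fluorophore density is imaged plane by plane
through a Gaussian widefield PSF whose lateral width grows with defocus,
once under uniform illumination and once modulated by a fully developed
laser speckle pattern; shot noise and readout noise are then applied with
an explicit camera model.

The speckle pattern is built as the intensity of a random-phase field
band-limited by a circular pupil, which gives exponential intensity
statistics (contrast std/mean = 1).  The illumination speckle is modeled as
a single static pattern; defocused planes lose imaged speckle contrast
through detection-side blur, which is the contrast-decay mechanism HiLo
sectioning relies on (axial decorrelation of the illumination speckle
itself is not modeled).

The defocus-dependent PSF width follows the Gaussian-beam approximation
sigma(dz) = sigma0 * sqrt(1 + (dz/zR)^2) with sigma0 = 0.21 * lambda / NA
and zR = n * lambda / NA^2.  This is adequate for reproducing contrast
decay; it is not a rigorous diffraction PSF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .hilo import CameraModel, ImagePair

__all__ = [
    "PSFModel",
    "SpeckleField",
    "SyntheticScene",
    "generate_speckle",
    "defocus_speckle",
    "render_pair",
    "render_stack",
    "make_rotated_background_target",
    "make_phantom",
    "make_test_target",
    "DEFAULT_CAMERA",
]

# Simulation-default camera: gain 2.5 ADU/e-, readout 1.6 e- rms.
DEFAULT_CAMERA = CameraModel(gain=2.5, read_noise_e=1.6)


@dataclass(frozen=True)
class PSFModel:
    """Lateral Gaussian PSF with defocus-dependent width.

    Parameters
    ----------
    na : float
        Numerical aperture, 0 < NA < 1.5.
    wavelength_um : float
        Emission wavelength in microns.
    n_medium : float
        Immersion refractive index (1.33 for water).
    """

    na: float = 0.8
    wavelength_um: float = 0.52
    n_medium: float = 1.33

    def __post_init__(self) -> None:
        if not (0.0 < self.na < 1.5):
            raise ValueError("numerical aperture must be in (0, 1.5)")
        if not self.wavelength_um > 0:
            raise ValueError("wavelength must be > 0")

    @property
    def sigma0_um(self) -> float:
        """In-focus lateral Gaussian width, 0.21 * lambda / NA."""
        return 0.21 * self.wavelength_um / self.na

    @property
    def rayleigh_range_um(self) -> float:
        """Axial scale of defocus broadening, n * lambda / NA^2."""
        return self.n_medium * self.wavelength_um / self.na**2

    def sigma_px(self, dz_um: float, pixel_size_um: float) -> float:
        """Lateral width in pixels at defocus dz."""
        s = self.sigma0_um * np.sqrt(1.0 + (dz_um / self.rayleigh_range_um) ** 2)
        return float(s / pixel_size_um)


@dataclass(frozen=True)
class SpeckleField:
    """A speckle intensity modulation pattern, normalized to mean 1."""

    pattern: np.ndarray
    grain_size_px: float
    seed: Optional[int] = None

    @property
    def contrast(self) -> float:
        """std/mean of the pattern; ~1 for fully developed speckle at focus."""
        return float(np.std(self.pattern) / np.mean(self.pattern))


@dataclass(frozen=True)
class SyntheticScene:
    """3D fluorophore density plus the optics needed to image it.

    `object_stack` has shape (planes, rows, cols) in arbitrary density
    units; `focus_index` selects the in-focus plane.
    """

    object_stack: np.ndarray
    pixel_size_um: float = 0.2
    z_step_um: float = 3.0
    psf: PSFModel = field(default_factory=PSFModel)
    focus_index: int = 0

    def __post_init__(self) -> None:
        stack = np.asarray(self.object_stack, dtype=float)
        if stack.ndim != 3 or stack.shape[0] < 1:
            raise ValueError("object_stack must be (planes, rows, cols) with >= 1 plane")
        if np.any(stack < 0):
            raise ValueError("fluorophore densities must be >= 0")
        if not (0 <= self.focus_index < stack.shape[0]):
            raise ValueError("focus_index out of range")
        object.__setattr__(self, "object_stack", stack)

    @property
    def n_planes(self) -> int:
        return self.object_stack.shape[0]

    def with_focus(self, focus_index: int) -> "SyntheticScene":
        return SyntheticScene(
            self.object_stack, self.pixel_size_um, self.z_step_um, self.psf, focus_index
        )


def generate_speckle(shape: tuple[int, int], grain_size_px: float, seed: Optional[int] = None) -> SpeckleField:
    """Fully developed speckle: |FFT of a pupil-masked random-phase field|^2.

    The pupil is a disk of radius 1/(2*grain_size_px) in normalized
    frequency; grains below 2 px would alias the intensity spectrum past
    Nyquist and are rejected.  The pattern is periodic (FFT-synthesized),
    normalized to mean 1, and deterministic given the seed.
    """
    if grain_size_px < 2.0:
        raise ValueError("grain_size_px must be >= 2 (sampling limit)")
    rng = np.random.default_rng(seed)
    ky = np.fft.fftfreq(shape[0])
    kx = np.fft.fftfreq(shape[1])
    pupil = np.hypot(ky[:, None], kx[None, :]) <= 1.0 / (2.0 * grain_size_px)
    phase = np.exp(2j * np.pi * rng.random(shape))
    amplitude = np.fft.ifft2(pupil * phase)
    intensity = np.abs(amplitude) ** 2
    intensity /= intensity.mean()
    return SpeckleField(pattern=intensity, grain_size_px=float(grain_size_px), seed=seed)


def _blur(a: np.ndarray, sigma_px: float) -> np.ndarray:
    # periodic boundary: consistent with the FFT-synthesized speckle and
    # exactly flux-conserving
    if sigma_px <= 0:
        return np.array(a, dtype=float, copy=True)
    return ndimage.gaussian_filter(np.asarray(a, dtype=float), sigma_px, mode="wrap")


def defocus_speckle(
    field: SpeckleField, dz_um: float, psf: PSFModel, pixel_size_um: float = 0.2
) -> SpeckleField:
    """Imaged speckle at defocus dz: pattern blurred by the detection PSF.

    The in-focus PSF width is already baked into the generated pattern's
    grain, so only the excess defocus broadening
    sqrt(sigma(dz)^2 - sigma0^2) = sigma0*|dz|/zR is applied; dz = 0 returns
    the pattern unchanged.  Contrast is non-increasing in |dz|; the mean
    stays 1 exactly.
    """
    sigma = psf.sigma0_um * abs(dz_um) / psf.rayleigh_range_um / pixel_size_um
    return SpeckleField(
        pattern=_blur(field.pattern, sigma),
        grain_size_px=field.grain_size_px,
        seed=field.seed,
    )


def render_pair(
    scene: SyntheticScene,
    speckle: SpeckleField,
    camera: Optional[CameraModel] = None,
    photons_peak: float = 1000.0,
    seed: Optional[int] = None,
    focus_offset_um: float = 0.0,
    photons_per_unit: Optional[float] = None,
) -> tuple[ImagePair, np.ndarray]:
    """Render one uniform/speckle pair plus its noise-free in-focus image.

    Each object plane is blurred by the PSF at its defocus from the focal
    plane and summed; the speckle frame modulates each plane by the common
    illumination pattern before blurring.  Expected photon counts are scaled
    so the brightest uniform-image pixel collects `photons_peak` photons
    (or by the explicit `photons_per_unit` scale, used when several focal
    positions must share one normalization); Poisson shot noise and
    Gaussian readout noise are then applied through the camera model.

    Returns ``(pair, ground_truth)`` where ground_truth is the noise-free
    in-focus plane image in expected-ADU units.
    """
    camera = camera if camera is not None else DEFAULT_CAMERA
    stack = scene.object_stack
    if stack.shape[1:] != speckle.pattern.shape:
        raise ValueError(
            f"scene lateral shape {stack.shape[1:]} != speckle shape {speckle.pattern.shape}"
        )
    if photons_per_unit is None and not photons_peak > 0:
        raise ValueError("photons_peak must be > 0")
    rng = np.random.default_rng(seed)

    uniform = np.zeros(stack.shape[1:])
    speckled = np.zeros(stack.shape[1:])
    for j in range(scene.n_planes):
        dz = (j - scene.focus_index) * scene.z_step_um + focus_offset_um
        sigma = scene.psf.sigma_px(abs(dz), scene.pixel_size_um)
        uniform += _blur(stack[j], sigma)
        speckled += _blur(stack[j] * speckle.pattern, sigma)

    scale = photons_per_unit if photons_per_unit is not None else photons_peak / uniform.max()
    uniform *= scale
    speckled *= scale

    g, rn = camera.gain, camera.read_noise_e
    adu_u = g * rng.poisson(uniform) + rng.normal(0.0, g * rn, uniform.shape)
    adu_s = g * rng.poisson(speckled) + rng.normal(0.0, g * rn, speckled.shape)
    pair = ImagePair(np.clip(adu_u, 0.0, None), np.clip(adu_s, 0.0, None), camera)

    in_focus_sigma = scene.psf.sigma_px(abs(focus_offset_um), scene.pixel_size_um)
    ground_truth = g * scale * _blur(stack[scene.focus_index], in_focus_sigma)
    return pair, ground_truth


def render_stack(
    scene: SyntheticScene,
    speckle: SpeckleField,
    camera: Optional[CameraModel] = None,
    photons_peak: float = 1000.0,
    seed: Optional[int] = None,
) -> tuple[list[ImagePair], np.ndarray]:
    """Render a through-focus series: one pair per focal plane of the scene.

    A single photon scale is shared across planes so `photons_peak` is the
    maximum expected photon count over the whole uniform stack, and the
    speckle pattern is the same static realization for every plane (as with
    a fixed diffuser).  Returns the list of pairs (shallow to deep) and the
    noise-free in-focus stack in expected-ADU units.
    """
    camera = camera if camera is not None else DEFAULT_CAMERA
    peaks = []
    for z in range(scene.n_planes):
        focused = scene.with_focus(z)
        uniform = np.zeros(scene.object_stack.shape[1:])
        for j in range(scene.n_planes):
            dz = (j - z) * scene.z_step_um
            uniform += _blur(scene.object_stack[j], scene.psf.sigma_px(abs(dz), scene.pixel_size_um))
        peaks.append(uniform.max())
    scale = photons_peak / max(peaks)

    rng = np.random.default_rng(seed)
    pairs = []
    truths = []
    for z in range(scene.n_planes):
        child_seed = int(rng.integers(0, 2**31 - 1))
        pair, gt = render_pair(
            scene.with_focus(z),
            speckle,
            camera,
            seed=child_seed,
            photons_per_unit=scale,
        )
        pairs.append(pair)
        truths.append(gt)
    return pairs, np.stack(truths)


def make_rotated_background_target(
    base_image: np.ndarray,
    dz_um: float = 10.0,
    pixel_size_um: float = 0.2,
    psf: Optional[PSFModel] = None,
) -> SyntheticScene:
    """Two-plane test scene: in-focus base plus the same image rotated 180 deg.

    The rotated copy sits `dz_um` out of focus and plays the role of a
    structured out-of-focus background with known geometry, so in-focus and
    background-only regions can be masked exactly.
    """
    base = np.asarray(base_image, dtype=float)
    if base.ndim != 2 or np.any(base < 0):
        raise ValueError("base_image must be a non-negative 2D array")
    stack = np.stack([base, base[::-1, ::-1]])
    return SyntheticScene(
        object_stack=stack,
        pixel_size_um=pixel_size_um,
        z_step_um=dz_um,
        psf=psf if psf is not None else PSFModel(),
        focus_index=0,
    )


def make_test_target(shape: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Deterministic resolution-style test image in [0, 1].

    A large filled disk (uniform-intensity region for noise statistics),
    line groups at several pitches, and small squares, placed asymmetrically
    so the 180-degree rotation differs from the original.
    """
    h, w = shape
    img = np.zeros(shape)
    yy, xx = np.mgrid[0:h, 0:w]
    # uniform disk, upper-left quadrant
    cy, cx, r = h * 0.30, w * 0.30, min(h, w) * 0.16
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 0.8
    # vertical line groups at two pitches, right half
    for pitch, x0 in ((6, int(w * 0.60)), (12, int(w * 0.80))):
        for k in range(5):
            x = x0 + k * pitch
            img[int(h * 0.10) : int(h * 0.45), x : x + max(2, pitch // 3)] = 1.0
    # small squares, lower band
    for k in range(4):
        y0 = int(h * 0.65)
        x0 = int(w * (0.15 + 0.18 * k))
        s = 6 + 3 * k
        img[y0 : y0 + s, x0 : x0 + s] = 0.9
    return img


def _bead_phantom(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    nz, h, w = shape
    stack = np.zeros(shape)
    zz, yy, xx = np.mgrid[0:nz, 0:h, 0:w].astype(float)
    n_beads = max(6, (h * w * nz) // 4000)
    for _ in range(n_beads):
        cz = rng.uniform(0, nz - 1)
        cy = rng.uniform(0.1 * h, 0.9 * h)
        cx = rng.uniform(0.1 * w, 0.9 * w)
        r_lat = rng.uniform(2.0, 6.0)
        r_ax = rng.uniform(0.5, 1.2)
        amp = rng.uniform(0.4, 1.0)
        stack += amp * np.exp(
            -(((zz - cz) / r_ax) ** 2 + ((yy - cy) / r_lat) ** 2 + ((xx - cx) / r_lat) ** 2)
        )
    return stack


def _shell_phantom(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    nz, h, w = shape
    zz, yy, xx = np.mgrid[0:nz, 0:h, 0:w].astype(float)
    # anisotropic normalized radius so the shell spans the volume
    rho = np.sqrt(
        ((zz - (nz - 1) / 2) / max(nz / 2.0, 1.0)) ** 2
        + ((yy - (h - 1) / 2) / (h * 0.35)) ** 2
        + ((xx - (w - 1) / 2) / (w * 0.35)) ** 2
    )
    shell = np.exp(-(((rho - 1.0) / 0.12) ** 2))
    shell[rho > 1.35] = 0.0
    shell[rho < 0.65] = 0.0
    texture = 0.5 + 0.5 * rng.random(shape)
    return shell * texture


def _grid_phantom(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    nz, h, w = shape
    stack = np.zeros(shape)
    mid = nz // 2
    grid = np.zeros((h, w))
    grid[:, ::16] = 1.0
    grid[::16, :] = 1.0
    stack[mid] = grid
    for z in range(nz):
        if z != mid:
            stack[z] = 0.15 * (0.5 + 0.5 * rng.random((h, w)))
    return stack


_PHANTOMS = {"beads": _bead_phantom, "shell": _shell_phantom, "grid": _grid_phantom}


def make_phantom(
    kind: str,
    shape: tuple[int, int, int],
    seed: Optional[int] = None,
    pixel_size_um: float = 0.2,
    z_step_um: float = 3.0,
    psf: Optional[PSFModel] = None,
) -> SyntheticScene:
    """Procedural 3D phantom scene ("beads", "shell" or "grid").

    Deterministic given the seed; stands in for real volumetric specimens
    (synthetic).  `shape` is (planes, rows, cols); focus defaults to the
    middle plane.
    """
    if kind not in _PHANTOMS:
        raise ValueError(f"unknown phantom kind {kind!r}; choose from {sorted(_PHANTOMS)}")
    rng = np.random.default_rng(seed)
    stack = _PHANTOMS[kind](tuple(int(s) for s in shape), rng)
    return SyntheticScene(
        object_stack=stack,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        psf=psf if psf is not None else PSFModel(),
        focus_index=shape[0] // 2,
    )
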