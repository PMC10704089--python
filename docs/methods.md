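# Methods

This note documents the models, estimators and numerical choices behind
`specklehilo`, what the synthetic-data generator does and does not emulate,
and the problem sizes at which the packaged validations run.

## Reconstruction model

Two co-registered frames of the same scene are acquired: `Iu` under
uniform illumination and `Is` under a static laser speckle pattern, both in
ADU with the dark level already subtracted.  Only in-focus structure
retains the speckle modulation, so the local contrast of the band-passed
difference image is a depth weight:

1. `δI = Is − Iu`.
2. `F = W ⊛ δI`, where `W` is the difference-of-Gaussians wavelet
   `W(κ) = exp(−π²κ²σw²) − exp(−2π²κ²σw²)` on the normalized frequency grid
   (Nyquist = 1/2).  `W(0) = 0` removes the local mean and its global
   maximum is exactly 1/4 at `κ = √(ln 2)/(π σw)` for every width.
3. Local moments with a Gaussian window `G` of width `σstat`:
   `V = G⊛F² − (G⊛F)²`, `⟨Iu⟩ = G⊛Iu`.
4. Noise-bias subtraction (below), clipping negatives, then
   `C = √V_corr / max(⟨Iu⟩, ε)` with `ε = max(tiny, 10⁻⁶·mean(Iu))`.
5. `Icu = C·Iu`; optionally guided-NLM denoised to `Ĩcu`.
6. `IHiLo = η·LP[Ĩcu] + HP[Ĩu]`, with Gaussian low-pass
   `LP(κ) = exp(−κ²/(2κc²))` and `HP = 1 − LP` exactly.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `σw` (px) | wavelet width | 2.0 | positive spatial lobe FWHM ≈ 1.67·σw ≈ 3.3 px, about one grain of the default 4 px speckle; set it to the grain size of your system, slightly larger at low signal |
| `κc` | LP/HP crossover (cycles/px) | auto = `√(ln 2)/(π σw)` | places the seam at the frequency where speckle contrast is measured |
| `σstat` (px) | local-moment window | `1/(2π κc)` | the Lo-band spatial scale: statistics are stationary at the resolution the Lo channel can represent |
| `η` | Lo/Hi balance | auto | transfer-compensated spectral match (below) |
| camera gain | ADU per e⁻ | required for bias subtraction | accepted as ADU/e⁻ or e⁻/ADU with an explicit unit tag |
| read noise | e⁻ rms | 0 | |

### Noise-bias correction

For difference data `δI = Is − Iu` in ADU with gain `g` (ADU/e⁻) and
readout `σr` (e⁻), the white-noise variance is
`g·(⟨Is⟩ + ⟨Iu⟩) + 2(gσr)²` (shot variance in ADU² is `g` × mean ADU per
frame; subtraction doubles the readout term).  Propagating white noise
through the estimator of step 3 transmits the fraction

    T = mean over the grid of W²·(1 − Ĝ²),

not `mean(W²)` alone: the `(G⊛F)²` term removes exactly the noise power the
local-mean window can represent, and omitting the `Ĝ²` term leaves the
corrected variance systematically negative on pure noise.  `Ĝ` is the exact
DFT of the truncated discrete Gaussian kernel that the smoothing actually
applies (per axis, circular boundary), so the identity `E[V_corr] = 0`
holds to kernel precision.  The validation (`pure_noise_bias_check`, 20
seeds of 128×128 constant-fluorescence pairs at 100 photons, gain
2.5 ADU/e⁻, readout 1.6 e⁻) tests the *signed* corrected variance, which is
exposed on `ContrastMap.variance`; the contrast map itself clips negative
variances before the square root, so its mean is positive by construction
and is not a valid unbiasedness diagnostic.

Local statistics use circular (wrap) boundaries so this identity is exact
under FFT filtering; real borders are handled by the mirror padding that
`reconstruct` applies to the raw frames (pad width ≈ 4 filter supports,
cropped after fusion).  With a mirror pad, `LP[X] + HP[X] = X` still holds
exactly because the operation is linear and `LP + HP = 1`.

### η estimation

Empirical mode: over the annulus `0.75κc ≤ κ ≤ 4/3·κc` the amplitude
spectra of `IHi` and the η-free `ILo` are each divided by their own
transfer function (HP, LP) to estimate the object spectrum each channel
saw; η is the ratio of the band means.  Exactly κ-matched channels give
η = 1, and scaling `ILo` by a scales η by 1/a.  Seam quality is assessed as
the fused below/above band-amplitude ratio *normalized by the uniform
image's own ratio* — the raw ratio is dominated by the object's ~1/κ²
spectral decay across the band (≈3 even for `Iu` itself) and would say
nothing about the seam.  The theoretical mode (from optical system
parameters) is out of scope; pass a numeric η instead.

## Guided NLM

Patch similarity uses the Poisson generalized likelihood ratio in the
KL rearrangement `log LG = −[i1·log(2i1/s) + i2·log(2i2/s)]`, `s = i1+i2`,
with `0·log 0 := 0`.  This is algebraically the textbook form but is
exactly zero in floating point for equal intensities and immune to
overflow.  Patch log-likelihood sums `log LG` over a (2N+1)² patch;
weights are `ω = exp(L/h)`; the denoised value is the ω-weighted average of
the target over a (2Ny+1)² search window with the self pixel included
(weight exactly 1).  Guide and target are mirror-padded by `N+Ny` so every
pixel carries a complete window.

Defaults: N = 1 (3×3 patch, about one speckle grain), Ny = 10 (21×21
window; larger windows average more uncorrelated grains at quadratic cost),
h = 10 for the Lo channel, h′ = 0.5 for the Hi channel.  The h values are
empirical and scale with the guide's intensity units: `L` for two noisy
observations of the same underlying patch concentrates around
`−(2N+1)²·ĝ/2`, where `ĝ = g·(1 + σr²/n̄)` is the guide's ADU-scale
variance-to-mean ratio, so the defaults correspond to unit-gain
photon-count data.  `experiments.suggest_h` sets `h = α·(2N+1)²·ĝ/2` from
the camera model (α = 1 for Hi — statistically identical patches weighted
e⁻¹, conservative of resolution; α = 3 for Lo — aggressive ensemble
averaging), which is how the packaged experiments adapt h to each simulated
photon level.  When `h_lo = h_hi` the weights are shared; otherwise the
patch log-likelihood maps are computed once and re-exponentiated per
channel (`guided_denoise_channels`), so denoising both channels costs
little more than one.

The vectorized implementation accumulates shifted full-frame log-LG maps in
the same summation order as the literal quadruple loop
(`nlm_denoise_reference`, numba-compiled), so the two agree to ~1e−15; the
reference is the sole correctness oracle.

## Simulator

`generate_speckle` synthesizes fully developed speckle as the intensity of
a random-phase field band-limited by a disk pupil of radius
`1/(2·grain)` in normalized frequency (grain < 2 px would alias and is
rejected).  The intensity is exponential-distributed: contrast = 1, checked
at 512² to within 5%.  `render_pair` images a 3D density plane by plane
through a lateral Gaussian PSF with `σ(dz) = σ0·√(1 + (dz/zR)²)`,
`σ0 = 0.21·λ/NA`, `zR = n·λ/NA²` (Gaussian-beam approximation — adequate
for contrast-decay physics, not a diffraction-rigorous PSF), scales the
uniform image to a requested peak photon count, and applies Poisson shot
noise plus Gaussian readout noise through the camera model (defaults: gain
2.5 ADU/e⁻, readout 1.6 e⁻ rms).  `render_stack` shares one photon scale
across a through-focus series so "peak photons" refers to the whole
uniform stack.

Deliberate simplifications: the illumination speckle is a single static 2D
pattern and only detection-side blur reduces its imaged contrast with
defocus; axial decorrelation of the 3D illumination speckle, aberrations,
scattering, and sample motion are not modeled.  Blurs use periodic
boundaries (flux-conserving, consistent with the FFT-periodic pattern).
Passing tests on this generator therefore demonstrates the estimator
chain — contrast decay, bias correction, channel fusion, denoising — under
an idealized optical model, not performance on aberrated or scattering
real tissue.

Test scenes: `make_rotated_background_target` stacks a base image over its
180°-rotated copy at a configurable defocus, giving exactly known in-focus
and background-only masks; `make_phantom` builds deterministic 3D bead,
shell and grid phantoms (synthetic stand-ins for real volumetric
specimens).

## Multiplane processing

Mosaic frames are split by pure integer crops from a user-calibrated
layout (per-tile offsets, optional flips and per-plane gains); integer
crops preserve the noise statistics the contrast estimator needs, so
subpixel registration is deliberately out of scope.  Stack reconstruction
is the plane-wise composition of the single-pair reconstruction,
bit-exactly.  Depth-coded projections assign hue from the argmax plane
(ties toward the shallower plane) and brightness from the MIP.

## Metrics

`psnr` implements `10·log10(peakval²/MSE)` with `peakval` defaulting to the
reference maximum, a single MSE over full volumes, and (by default, and
switchable off) a least-squares scalar fit of the test image before the
MSE, since HiLo output units are arbitrary relative to ground truth.
`ssim` delegates to scikit-image with the joint min/max of both images as
the data range.  `sbr` is the mean inside a signal mask over the mean in
its circular dilation (annulus) of configurable radius.

## Validation problem sizes

The packaged validations run at desk scale, chosen to keep the full test
suite around a minute while leaving each statistical check well powered:
oracle equivalence on 50 random 32×32 pairs (N = 1, Ny = 5); bias
unbiasedness over 20 seeds at 128²; sectioning and denoising direction on a
256² rotated-background target at 1000 peak photons; the PSNR sweep on a
128×128×5 bead phantom at 50/200/1000 peak photons with seed 0 (the
experiment is stochastic; the low-signal Hi-vs-Lo gain ordering can come
within ~0.01 dB of a tie on particular realizations, while the
direction-of-effect of the full-denoising arm is stable across all seeds
tried).

## Known limitations

- The Gaussian defocus PSF underestimates the structured sidelobes of real
  widefield defocus; absolute sectioning strengths are indicative only.
- η "theoretical" mode and space-frequency / spatio-temporal NLM variants
  are not implemented.
- NLM cost grows as (2Ny+1)²·(2N+1)² per pixel; the vectorized path is
  practical to Ny ≈ 30 on megapixel frames but is not real-time.
- The GLR assumes Poisson-scale counts; strongly non-Poisson pre-processed
  data require re-tuning h (see `suggest_h`).
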