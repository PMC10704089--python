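# specklehilo

Optically sectioned widefield fluorescence reconstruction from two-shot
speckle-illumination (HiLo) image pairs, with guided non-local-means (NLM)
denoising of both frequency channels, a forward simulator of paired test
data, and multiplane z-splitter mosaic processing.

## Who this is for

Camera-based widefield microscopes are fast and sensitive but collect
out-of-focus fluorescence that buries contrast in thick samples.  HiLo
microscopy restores optical sectioning from just two frames per image: one
under uniform illumination (`Iu`) and one under high-contrast laser speckle
(`Is`).  This package is for microscopists and image-analysis developers
who need to reconstruct such pairs — including mosaics from a z-splitter
prism that projects many focal planes onto one sensor — and for anyone who
wants a tested, self-contained simulation bench for speckle-HiLo methods.

## The method

In-focus structure preserves the speckle modulation; defocused background
washes it out.  The local contrast of the wavelet-filtered difference image
`δI = Is − Iu`,

    C(ρ) = σ[W ⊛ δI](ρ) / ⟨Iu⟩(ρ),

is therefore a depth-discriminating weight (`W` is a zero-DC
difference-of-Gaussians band-pass matched to the speckle grain; shot/readout
noise bias predicted from the camera gain and readout noise is subtracted
from the measured variance).  The weighted image `Icu = C·Iu` estimates the
in-focus contribution, and the final image fuses its low-pass part with the
inherently sectioned high-pass part of the uniform image:

    IHiLo = η · LP[Icu] + HP[Iu],    HP = 1 − LP,

with `η` chosen (spectrally, or by hand) so the two bands meet seamlessly.

Residual speckle noise in `Icu` is suppressed by guided NLM: patch
similarity is measured in the *uniform* image with the Poisson generalized
likelihood ratio

    LG(I1, I2) = (I1+I2)^(I1+I2) / (2^(I1+I2) · I1^I1 · I2^I2),

summed in log space over (2N+1)² patches; weights `ω = exp(L/h)` average
`Icu` (filtering parameter `h`) and, with a second parameter `h'`, `Iu`
itself before the high-pass — denoising both channels without lowering the
cutoff frequency or the resolution.

## Worked example

`examples/01_basic_vs_nlm_reconstruction.py` builds a two-plane scene (a
resolution-style target in focus, the same target rotated 180° placed 10 µm
out of focus), renders a uniform/speckle pair at 1000 peak photons with the
default camera model (gain 2.5 ADU/e⁻, readout 1.6 e⁻ rms), and
reconstructs it both ways:

```
rotated-background target, 256x256, 1000 peak photons
  basic     background left:   4.2% of Iu   in-focus/background contrast:   21.1   eta: 5.47
  nlm_both  background left:   4.6% of Iu   in-focus/background contrast:   29.0   eta: 8.58
```

Reading the numbers: regions containing only out-of-focus structure retain
~4% of their raw widefield intensity after reconstruction — that is the
optical sectioning.  NLM denoising then lifts the in-focus/background
contrast ratio from 21 to 29 by smoothing residual speckle noise without
touching the in-focus detail.

The other examples demonstrate the speckle-contrast physics
(`02_speckle_and_sectioning_physics.py`), the PSNR-versus-signal sweep with
channel-wise denoising ablation (`03_psnr_vs_signal_sweep.py`), and
nine-plane mosaic processing with depth-coded projection
(`04_multiplane_mosaic.py`).

## Command line

A thin `hilo` CLI wraps the library for shell use:

```bash
hilo simulate --phantom beads --shape 9,256,256 --grain-px 4 --photons 1000 --seed 7 --out pair.tif
hilo reconstruct --uniform u.tif --speckle s.tif --out hilo.tif --config run.yaml --save-intermediates
hilo reconstruct-stack --uniform um.tif --speckle sm.tif --layout layout.yaml --out stack.tif
hilo split --in frame.tif --layout layout.yaml --out planes.tif
hilo project --in stack.tif --out depthcoded.png
hilo metrics --test hilo.tif --ref truth.tif --metric psnr,ssim --report report.json
```

Configuration is a single YAML file (camera gain/readout, wavelet width,
cutoff, η, NLM patch/search/filtering parameters); unknown keys are
rejected, and every run writes a JSON manifest that reproduces it exactly.

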