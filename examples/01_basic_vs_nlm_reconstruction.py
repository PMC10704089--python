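"""Reconstruct a simulated pair with basic HiLo and NLM HiLo, side by side.

Builds a two-plane test scene (an in-focus resolution-style target over the
same target rotated 180 degrees, 10 um out of focus), renders a
uniform/speckle pair at 1000 peak photons, and reconstructs with and
without guided non-local-means denoising.  The printed background ratio is
the mean intensity the reconstruction leaves in regions that contain *only*
out-of-focus structure, relative to the raw uniform image (smaller =
stronger optical sectioning); the contrast ratio is in-focus mean over
background mean within each reconstruction (larger = cleaner image).
"""

from specklehilo.experiments import rotated_target_experiment

result = rotated_target_experiment(shape=(256, 256), photons_peak=1000.0, seed=0)

print("rotated-background target, 256x256, 1000 peak photons")
for name in ("basic", "nlm_both"):
    stats = result[name]
    print(
        f"  {name:8s}  background left: {100 * stats['background_ratio']:5.1f}% of Iu   "
        f"in-focus/background contrast: {stats['contrast_ratio']:6.1f}   eta: {stats['eta']:.2f}"
    )
print(
    "\nBoth reconstructions suppress the defocused background far below the raw\n"
    "widefield level; NLM additionally smooths residual speckle noise, which\n"
    "raises the in-focus/background contrast ratio."
)
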