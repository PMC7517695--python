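"""Generate a synthetic echocardiogram phantom with known ground truth.

The phantom emulates what the measurement pipeline needs from a B-mode
still: a bright sector on dark background, a posterior-wall band of known
thickness, multiplicative speckle, and a ruler of ticks with known pixel
pitch. The printed ground truth is what the pipeline should recover.
"""

from echowall import PhantomParams, generate_phantom, write_phantom

params = PhantomParams(seed=7, band_thickness_px=20, ruler_pitch_px=25,
                       speckle_sigma=0.2)
image, truth = generate_phantom(params)

print(f"image: {image.shape[0]}x{image.shape[1]} 8-bit gray")
print(f"true wall thickness: {truth.true_thickness_px} px "
      f"= {truth.true_thickness_mm:.2f} mm")
print(f"scale: {truth.ruler_pitch_px} px per 10 mm "
      f"-> {truth.mm_per_px:.3f} mm/px")
print(f"target window for the localizer: row {truth.band_bounding_box.row}, "
      f"col {truth.band_bounding_box.col}, side {truth.band_bounding_box.side}")

png, sidecar = write_phantom("phantom_demo", image, truth, seed=7)
print(f"wrote {png} and {sidecar}")
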