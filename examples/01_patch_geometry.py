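"""Patch-grid geometry on a full-field CLE frame.

Builds a 576x576 frame whose field of view is the inscribed disc,
downscales it 0.5x and extracts the center-anchored 80x80 patch grid with
50% overlap, keeping only patches fully inside the circular field.
"""

import numpy as np

from clippf import CLEFrame, downscale_image, extract_patches, plan_patch_grid

frame = CLEFrame(
    pixels=np.random.default_rng(0).integers(0, 65536, (576, 576), dtype=np.uint16),
    patient_id="demo", location="alveolar_ridge", label="normal",
)
small = downscale_image(frame, 0.5)
grid = plan_patch_grid(small.pixels.shape[::-1])
patches = extract_patches(small, grid)

print(f"downscaled frame: {small.pixels.shape}, field radius {small.field_radius}")
print(f"candidate positions per axis: {grid.xs}")
print(f"patches kept inside the circular field: {len(patches)} of {len(grid.candidate_positions)}")
# 21 of 25: the four corner candidates poke out of the disc and are dropped.
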