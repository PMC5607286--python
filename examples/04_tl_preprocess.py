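"""Transfer-learning input chain: percentile compression, maximum square,
RGB resize.

Shows the 16-bit -> 8-bit dynamic compression over the circular field, the
centered maximum-square crop (side = floor(sqrt(2) r)), and the 224x224
RGB input an ImageNet-style classifier would consume.
"""

import numpy as np

from clippf import CLEFrame
from clippf.tl import (
    discarded_field_fraction, max_square_crop, percentile_compress,
    prepare_rgb_input,
)

rng = np.random.default_rng(4)
frame = CLEFrame(
    pixels=rng.integers(2000, 40000, (576, 576), dtype=np.uint16),
    patient_id="demo", location="alveolar_ridge", label="normal",
)

eight = percentile_compress(frame)
print(f"8-bit range after percentile compression: "
      f"{eight.pixels.min()}..{eight.pixels.max()}")

crop = max_square_crop(eight, (frame.field_center, frame.field_radius))
print(f"maximum-square crop: {crop.shape[0]} px "
      f"(field radius {frame.field_radius:.0f})")
print(f"in-field area discarded by the crop: "
      f"{100 * discarded_field_fraction(frame.field_radius, (576, 576)):.1f}%")

rgb, scale = prepare_rgb_input(crop)
print(f"network input: {rgb.shape}, pre-scaling factor {scale:.2f}")
# 407 px crop -> 224 px input is the ~0.55x pre-scaling of the chain.
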