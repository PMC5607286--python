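"""Classical texture baseline: riu2 LBP histograms + random forest.

Computes image-level feature vectors (mean + std of per-patch multiscale
LBP histograms) for a few synthetic frames per class and scores held-out
frames with a random forest.
"""

import numpy as np

from clippf import downscale_image, extract_patches
from clippf.synth import SyntheticConfig, draw_patient_params, \
    synth_carcinoma_frame, synth_normal_frame
from clippf.textures import image_feature_vector, rf_classify

cfg = SyntheticConfig(rng_seed=3)
rng = np.random.default_rng(3)
params = draw_patient_params(cfg, rng)


def vectors(n, start):
    out = []
    for k in range(n):
        for maker in (synth_normal_frame, synth_carcinoma_frame):
            meta = dict(patient_id="demo", sequence_id="s0", frame_index=start + k)
            frame = maker(cfg, params, rng, **meta)
            patches = extract_patches(downscale_image(frame, 0.5))
            out.append(image_feature_vector(patches, "lbp"))
    return out


train, test = vectors(5, 0), vectors(3, 100)
print(f"feature vector length: {len(train[0].values)} (54 means + 54 stds)")
probs = rf_classify(train, test, n_trees=200, rng_seed=0)
for v, p in zip(test, probs):
    print(f"true {v.label:13s} -> P(carcinogenic) = {p:.2f}")
# the forest's vote fraction should be low for normal frames, high for
# carcinogenic ones.
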