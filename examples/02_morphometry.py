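"""Nuclear morphometry on a synthetic slide.

Renders ~180 nuclei (three classes with distinct size/shape/staining),
extracts the 27 per-nucleus features from the label mask + intensity
image, and matches the ground-truth annotations back to the detected
centroids.
"""

import pandas as pd

from panmorph import (
    MorphologyProfile,
    extract_features,
    gen_cell_image,
    map_annotations_to_cells,
)

mask, img, truth = gen_cell_image(
    MorphologyProfile(),
    {"cancer": 60, "lymphocyte": 60, "stromal": 60},
    canvas_um=(500.0, 500.0),
    scale=0.5,  # µm per pixel
    seed=7,
)
feats = extract_features(mask, img, scale=0.5)
cls = pd.Series({i + 1: c.cls for i, c in enumerate(truth.cells)}, name="cls")
table = feats.join(cls)

print(f"extracted {len(table)} cells x {len(feats.columns) - 3} features "
      f"(registry {feats['registry_hash'].iloc[0]})")
print("\nper-class medians (area µm², aspect ratio, mean stain intensity):")
print(table.groupby("cls")[["area", "aspect_ratio", "intensity_mean"]].median().round(2))

pairing = map_annotations_to_cells(truth, feats, max_dist=1.824)
print(f"\nannotation matching: {len(pairing.matches)} matched, "
      f"{len(pairing.unmatched_annotations)} unmatched (threshold 1.824 µm)")
print(
    "\nLymphocytes should be small, round and dark; stromal nuclei elongated;"
    "\ncancer nuclei large and pale - the same contrasts a classifier exploits."
)
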