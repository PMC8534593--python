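"""Generate a small synthetic breast-ultrasound phantom dataset.

Writes speckled grayscale PNGs with three classes (normal / benign /
malignant) plus ground-truth masks (0 background, 127 tissue, 255 tumor)
and a manifest CSV recording each lesion's true center and pixel area.
"""

import numpy as np

from busecho import generate_dataset, generate_phantom, PhantomParams, BENIGN

manifest = generate_dataset(n_per_class=3, seed=7, out_dir="scratch/example_phantoms")
print(manifest[["file", "class", "lesion_row", "lesion_col", "lesion_area_px"]])
# class 0 rows have area 0 (no lesion); benign/malignant rows record where
# the generator placed the hypoechoic mass and how many pixels it covers.

params = PhantomParams(class_label=BENIGN, lesion_axes=(30, 20), seed=1)
image, mask = generate_phantom(params)
tumor_px = int(np.sum(mask == 255))
print(f"\nsingle phantom: image {image.shape}, tumor pixels {tumor_px} "
      f"(ellipse area pi*30*20 = {np.pi * 600:.0f})")
print(f"lesion is darker than tissue: {image[mask == 255].mean():.1f} "
      f"vs {image[mask == 127].mean():.1f} mean intensity")
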