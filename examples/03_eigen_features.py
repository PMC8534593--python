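"""Eigen-image features via the small-matrix trick.

With M images of N x N pixels, the pixel covariance is N^2 x N^2, but its
nonzero eigenpairs come from the small M x M matrix A^T A - so the basis is
computed without ever forming the big matrix.
"""

import numpy as np

from busecho import (PhantomParams, BENIGN, NORMAL, build_data_matrix,
                     eigen_decompose, generate_phantom, project, reconstruct)

images = []
for seed in range(6):
    cls = BENIGN if seed % 2 else NORMAL
    img, _ = generate_phantom(PhantomParams(image_size=(64, 64), class_label=cls,
                                            lesion_center=(32, 32),
                                            lesion_axes=(12, 8), seed=seed))
    images.append(img)

D = build_data_matrix(images)
model = eigen_decompose(D)
nz = model.n_nonzero
explained = model.eigenvalues[:nz] / model.eigenvalues.sum()
print(f"{D.n_images} images of {D.n_pixels} pixels -> {nz} nonzero eigenvalues")
print("explained variance per component:", np.round(explained, 3))

coords = project(model, images[0], f=nz)
err = np.abs(reconstruct(model, coords) - images[0]).max()
print(f"full-rank reconstruction error: {err:.2e}")
# 6 centered images span at most 5 directions; projecting onto all of them
# reconstructs any training image exactly (up to float round-off).
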