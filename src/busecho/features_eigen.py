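"""Eigen-decomposition (eigenface-style) image features.

Given M same-sized training images, each image is flattened to a column of
the data matrix, columns are centered by the mean image, and the principal
directions of the pixel covariance C = A A^T are obtained through the small
M x M matrix A^T A: if A^T A v = lam v then u = A v is an eigenvector of
A A^T with the same eigenvalue, so the full N^2 x N^2 covariance is never
formed.  Retaining the top-f unit eigenvectors gives the projection that
maximizes the total scatter of the projected training set; projecting an
image x yields the f-dimensional feature W^T (x - mean).

This is the classical eigen-image construction; it is provided as a
companion feature path to :mod:`busecho.features_histogram`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

_EIG_TOL = 1e-10


@dataclasses.dataclass
class DataMatrix:
    """Centered image data matrix and its first two pixelwise moments.

    ``A`` has one centered image per column (shape n_pixels x M);
    ``mean_image`` and ``variance_image`` are flat length-n_pixels vectors;
    ``image_shape`` remembers the 2-D raster shape.
    """

    A: np.ndarray
    mean_image: np.ndarray
    variance_image: np.ndarray
    image_shape: tuple[int, int]

    @property
    def n_images(self) -> int:
        return self.A.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.A.shape[0]


@dataclasses.dataclass
class EigenFeatureModel:
    """Eigenpairs of the image covariance plus the centering mean.

    ``eigenvalues`` are descending and >= 0 (at most M-1 nonzero);
    ``eigenvectors`` holds the corresponding unit-norm pixel-space vectors
    as columns.  ``projection(f)`` returns the scatter-maximizing top-f
    basis.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mean_image: np.ndarray
    image_shape: tuple[int, int]

    @property
    def n_nonzero(self) -> int:
        scale = max(1.0, float(self.eigenvalues[0])) if self.eigenvalues.size else 1.0
        return int(np.sum(self.eigenvalues > _EIG_TOL * scale))

    def projection(self, f: int) -> np.ndarray:
        if not 1 <= f <= self.n_nonzero:
            raise ValueError(f"f must be in [1, {self.n_nonzero}], got {f}")
        return self.eigenvectors[:, :f]

    def save(self, path) -> None:
        np.savez(Path(path), eigenvalues=self.eigenvalues,
                 eigenvectors=self.eigenvectors, mean_image=self.mean_image,
                 image_shape=np.asarray(self.image_shape))

    @classmethod
    def load(cls, path) -> "EigenFeatureModel":
        with np.load(Path(path)) as data:
            return cls(eigenvalues=data["eigenvalues"],
                       eigenvectors=data["eigenvectors"],
                       mean_image=data["mean_image"],
                       image_shape=tuple(int(v) for v in data["image_shape"]))


def build_data_matrix(images) -> DataMatrix:
    """Stack >= 2 same-shape images into a centered column data matrix."""
    arrays = [np.asarray(im, dtype=float) for im in images]
    if len(arrays) < 2:
        raise ValueError("need at least 2 images")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all images must share a shape")
    if len(shape) != 2:
        raise ValueError("images must be 2-D")
    stacked = np.column_stack([a.ravel() for a in arrays])
    mean_image = stacked.mean(axis=1)
    variance_image = ((stacked - mean_image[:, None]) ** 2).mean(axis=1)
    return DataMatrix(A=stacked - mean_image[:, None], mean_image=mean_image,
                      variance_image=variance_image, image_shape=shape)


def eigen_decompose(D: DataMatrix) -> EigenFeatureModel:
    """Eigenpairs of the pixel covariance via the small-matrix trick.

    Solves the M x M problem A^T A and maps eigenvectors up with u = A v;
    the nonzero spectrum equals that of A A^T exactly.  Eigenvector signs
    are fixed by making each vector's largest-magnitude entry positive.
    """
    small = D.A.T @ D.A
    lam, V = np.linalg.eigh(small)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    V = V[:, order]

    U = D.A @ V
    norms = np.linalg.norm(U, axis=0)
    scale = max(1.0, lam[0] if lam.size else 1.0)
    keep = norms > np.sqrt(_EIG_TOL * scale)
    U[:, keep] /= norms[keep]
    U[:, ~keep] = 0.0

    # sign convention: largest-|entry| positive, for reproducibility
    for j in np.nonzero(keep)[0]:
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]

    return EigenFeatureModel(eigenvalues=lam, eigenvectors=U,
                             mean_image=D.mean_image, image_shape=D.image_shape)


def project(model: EigenFeatureModel, img: np.ndarray, f: int) -> np.ndarray:
    """Feature vector W^T (x - mean) using the top-f eigenvectors."""
    x = np.asarray(img, dtype=float)
    if x.shape != model.image_shape:
        raise ValueError(f"image shape {x.shape} != model shape {model.image_shape}")
    W = model.projection(f)
    return W.T @ (x.ravel() - model.mean_image)


def reconstruct(model: EigenFeatureModel, coords: np.ndarray) -> np.ndarray:
    """Map an f-dimensional feature vector back to image space."""
    coords = np.asarray(coords, dtype=float)
    W = model.projection(len(coords))
    flat = W @ coords + model.mean_image
    return flat.reshape(model.image_shape)
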