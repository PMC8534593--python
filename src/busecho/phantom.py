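"""Synthetic ultrasound-like phantom generation.

Real breast-ultrasound B-mode images show a speckled tissue texture with
masses appearing as hypoechoic (darker) regions; benign masses tend to have
smooth, roughly elliptical margins while malignant masses are irregular or
spiculated.  This module generates controllable stand-ins for such images,
together with pixel-exact ground-truth masks, so that every downstream stage
(feature extraction, classification, segmentation, localization) is testable
without any external download.

The phantom is a piecewise-constant intensity template (dark background
outside an elliptical field of view, mid-gray tissue, dark lesion) degraded
by multiplicative unit-mean gamma speckle — the standard first-order model
of fully developed ultrasound speckle.  Masks use the three-level code
0 = background, 127 = normal tissue, 255 = tumor (see :mod:`busecho.dataio`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from busecho import dataio

NORMAL, BENIGN, MALIGNANT = 0, 1, 2
CLASS_NAMES = {NORMAL: "normal", BENIGN: "benign", MALIGNANT: "malignant"}
_NAME_TO_CLASS = {v: k for k, v in CLASS_NAMES.items()}

#: number of low-order harmonics used for the seeded boundary perturbation
_N_HARMONICS = 6


@dataclasses.dataclass
class PhantomParams:
    """Parameters of a single synthetic phantom.

    Attributes
    ----------
    image_size : (rows, cols) in pixels.
    class_label : 0 (normal, no lesion), 1 (benign, smooth ellipse) or
        2 (malignant, irregular boundary).
    lesion_center : (row, col) of the lesion center, pixels.
    lesion_axes : (a, b) ellipse semi-axes, pixels (row/col directions).
    boundary_irregularity : dimensionless amplitude of the radial boundary
        perturbation; 0 gives an exact ellipse.
    background_mean, lesion_mean : template intensities in [0, 255]; the
        lesion must be darker (hypoechoic).
    speckle_scale : coefficient of variation of the multiplicative speckle;
        the gamma shape parameter is 1/speckle_scale**2.
    seed : integer seed; identical (params, seed) gives bit-identical output.
    """

    image_size: tuple[int, int] = (256, 256)
    class_label: int = BENIGN
    lesion_center: tuple[float, float] = (128.0, 128.0)
    lesion_axes: tuple[float, float] = (30.0, 20.0)
    boundary_irregularity: float = 0.0
    background_mean: float = 140.0
    lesion_mean: float = 60.0
    speckle_scale: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.class_label, str):
            self.class_label = _NAME_TO_CLASS[self.class_label]
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"class_label must be 0/1/2, got {self.class_label}")
        if not (0.0 <= self.lesion_mean < self.background_mean <= 255.0):
            raise ValueError(
                "lesion must be hypoechoic: need 0 <= lesion_mean < "
                f"background_mean <= 255, got {self.lesion_mean} / {self.background_mean}"
            )
        if self.speckle_scale <= 0:
            raise ValueError("speckle_scale must be positive")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")
        if self.class_label != NORMAL:
            self._check_lesion_in_bounds()

    def _check_lesion_in_bounds(self) -> None:
        r0, c0 = self.lesion_center
        a, b = self.lesion_axes
        if a <= 0 or b <= 0:
            raise ValueError("lesion_axes must be positive")
        # the radial perturbation can inflate the boundary by at most this factor
        reach = 1.0 + self.boundary_irregularity
        h, w = self.image_size
        if (r0 - a * reach < 0 or r0 + a * reach > h - 1
                or c0 - b * reach < 0 or c0 + b * reach > w - 1):
            raise ValueError(
                f"lesion (center {self.lesion_center}, axes {self.lesion_axes}, "
                f"irregularity {self.boundary_irregularity}) does not fit inside "
                f"image of size {self.image_size}"
            )


def _boundary_perturbation(theta: np.ndarray, irregularity: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Smooth seeded radial multiplier r(theta) with mean ~1.

    A low-order random Fourier series, scaled so its maximum absolute
    deviation equals ``irregularity``; mimics spiculated margins without
    claiming clinical realism.
    """
    if irregularity == 0.0:
        return np.ones_like(theta)
    coef_cos = rng.normal(size=_N_HARMONICS)
    coef_sin = rng.normal(size=_N_HARMONICS)
    k = np.arange(2, _N_HARMONICS + 2)  # skip k=1 (pure translation look)
    flat = theta.ravel()
    wave = (coef_cos @ np.cos(np.outer(k, flat))
            + coef_sin @ np.sin(np.outer(k, flat))).reshape(theta.shape)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = wave / peak
    return 1.0 + irregularity * wave


def _lesion_support(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Boolean raster of the (possibly perturbed) elliptical lesion."""
    h, w = params.image_size
    r0, c0 = params.lesion_center
    a, b = params.lesion_axes
    rr, cc = np.mgrid[0:h, 0:w]
    dr = (rr - r0) / a
    dc = (cc - c0) / b
    rho = np.hypot(dr, dc)
    theta = np.arctan2(dc, dr)
    limit = _boundary_perturbation(theta, params.boundary_irregularity, rng)
    return rho <= limit


def _field_of_view(image_size: tuple[int, int]) -> np.ndarray:
    """Elliptical imaging field of view; pixels outside are background (0)."""
    h, w = image_size
    rr, cc = np.mgrid[0:h, 0:w]
    return ((rr - (h - 1) / 2) / (0.49 * h)) ** 2 + (
        (cc - (w - 1) / 2) / (0.49 * w)) ** 2 <= 1.0


def generate_phantom(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phantom image and its ground-truth mask.

    Returns
    -------
    image : uint8 array of shape ``params.image_size``
        Speckled grayscale image.
    mask : uint8 array, values in {0, 127, 255}
        255 on the lesion, 127 on normal tissue inside the field of view,
        0 on the background.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    fov = _field_of_view(params.image_size)

    template = np.full((h, w), 4.0)  # near-black outside the field of view
    template[fov] = params.background_mean

    if params.class_label == NORMAL:
        lesion = np.zeros((h, w), dtype=bool)
    else:
        lesion = _lesion_support(params, rng)
        template[lesion] = params.lesion_mean

    shape = 1.0 / params.speckle_scale ** 2
    speckle = rng.gamma(shape, scale=1.0 / shape, size=(h, w))
    image = np.clip(template * speckle, 0, 255).astype(np.uint8)

    mask = dataio.encode_mask(tumor=lesion, tissue=fov & ~lesion)
    return image, mask


def generate_mixture_image(gauss_params, n_pixels: int, seed: int,
                           shape: tuple[int, int] | None = None) -> np.ndarray:
    """Image whose pixel intensities are i.i.d. draws from a Gaussian mixture.

    The inverse problem of the histogram feature extractor: given four
    (weight, mean, sigma) triplets, produce an image whose intensity
    histogram realizes that mixture, for fit-recovery tests.

    Parameters
    ----------
    gauss_params : array-like of shape (k, 3)
        Rows of (weight, mean, sigma). Weights need not be normalized;
        components with zero weight are inactive. Negative weights, or a
        non-positive sigma on an active component, are rejected.
    n_pixels : total number of pixels to draw.
    seed : RNG seed.
    shape : optional (rows, cols); default is the most-square factorization.
    """
    comps = np.asarray(gauss_params, dtype=float)
    if comps.ndim != 2 or comps.shape[1] != 3:
        raise ValueError("gauss_params must have shape (k, 3): (weight, mean, sigma)")
    weights, means, sigmas = comps.T
    if np.any(weights < 0):
        raise ValueError("mixture weights must be non-negative")
    active = weights > 0
    if not np.any(active):
        raise ValueError("at least one mixture weight must be positive")
    if np.any(sigmas[active] <= 0):
        raise ValueError("sigma must be positive for components with positive weight")
    if np.any((means < 0) | (means > 255)):
        raise ValueError("component means must lie in [0, 255]")
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")

    rng = np.random.default_rng(seed)
    probs = weights / weights.sum()
    which = rng.choice(len(comps), size=n_pixels, p=probs)
    values = rng.normal(means[which], sigmas[which])
    values = np.clip(np.rint(values), 0, 255).astype(np.uint8)

    if shape is None:
        side = int(np.floor(np.sqrt(n_pixels)))
        while n_pixels % side:
            side -= 1
        shape = (side, n_pixels // side)
    if shape[0] * shape[1] != n_pixels:
        raise ValueError(f"shape {shape} incompatible with n_pixels={n_pixels}")
    return values.reshape(shape)


def _random_params(class_label: int, image_size: tuple[int, int],
                   rng: np.random.Generator, seed: int) -> PhantomParams:
    """Draw per-image geometry/contrast variation for dataset generation."""
    h, w = image_size
    scale = min(h, w) / 256.0
    a = rng.uniform(28, 52) * scale
    b = rng.uniform(20, 40) * scale
    irregularity = 0.0 if class_label != MALIGNANT else rng.uniform(0.25, 0.45)
    reach = 1.0 + irregularity
    margin_r = a * reach + 0.1 * h
    margin_c = b * reach + 0.1 * w
    center = (rng.uniform(margin_r, h - 1 - margin_r),
              rng.uniform(margin_c, w - 1 - margin_c))
    return PhantomParams(
        image_size=image_size,
        class_label=class_label,
        lesion_center=center,
        lesion_axes=(a, b),
        boundary_irregularity=irregularity,
        background_mean=rng.uniform(130, 150),
        lesion_mean=rng.uniform(50, 70),
        speckle_scale=0.25,
        seed=seed,
    )


def generate_dataset(n_per_class: int, seed: int, out_dir,
                     image_size: tuple[int, int] = (256, 256)) -> pd.DataFrame:
    """Write a balanced phantom dataset (PNGs + masks + manifest CSV).

    Produces ``n_per_class`` images for each of the three classes, with
    seeded per-image variation in lesion geometry and contrast.  The manifest
    records file, mask_file, class, and the generator's lesion truth
    (center and pixel area) for localization scoring.

    Returns the manifest as a DataFrame; also written to
    ``out_dir/manifest.csv``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    idx = 0
    for class_label in (NORMAL, BENIGN, MALIGNANT):
        for _ in range(n_per_class):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
            param_rng = np.random.default_rng(child)
            img_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
            if class_label == NORMAL:
                params = PhantomParams(image_size=image_size,
                                       class_label=NORMAL, seed=img_seed)
            else:
                params = _random_params(class_label, image_size, param_rng, img_seed)
            image, mask = generate_phantom(params)

            name = f"img_{idx:04d}"
            img_file = f"{name}.png"
            mask_file = f"{name}_mask.png"
            dataio.save_image(image, out_dir / img_file)
            dataio.save_image(mask, out_dir / mask_file)

            tumor = mask == dataio.TUMOR_LABEL
            if tumor.any():
                rr, cc = np.nonzero(tumor)
                lesion_row, lesion_col = float(rr.mean()), float(cc.mean())
                lesion_area = int(tumor.sum())
            else:
                lesion_row = lesion_col = np.nan
                lesion_area = 0
            rows.append({
                "file": img_file,
                "mask_file": mask_file,
                "class": class_label,
                "lesion_row": lesion_row,
                "lesion_col": lesion_col,
                "lesion_area_px": lesion_area,
            })
            idx += 1

    manifest = pd.DataFrame(rows)
    dataio.save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
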