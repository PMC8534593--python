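"""Image/mask I/O, the three-level mask code, resizing, and seeded splits.

Images are plain 2-D uint8 numpy arrays. Ground-truth masks use a
three-level code on the same grid: 0 = background, 127 = normal breast
tissue, 255 = tumor.  Some sources print 225 for the tumor level; since 255
is the 8-bit maximum and the segmentation convention is explicit about 255,
255 is canonical here and 225 is accepted on decode for robustness.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

BACKGROUND_LABEL = 0
TISSUE_LABEL = 127
TUMOR_LABEL = 255
#: legacy alias for the tumor level, accepted on decode only
_TUMOR_ALIAS = 225

MASK_ALPHABET = frozenset({BACKGROUND_LABEL, TISSUE_LABEL, TUMOR_LABEL})

#: standard working resolution of the pipeline
STANDARD_SIZE = (256, 256)


def load_image(path) -> np.ndarray:
    """Load an image as a 2-D uint8 array.

    RGB(A) inputs are converted to grayscale with the standard ITU-R 601
    luma transform (and the conversion is logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    with Image.open(path) as im:
        if im.mode != "L":
            logger.info("converting %s from mode %s to grayscale", path, im.mode)
            im = im.convert("L")
        return np.asarray(im, dtype=np.uint8)


def save_image(img: np.ndarray, path) -> None:
    """Save a 2-D array with values in [0, 255] as an 8-bit grayscale PNG."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr, mode="L").save(path)


def standardize(img: np.ndarray, size: tuple[int, int] = STANDARD_SIZE,
                is_mask: bool = False) -> np.ndarray:
    """Resize to the working resolution (default 256x256).

    Images are resampled bilinearly; masks use nearest-neighbor so the
    {0, 127, 255} alphabet is preserved exactly.
    """
    arr = np.asarray(img, dtype=np.uint8)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D array, got shape {arr.shape}")
    if arr.shape == tuple(size):
        return arr.copy()
    resample = Image.Resampling.NEAREST if is_mask else Image.Resampling.BILINEAR
    # PIL size is (width, height)
    out = Image.fromarray(arr, mode="L").resize((size[1], size[0]), resample)
    return np.asarray(out, dtype=np.uint8)


def encode_mask(tumor: np.ndarray, tissue: np.ndarray) -> np.ndarray:
    """Encode disjoint boolean rasters into the three-level mask."""
    tumor = np.asarray(tumor, dtype=bool)
    tissue = np.asarray(tissue, dtype=bool)
    if tumor.shape != tissue.shape:
        raise ValueError("tumor and tissue rasters must share a shape")
    if np.any(tumor & tissue):
        raise ValueError("tumor and tissue regions overlap")
    mask = np.zeros(tumor.shape, dtype=np.uint8)
    mask[tissue] = TISSUE_LABEL
    mask[tumor] = TUMOR_LABEL
    return mask


def decode_mask(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a three-level mask into (tumor, tissue, background) rasters.

    Accepts the legacy 225 tumor level alongside the canonical 255.
    """
    arr = np.asarray(mask)
    allowed = MASK_ALPHABET | {_TUMOR_ALIAS}
    bad = set(np.unique(arr)) - allowed
    if bad:
        raise ValueError(f"mask contains values outside {sorted(allowed)}: {sorted(bad)}")
    tumor = (arr == TUMOR_LABEL) | (arr == _TUMOR_ALIAS)
    tissue = arr == TISSUE_LABEL
    return tumor, tissue, ~(tumor | tissue)


def save_manifest(manifest: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(path, index=False)


def load_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    return pd.read_csv(path)


def split_dataset(manifest: pd.DataFrame, ratio: float = 0.7,
                  seed: int = 0) -> pd.DataFrame:
    """Stratified seeded train/test split.

    Adds a ``split`` column with values ``train``/``test``; within each
    class, round(ratio * n) items go to train after a seeded shuffle, so the
    per-class train fraction deviates from ``ratio`` by less than one item.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    if "class" not in manifest.columns:
        raise ValueError("manifest must have a 'class' column")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = "test"
    for label, group in manifest.groupby("class", sort=True):
        if len(group) < 2:
            raise ValueError(f"class {label} has fewer than 2 items; cannot split")
        order = rng.permutation(len(group))
        n_train = int(round(ratio * len(group)))
        train_idx = group.index.to_numpy()[order[:n_train]]
        out.loc[train_idx, "split"] = "train"
    return out
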