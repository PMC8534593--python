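"""Morphological post-processing and lesion localization.

Raw pixel-wise segmentation output is often fragmented; a morphological
closing with a disk structuring element connects nearby fragments, and
small spurious components are removed.  The refined binary mask is then
summarized as a lesion report: centroid, pixel area (and physical area if a
pixel spacing is known), bounding box, and component counts before/after
refinement.  A single 2-D frame cannot yield a volume, so size is reported
honestly as area.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from skimage import measure, morphology

from busecho.dataio import TUMOR_LABEL

#: default structuring-element radius (pixels) at 256x256
DEFAULT_RADIUS = 5
#: default minimum connected-component size (pixels) kept after closing
DEFAULT_MIN_SIZE = 20
#: 8-connectivity for components, so counts are reproducible
_CONNECTIVITY = 2


@dataclasses.dataclass
class LesionReport:
    """Location and size of the largest lesion component in a binary mask."""

    present: bool
    centroid: tuple[float, float] | None = None
    area_px: int | None = None
    area_physical: float | None = None  # mm^2; needs pixel spacing
    bounding_box: tuple[int, int, int, int] | None = None  # (min_r, min_c, max_r, max_c) half-open
    n_components_before: int = 0
    n_components_after: int = 0

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _as_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    values = set(np.unique(arr))
    if not values <= {0, TUMOR_LABEL}:
        raise ValueError(f"expected a binary 0/{TUMOR_LABEL} mask, found values {sorted(values)}")
    return arr == TUMOR_LABEL


def morphological_refine(mask: np.ndarray, radius: int = DEFAULT_RADIUS,
                         min_size: int = DEFAULT_MIN_SIZE) -> np.ndarray:
    """Closing with a disk of ``radius`` px, then small-object removal.

    Input and output masks are binary {0, 255}.  Closing never decreases
    the foreground; small-object removal never increases it.
    """
    binary = _as_binary(mask)
    if radius > 0:
        binary = morphology.closing(binary, morphology.disk(radius))
    if min_size > 0:
        # max_size removes components <= its value; keep "smaller than min_size"
        binary = morphology.remove_small_objects(binary, max_size=min_size - 1,
                                                 connectivity=_CONNECTIVITY)
    return np.where(binary, TUMOR_LABEL, 0).astype(np.uint8)


def lesion_report(mask: np.ndarray, pixel_spacing: float | None = None,
                  raw_mask: np.ndarray | None = None) -> LesionReport:
    """Describe the largest connected component of a refined binary mask.

    ``pixel_spacing`` (mm per pixel) converts the pixel area to mm^2.
    ``raw_mask``, if given, is the pre-refinement mask used only for the
    before/after component count.  An empty mask yields ``present=False``.
    """
    binary = _as_binary(mask)
    n_before = (
        int(measure.label(_as_binary(raw_mask), connectivity=_CONNECTIVITY).max())
        if raw_mask is not None else 0
    )
    labels = measure.label(binary, connectivity=_CONNECTIVITY)
    n_after = int(labels.max())
    if n_after == 0:
        return LesionReport(present=False, n_components_before=n_before,
                            n_components_after=0)

    regions = measure.regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    area = int(largest.area)
    return LesionReport(
        present=True,
        centroid=(float(largest.centroid[0]), float(largest.centroid[1])),
        area_px=area,
        area_physical=(area * pixel_spacing ** 2) if pixel_spacing is not None else None,
        bounding_box=tuple(int(v) for v in largest.bbox),
        n_components_before=n_before,
        n_components_after=n_after,
    )
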