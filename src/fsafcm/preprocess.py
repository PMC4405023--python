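"""Pulmonary-parenchyma extraction from a chest slice.

Before clustering, the lung fields are isolated from the rest of the slice:
automatic global thresholding separates dark regions (air, lung) from the
bright trunk; dark components touching the image border (exterior air) are
discarded; the largest one or two remaining dark components are kept as the
lung fields; and morphological closing plus hole filling re-includes the
vessels and nodules inside the lungs, which are brighter than the threshold
and would otherwise be punched out of the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk
from skimage.segmentation import clear_border

from .errors import EmptyParenchymaError, ParameterError
from .imaging import GrayImage, as_gray_image

__all__ = ["ParenchymaMask", "extract_parenchyma"]


@dataclass
class ParenchymaMask:
    """Binary lung-field mask plus how it was obtained."""

    mask: np.ndarray
    threshold_used: float
    components_kept: int


def extract_parenchyma(
    slice_image,
    *,
    closing_radius: int = 3,
    max_components: int = 2,
    min_relative_area: float = 0.05,
) -> tuple[ParenchymaMask, GrayImage]:
    """Extract the lung fields of a chest slice.

    Returns the binary parenchyma mask and the slice with intensities kept
    inside the mask and zeroed outside.  ``max_components`` limits how many
    dark interior components count as lung fields (two lungs on a typical
    slice; one near the apices); components smaller than
    ``min_relative_area`` of the largest are treated as noise.

    Raises :class:`EmptyParenchymaError` when no dark component lies strictly
    inside the trunk (e.g. a uniform image).
    """
    if closing_radius < 0:
        raise ParameterError(f"closing radius must be >= 0, got {closing_radius}")
    if max_components < 1:
        raise ParameterError(f"max_components must be >= 1, got {max_components}")
    img = as_gray_image(slice_image)
    px = img.pixels
    if np.ptp(px) == 0.0:
        raise EmptyParenchymaError("uniform image: no threshold separates lung fields")
    threshold = float(threshold_otsu(px))
    dark = px < threshold
    interior = clear_border(dark)
    if not interior.any():
        raise EmptyParenchymaError("no interior dark component found")
    labeled = label(interior)
    regions = sorted(regionprops(labeled), key=lambda rg: rg.area, reverse=True)
    largest = regions[0].area
    keep = [
        rg.label
        for rg in regions[:max_components]
        if rg.area >= min_relative_area * largest
    ]
    mask = np.isin(labeled, keep)
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius))
    mask = binary_fill_holes(mask)
    masked = np.where(mask, px, 0.0)
    return (
        ParenchymaMask(mask=mask, threshold_used=threshold, components_kept=len(keep)),
        GrayImage(masked, L=img.L),
    )
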