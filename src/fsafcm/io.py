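"""Reading and writing images for the segmentation pipeline.

PNG and TIFF grayscale images (8- or 16-bit; 16-bit data is rescaled to the
8-bit range) are read with imageio.  DICOM slices are read with pydicom and
windowed with a fixed window center/width before rescaling, the standard way
CT Hounsfield data is mapped to display gray levels.  Label maps and binary
masks are written as 8-bit PNG.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .imaging import GrayImage

__all__ = ["read_gray", "read_dicom_slice", "write_mask", "write_labels", "write_gray"]


def read_gray(path, L: int = 256) -> GrayImage:
    """Read a grayscale PNG/TIFF image and rescale it to ``[0, L-1]``."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4):
            arr = arr[..., :3].mean(axis=2)
        else:
            raise ParameterError(f"unsupported image shape {arr.shape}")
    arr = arr.astype(np.float64)
    if arr.max() > L - 1:  # 16-bit payload: rescale into the 8-bit range
        arr = arr * ((L - 1) / 65535.0)
    return GrayImage(np.clip(arr, 0, L - 1), L=L)


def read_dicom_slice(
    path, *, window_center: float = -600.0, window_width: float = 1500.0, L: int = 256
) -> GrayImage:
    """Read one DICOM slice and window it to ``[0, L-1]``.

    The default window (center -600 HU, width 1500 HU) is the standard lung
    window.  Rescale slope/intercept from the header are applied first.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + intercept
    lo = window_center - window_width / 2.0
    scaled = np.clip((hu - lo) / window_width, 0.0, 1.0) * (L - 1)
    return GrayImage(scaled, L=L)


def write_mask(path, mask) -> None:
    """Write a binary mask as an 8-bit PNG (foreground = 255)."""
    import imageio.v3 as iio

    arr = (np.asarray(mask, dtype=bool) * np.uint8(255)).astype(np.uint8)
    iio.imwrite(path, arr)


def write_labels(path, labels, C: int | None = None) -> None:
    """Write an integer label map as an 8-bit PNG, spreading labels over [0, 255]."""
    import imageio.v3 as iio

    lab = np.asarray(labels)
    n = C if C is not None else int(lab.max()) + 1
    step = 255 if n <= 1 else 255 // (n - 1)
    iio.imwrite(path, (lab * step).astype(np.uint8))


def write_gray(path, image: GrayImage) -> None:
    """Write a gray image as an 8-bit PNG (values rounded)."""
    import imageio.v3 as iio

    iio.imwrite(path, np.rint(image.pixels).astype(np.uint8))
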