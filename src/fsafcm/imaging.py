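"""Image container, neighborhood statistics and the 2D gray/neighborhood histogram.

The segmentation algorithms in this package describe each pixel ``x_j`` by the
pair ``[f(x_j), g(x_j)]``: its own gray level and the mean gray level of the
``(2r+1) x (2r+1)`` window centered on it.  The empirical frequency ``p_j`` of
that pair over the whole image is the per-pixel weight driving the
self-adaptive spatial regularization in :mod:`fsafcm.core`.  Pixels of smooth
tissue (parenchyma interior, nodule interior) have ``f ~= g`` and a common,
frequent pair; pixels on edges or impulse noise have ``f`` far from ``g`` and a
rare pair.

Conventions: coordinates are 0-based, row-major ``(row, col)``; window borders
use edge-replicate padding so neighborhood means stay inside the image's
intensity range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "GrayImage",
    "NeighborhoodModel",
    "JointHistogram",
    "as_gray_image",
    "neighborhood_mean",
    "local_mean_square_deviation",
    "build_joint_histogram",
]


@dataclass(frozen=True)
class GrayImage:
    """A single-channel 2D image with gray levels in ``[0, L-1]``.

    Intensities are held as float64 internally (integer-valued on load) so
    that fractional neighborhood means and cluster centers share the scale.
    """

    pixels: np.ndarray
    L: int = 256

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ParameterError("GrayImage requires a non-empty 2D array")
        if self.L < 2:
            raise ParameterError(f"number of gray levels L must be >= 2, got {self.L}")
        lo, hi = float(px.min()), float(px.max())
        if lo < 0.0 or hi > self.L - 1:
            raise ParameterError(
                f"intensities must lie in [0, {self.L - 1}], got [{lo}, {hi}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def N(self) -> int:
        """Total pixel count."""
        return self.pixels.size


def as_gray_image(image, L: int = 256) -> GrayImage:
    """Coerce an array (or pass through a :class:`GrayImage`) to ``GrayImage``."""
    if isinstance(image, GrayImage):
        return image
    return GrayImage(np.asarray(image), L=L)


@dataclass(frozen=True)
class NeighborhoodModel:
    """Square ``(2r+1) x (2r+1)`` neighborhood with edge-replicate padding.

    The center pixel is a member of its own neighborhood, so the window holds
    ``(2r+1)**2`` pixels; this is also the neighbor count ``N_R`` used by the
    baseline algorithms (``N_R = 9`` for ``r = 1``).
    """

    r: int = 2
    padding: str = "edge"

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ParameterError(f"neighborhood radius r must be >= 1, got {self.r}")
        if self.padding != "edge":
            raise ParameterError("only edge-replicate padding is supported")

    @property
    def window_size(self) -> int:
        return (2 * self.r + 1) ** 2

    def offsets(self) -> list[tuple[int, int]]:
        """All ``(dy, dx)`` offsets of the window, center included."""
        r = self.r
        return [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)]


def _padded_views(arr: np.ndarray, nb: NeighborhoodModel):
    """Yield, per window offset, the view of ``arr`` shifted by that offset."""
    r = nb.r
    h, w = arr.shape[-2], arr.shape[-1]
    pad_spec = [(0, 0)] * (arr.ndim - 2) + [(r, r), (r, r)]
    pad = np.pad(arr, pad_spec, mode="edge")
    for dy, dx in nb.offsets():
        yield pad[..., r + dy : r + dy + h, r + dx : r + dx + w]


def neighborhood_mean(image, nb: NeighborhoodModel | int = 2) -> np.ndarray:
    """Per-pixel mean ``g(x_j)`` of the ``(2r+1) x (2r+1)`` window.

    Border windows are completed by edge replication, so the output always
    lies within ``[min(image), max(image)]``.
    """
    if isinstance(nb, int):
        nb = NeighborhoodModel(nb)
    img = as_gray_image(image)
    acc = np.zeros(img.shape, dtype=np.float64)
    for view in _padded_views(img.pixels, nb):
        acc += view
    return acc / nb.window_size


def local_mean_square_deviation(
    image, nb: NeighborhoodModel, g: np.ndarray | None = None
) -> np.ndarray:
    """Per-pixel ``sum_r (f(x_r) - g(x_j))**2 / (2r+1)**2``.

    ``g`` defaults to :func:`neighborhood_mean` of the same window, in which
    case this is the window variance; it is zero exactly on constant windows.
    """
    img = as_gray_image(image)
    if g is None:
        g = neighborhood_mean(img, nb)
    acc = np.zeros(img.shape, dtype=np.float64)
    for view in _padded_views(img.pixels, nb):
        acc += (view - g) ** 2
    return acc / nb.window_size


@dataclass(frozen=True)
class JointHistogram:
    """Joint histogram of the per-pixel pairs ``(f, round(g))``.

    ``counts`` maps each distinct pair to its occurrence count ``n_j`` and
    ``freqs`` to ``p_j = n_j / N``; ``M_star`` is the number of distinct
    pairs.  ``g_image`` keeps the *unquantized* neighborhood means (used by
    the adaptive factor), while ``p_image`` gives each pixel the frequency of
    its own bin, so any pixel index maps directly to its ``p_j``.
    """

    counts: dict[tuple[int, int], int]
    freqs: dict[tuple[int, int], float]
    M_star: int
    g_image: np.ndarray
    p_image: np.ndarray
    N: int
    r: int
    image_shape: tuple[int, int] = field(default=(0, 0))


def build_joint_histogram(image, nb: NeighborhoodModel | int = 2) -> JointHistogram:
    """Count the ``(gray level, rounded neighborhood mean)`` pairs of an image.

    The gray level is rounded to the nearest integer as well, so images loaded
    from integer formats keep their native bins.  The counts partition the
    pixels: their sum is ``N`` and the frequencies sum to one.
    """
    if isinstance(nb, int):
        nb = NeighborhoodModel(nb)
    img = as_gray_image(image)
    g = neighborhood_mean(img, nb)
    f_lvl = np.rint(img.pixels).astype(np.int64)
    g_lvl = np.rint(g).astype(np.int64)
    keys = f_lvl * img.L + g_lvl
    uniq, inverse, counts = np.unique(keys.ravel(), return_inverse=True, return_counts=True)
    n = img.N
    p_image = (counts[inverse] / n).reshape(img.shape)
    pairs = [(int(k // img.L), int(k % img.L)) for k in uniq]
    count_map = {pair: int(c) for pair, c in zip(pairs, counts)}
    freq_map = {pair: int(c) / n for pair, c in zip(pairs, counts)}
    return JointHistogram(
        counts=count_map,
        freqs=freq_map,
        M_star=len(pairs),
        g_image=g,
        p_image=p_image,
        N=n,
        r=nb.r,
        image_shape=img.shape,
    )
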