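"""Synthetic nodule phantoms with ground-truth masks.

Clinical CT series with expert masks cannot ship with the package, so this
module generates the test-bed instead: small parenchyma-like images holding
one nodule in each of the presentations that make clustering hard —

* ``isolated``      — a bright disk with a smoothly decaying rim;
* ``vessel_adhesion`` — the disk plus a bright tube of the *same mean
  intensity* touching it (vessels and nodules share gray levels);
* ``pleural_adhesion`` — a bright wall band along one edge with the disk
  attached through a smooth intensity ramp;
* ``ggo``           — the disk at low contrast above the background
  (ground-glass opacity);
* ``cavitary``      — a bright annulus with a dark interior.

The truth mask marks nodule pixels only (never the vessel or the wall).
Intensities default to background ~40, nodule/vessel ~180, wall ~220 and
GGO ~90 on the 8-bit scale; the millimeter scale defaults to 0.7 mm/px so
clinical nodule diameters of 8-30 mm map to disks of roughly 11-43 px.
Everything is reproducible from ``(kind, params, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GeometryError, ParameterError
from .imaging import GrayImage, as_gray_image

__all__ = [
    "Phantom",
    "NODULE_KINDS",
    "PALETTE",
    "make_phantom",
    "make_two_region",
    "make_chest_slice",
    "add_salt_pepper",
    "phantom_suite",
]

NODULE_KINDS = ("isolated", "vessel_adhesion", "pleural_adhesion", "ggo", "cavitary")

PALETTE = {
    "background": 40.0,
    "nodule": 180.0,
    "vessel": 180.0,
    "wall": 220.0,
    "ggo": 90.0,
}

MM_PER_PX = 0.7


@dataclass
class Phantom:
    """A synthetic image, its ground-truth nodule mask and how it was made."""

    image: GrayImage
    truth_mask: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def _disk_mask(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def make_phantom(
    kind: str,
    size: int = 128,
    *,
    radius: int = 12,
    contrast: float | None = None,
    vessel_width: int = 5,
    wall_thickness: int = 10,
    noise_sigma: float = 2.0,
    rim_sigma: float = 1.5,
    cavity_fraction: float = 0.5,
    seed: int = 0,
    center: tuple[int, int] | None = None,
) -> Phantom:
    """Generate one nodule phantom of the requested presentation.

    ``contrast`` is the nodule-minus-background intensity difference; it
    defaults to the palette value for the kind (140 solid, 50 GGO).  The
    background carries mild Gaussian texture noise (``noise_sigma``) and all
    shape boundaries are softened with a Gaussian of ``rim_sigma`` so edges
    transit smoothly, while the truth mask keeps the hard geometry.
    """
    if kind not in NODULE_KINDS:
        raise ParameterError(f"unknown nodule kind {kind!r}; choose from {NODULE_KINDS}")
    if size < 64:
        raise ParameterError(f"phantom side must be >= 64 px, got {size}")
    if radius < 3:
        raise ParameterError(f"nodule radius must be >= 3 px, got {radius}")
    bg = PALETTE["background"]
    if contrast is None:
        contrast = (PALETTE["ggo"] if kind == "ggo" else PALETTE["nodule"]) - bg
    shape = (size, size)
    if center is None:
        if kind == "pleural_adhesion":
            center = (size // 2, wall_thickness + radius - 2)
        else:
            center = (size // 2, size // 2)
    cy, cx = center
    if not (radius <= cy < size - radius and cx < size - radius and cx >= -radius):
        raise GeometryError(f"nodule at {center} with radius {radius} leaves the frame")
    if kind != "pleural_adhesion" and cx < radius:
        raise GeometryError(f"nodule at {center} with radius {radius} leaves the frame")

    ideal = np.full(shape, bg)
    disk = _disk_mask(shape, center, radius)
    nodule_level = bg + contrast

    if kind == "vessel_adhesion":
        # Horizontal tube at the nodule's own mean intensity, touching it.
        half = max(vessel_width // 2, 1)
        tube = np.zeros(shape, dtype=bool)
        tube[cy - half : cy + half + 1, : cx + 1] = True
        ideal[tube] = nodule_level
    elif kind == "pleural_adhesion":
        ideal[:, :wall_thickness] = PALETTE["wall"]

    if kind == "cavitary":
        inner = _disk_mask(shape, center, radius * cavity_fraction)
        ring = disk & ~inner
        ideal[ring] = nodule_level
        truth = ring
    else:
        ideal[disk] = nodule_level
        truth = disk.copy()
        if kind == "pleural_adhesion":
            truth[:, :wall_thickness] = False

    img = gaussian_filter(ideal, rim_sigma)
    rng = np.random.default_rng(seed)
    img = img + rng.normal(0.0, noise_sigma, shape)
    img = np.clip(img, 0.0, 255.0)
    params = {
        "radius": radius,
        "contrast": contrast,
        "vessel_width": vessel_width,
        "wall_thickness": wall_thickness,
        "noise_sigma": noise_sigma,
        "rim_sigma": rim_sigma,
        "cavity_fraction": cavity_fraction,
        "center": (cy, cx),
        "size": size,
    }
    return Phantom(
        image=GrayImage(img), truth_mask=truth, kind=kind, params=params, seed=seed
    )


def make_two_region(
    size: int = 64, low: float = 40.0, high: float = 200.0
) -> tuple[GrayImage, np.ndarray]:
    """Noiseless two-region image (left half ``low``, right half ``high``).

    Returns the image and the truth mask of the bright region.  The exact
    two-cluster structure makes brute-force two-level clustering (region
    means as centers, mid-threshold labels) the ground truth.
    """
    img = np.full((size, size), float(low))
    img[:, size // 2 :] = float(high)
    return GrayImage(img), img > (low + high) / 2.0


def make_chest_slice(
    size: int = 256, *, nodule: bool = True, seed: int = 0
) -> tuple[GrayImage, np.ndarray]:
    """Synthetic chest slice for the parenchyma-extraction stage.

    Dark exterior air, a bright elliptical trunk and two dark interior
    ellipses as lung fields (optionally holding one bright nodule).  Returns
    the image and the ground-truth lung-field mask.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[:size, :size]
    cy, cx = size / 2, size / 2
    body = ((yy - cy) / (0.42 * size)) ** 2 + ((xx - cx) / (0.46 * size)) ** 2 <= 1.0
    img = np.full((size, size), 8.0)
    img[body] = 200.0
    lungs = np.zeros((size, size), dtype=bool)
    for sign in (-1.0, 1.0):
        lx = cx + sign * 0.21 * size
        lung = ((yy - cy) / (0.28 * size)) ** 2 + ((xx - lx) / (0.14 * size)) ** 2 <= 1.0
        lungs |= lung
    img[lungs] = 45.0
    if nodule:
        ncy, ncx = int(cy), int(cx + 0.21 * size)
        img[_disk_mask((size, size), (ncy, ncx), max(size // 32, 4))] = 180.0
    img = np.clip(img + rng.normal(0.0, 2.0, (size, size)), 0.0, 255.0)
    return GrayImage(img), lungs


def add_salt_pepper(image, density: float, seed: int = 0) -> GrayImage:
    """Corrupt each pixel independently with probability ``density``.

    Corrupted pixels are set half to 0 and half to ``L - 1`` (impulse
    noise).  ``density = 0`` returns the image unchanged.
    """
    if not 0.0 <= density <= 1.0:
        raise ParameterError(f"noise density must lie in [0, 1], got {density}")
    img = as_gray_image(image)
    rng = np.random.default_rng(seed)
    hit = rng.random(img.shape) < density
    salt = rng.random(img.shape) < 0.5
    out = img.pixels.copy()
    out[hit & salt] = float(img.L - 1)
    out[hit & ~salt] = 0.0
    return GrayImage(out, L=img.L)


def phantom_suite(
    kinds: tuple[str, ...] = NODULE_KINDS,
    seeds: tuple[int, ...] = (0, 1),
    size: int = 96,
    **kwargs,
) -> list[Phantom]:
    """The default evaluation suite: every nodule kind at every seed."""
    return [
        make_phantom(kind, size=size, seed=seed, **kwargs)
        for kind in kinds
        for seed in seeds
    ]
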