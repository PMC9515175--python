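"""Periphery and core segmentation of a macrocolony.

The segmentation chain is: grayscale erosion (5x5 windowed minimum) →
Otsu binarization → border-following contour extraction → contours ranked
by descending enclosed area. The largest contour is the colony periphery.

The colony core — the inner, typically wrinkled and brighter region of a
mature macrocolony — shows up as the second-ranked contour whenever the
binary mask carries an interior boundary (a hole, or a separate bright
component). When the global threshold cleanly separates colony from
background the mask is a single filled blob and carries no interior
boundary at all; in that case a second Otsu pass restricted to pixels
inside the periphery recovers the core as the bright inner region. Both
routes gate the candidate core on containment in the periphery, relative
area, and (for the second pass) a minimum intensity contrast, so dust or
noise speckle is not mislabeled as a core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.draw import polygon as draw_polygon

from .errors import DegenerateImageError, SegmentationError
from .io import ColonyImage

__all__ = [
    "Contour",
    "BinaryMask",
    "SegmentationResult",
    "erode",
    "otsu_threshold",
    "binarize",
    "find_contours",
    "segment_colony",
    "coverage_area",
]

OTSU_BINS = 256


@dataclass(frozen=True)
class Contour:
    """A closed polygon in (row, col) pixel coordinates.

    ``vertices`` stores the ring without a duplicated closing vertex; the
    polygon is implicitly closed from the last vertex back to the first.
    """

    vertices: np.ndarray  # (N, 2) float, (row, col)
    enclosed_area_px: float

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError(f"contour needs >= 3 (row, col) vertices, got {v.shape}")
        object.__setattr__(self, "vertices", v)

    @classmethod
    def from_vertices(cls, vertices: np.ndarray) -> "Contour":
        v = np.asarray(vertices, dtype=np.float64)
        if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        return cls(vertices=v, enclosed_area_px=abs(shoelace_area(v)))

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside the polygon."""
        rr, cc = draw_polygon(self.vertices[:, 0], self.vertices[:, 1], shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask

    def representative_point(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def contains_point(self, point: np.ndarray) -> bool:
        return bool(
            skmeasure.points_in_poly(np.atleast_2d(point), self.vertices)[0]
        )


@dataclass(frozen=True)
class BinaryMask:
    """A boolean pixel mask tagged with its role in the analysis."""

    pixels: np.ndarray
    role: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class SegmentationResult:
    periphery: Contour
    core: Optional[Contour]
    threshold: float
    mask: np.ndarray  # the binarized image the contours came from


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed polygon area (shoelace formula) in pixel^2."""
    v = np.asarray(vertices, dtype=np.float64)
    r, c = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def erode(image: ColonyImage, kernel: int = 5) -> ColonyImage:
    """Grayscale erosion: each pixel replaced by the window minimum.

    ``kernel`` is the side of the square window and must be odd; borders
    use edge replication. Kernel 1 is the identity.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return image
    eroded = ndimage.grey_erosion(image.pixels, size=(kernel, kernel), mode="nearest")
    return image.with_pixels(eroded)


def otsu_threshold(image: ColonyImage | np.ndarray, nbins: int = OTSU_BINS) -> float:
    """Otsu's threshold over a fixed 256-bin histogram of [0, 1].

    Returns the bin edge that maximizes the between-class variance
    w0*w1*(mu1-mu0)^2 when pixels are split into "<= edge" and "> edge"
    classes. Ties take the lowest edge. A constant image has no two classes
    to separate and raises :class:`DegenerateImageError`.
    """
    px = image.pixels if isinstance(image, ColonyImage) else np.asarray(image)
    px = px.ravel()
    if px.size == 0 or np.nanmin(px) == np.nanmax(px):
        raise DegenerateImageError("cannot threshold a constant image")
    counts, edges = np.histogram(px, bins=nbins, range=(0.0, 1.0))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    sum0 = np.cumsum(counts * centers)[:-1]
    sum_all = float(np.sum(counts * centers))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (sum_all - sum0) / w1
        sigma_b = w0 * w1 * (mu1 - mu0) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))  # argmax takes the first maximum
    return float(edges[k + 1])


def binarize(image: ColonyImage | np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask: pixel true iff intensity strictly exceeds the threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    px = image.pixels if isinstance(image, ColonyImage) else np.asarray(image)
    return px > threshold


def find_contours(mask: np.ndarray | BinaryMask) -> list[Contour]:
    """All closed region boundaries of a binary mask, largest area first.

    Outer boundaries and hole boundaries are both reported (border
    following on the 0.5 iso-level of the padded mask). Ties in area break
    by the top-most, then left-most vertex of the contour.
    """
    px = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    padded = np.pad(px, 1, mode="constant", constant_values=False).astype(np.float64)
    raw = skmeasure.find_contours(padded, 0.5)
    contours = []
    for ring in raw:
        verts = ring - 1.0  # undo padding offset
        if verts.shape[0] < 4:  # needs >= 3 distinct vertices once closed
            continue
        contours.append(Contour.from_vertices(verts))

    def sort_key(c: Contour):
        top = c.vertices[np.lexsort((c.vertices[:, 1], c.vertices[:, 0]))][0]
        return (-c.enclosed_area_px, top[0], top[1])

    return sorted(contours, key=sort_key)


def _core_candidate(
    contours: list[Contour],
    periphery: Contour,
    min_area_frac: float,
    max_area_frac: float,
) -> Optional[Contour]:
    for cand in contours:
        frac = cand.enclosed_area_px / periphery.enclosed_area_px
        if not (min_area_frac <= frac <= max_area_frac):
            continue
        if periphery.contains_point(cand.representative_point()):
            return cand
    return None


def segment_colony(
    image: ColonyImage,
    kernel: int = 5,
    min_core_area_frac: float = 0.01,
    max_core_area_frac: float = 0.90,
    min_core_contrast: float = 0.10,
) -> SegmentationResult:
    """Segment one macrocolony into periphery and (when present) core.

    Runs ``erode(kernel) → otsu → binarize → find_contours``. The largest
    contour is the periphery. The core is the highest-ranked remaining
    contour that lies inside the periphery and whose area is between
    ``min_core_area_frac`` and ``max_core_area_frac`` of the periphery
    area. If the binary mask carries no such interior boundary, a second
    Otsu threshold computed over the pixels inside the periphery is tried;
    its result is accepted only when the two intensity classes it separates
    differ by at least ``min_core_contrast``, so a texture-free colony
    (no distinct core) yields ``core=None``.
    """
    eroded = erode(image, kernel=kernel)
    try:
        threshold = otsu_threshold(eroded)
    except DegenerateImageError as exc:
        raise SegmentationError(
            f"{image.source_path or 'image'}: no contrast to segment"
        ) from exc
    mask = _compensate_erosion(binarize(eroded, threshold), kernel)
    contours = find_contours(mask)
    if not contours:
        raise SegmentationError(
            f"{image.source_path or 'image'}: no contour found at Otsu "
            f"threshold {threshold:.4f}"
        )
    periphery = contours[0]
    core = _core_candidate(
        contours[1:], periphery, min_core_area_frac, max_core_area_frac
    )
    if core is None:
        core = _second_pass_core(
            eroded, periphery, min_core_area_frac, max_core_area_frac,
            min_core_contrast, kernel,
        )
    return SegmentationResult(
        periphery=periphery, core=core, threshold=threshold, mask=mask
    )


def _compensate_erosion(mask: np.ndarray, kernel: int) -> np.ndarray:
    """Undo the boundary shift of the grayscale-erosion prefilter.

    A k x k windowed minimum moves every step edge inward by (k-1)/2
    pixels, which would bias all area measurements low. Dilating the
    thresholded mask with the same window restores the boundary position
    for step edges (the combination acts as a binary opening), while
    bright speckle smaller than the window — already flattened by the
    erosion — stays removed.
    """
    if kernel <= 1:
        return mask
    return ndimage.binary_dilation(mask, structure=np.ones((kernel, kernel), dtype=bool))


def _second_pass_core(
    eroded: ColonyImage,
    periphery: Contour,
    min_area_frac: float,
    max_area_frac: float,
    min_contrast: float,
    kernel: int,
) -> Optional[Contour]:
    """Otsu restricted to the colony interior, gated on class contrast."""
    inside = periphery.rasterize(eroded.pixels.shape)
    values = eroded.pixels[inside]
    if values.size == 0 or values.min() == values.max():
        return None
    try:
        thr2 = otsu_threshold(values)
    except DegenerateImageError:
        return None
    lo, hi = values[values <= thr2], values[values > thr2]
    if lo.size == 0 or hi.size == 0 or (hi.mean() - lo.mean()) < min_contrast:
        return None
    mask2 = np.zeros_like(inside)
    mask2[inside] = values > thr2
    contours2 = find_contours(_compensate_erosion(mask2, kernel))
    return _core_candidate(contours2, periphery, min_area_frac, max_area_frac)


def coverage_area(periphery: Contour, pixel_size_um: float) -> float:
    """Total colony coverage area in µm²: enclosed pixels × pixel area."""
    if not (pixel_size_um > 0):
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    return periphery.enclosed_area_px * pixel_size_um**2
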