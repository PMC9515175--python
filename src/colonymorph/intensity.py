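"""Region intensity ratios and leading-edge intensity–distance regression.

Fluorescence intensity is treated as a proxy for live-cell density. Two
families of measurements are made:

* mean-intensity ratios between the exposed and unexposed sides of the
  periphery (the annulus between periphery and core) and the core. For
  controls, which have no source to define an exposed side, an augmented
  ratio is computed as the average over three partitions: left/right,
  top/bottom, and the pairing of diagonal quadrants.
* an ordinary least-squares regression of pixel intensity on Euclidean
  distance from the source, over the leading-edge band — the outermost
  ``width`` pixels of the exposed periphery, where cells are newest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, stats

from .errors import DegenerateRegionError, GeometryError
from .io import ColonyImage
from .morphometrics import SeparatingLine
from .segmentation import BinaryMask, Contour

__all__ = [
    "IntensityResult",
    "EdgeRegression",
    "region_masks",
    "intensity_ratio",
    "control_augmented_ratio",
    "pixel_distances",
    "leading_edge_band",
    "edge_regression",
]


@dataclass(frozen=True)
class IntensityResult:
    """Exposed/unexposed mean-intensity comparison for one region.

    For control colonies (augmented scheme) ``partition_ratios`` carries
    the three per-partition ratios whose arithmetic mean is ``ratio``, and
    the two means are the region means of the first-named cell of the
    left/right partition.
    """

    region: str
    mean_exposed: float
    mean_unexposed: float
    ratio: float
    partition_ratios: Optional[tuple[float, float, float]] = None


@dataclass(frozen=True)
class EdgeRegression:
    """OLS fit of intensity on distance over the leading-edge band."""

    slope: float  # intensity per pixel of distance
    intercept: float
    r_squared: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 2:
            raise ValueError("regression needs >= 2 pixels")
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def _signed_grid(shape: tuple[int, int], line: SeparatingLine) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    ur, uc = line.axis_u
    cr, cc = line.center
    return (rows - cr) * ur + (cols - cc) * uc


def region_masks(
    periphery: Contour,
    core: Optional[Contour],
    line: SeparatingLine,
    shape: tuple[int, int],
) -> dict[str, BinaryMask]:
    """Rasterized analysis regions split by the separating line.

    The periphery region is the set difference periphery∖core (an annulus
    when a core exists); the core region is the core's own footprint. Each
    is split into its exposed (positive side) and unexposed half. Pixels
    exactly on the line belong to neither half. With no core, only the
    periphery halves are returned (with a warning).
    """
    per_mask = periphery.rasterize(shape)
    s = _signed_grid(shape, line)
    if not (per_mask & (s > 0)).any() or not (per_mask & (s < 0)).any():
        raise GeometryError("separating line does not cross the colony")
    masks: dict[str, BinaryMask] = {}
    if core is not None:
        core_mask = core.rasterize(shape) & per_mask
        annulus = per_mask & ~core_mask
        masks["core_exposed"] = BinaryMask(core_mask & (s > 0), "core_exposed")
        masks["core_unexposed"] = BinaryMask(core_mask & (s < 0), "core_unexposed")
    else:
        warnings.warn("no core contour; returning periphery-only masks", stacklevel=2)
        annulus = per_mask
    masks["periphery_exposed"] = BinaryMask(annulus & (s > 0), "periphery_exposed")
    masks["periphery_unexposed"] = BinaryMask(annulus & (s < 0), "periphery_unexposed")
    return masks


def intensity_ratio(
    image: ColonyImage,
    exposed: BinaryMask,
    unexposed: BinaryMask,
    region: str,
) -> IntensityResult:
    """Ratio of mean intensity, exposed half over unexposed half."""
    if exposed.count == 0 or unexposed.count == 0:
        raise DegenerateRegionError(f"{region}: empty half-mask")
    mean_ex = float(image.pixels[exposed.pixels].mean())
    mean_un = float(image.pixels[unexposed.pixels].mean())
    if mean_un == 0.0:
        raise DegenerateRegionError(f"{region}: unexposed mean intensity is zero")
    return IntensityResult(
        region=region, mean_exposed=mean_ex, mean_unexposed=mean_un,
        ratio=mean_ex / mean_un,
    )


def control_augmented_ratio(
    image: ColonyImage,
    region_mask: BinaryMask,
    center: tuple[float, float],
    region: str,
) -> IntensityResult:
    """Augmented intensity ratio for control colonies.

    With no antimicrobial source there is no exposed side, so the ratio is
    averaged over three partitions about the colony center: left vs right
    halves, top vs bottom halves, and upper-left + bottom-right quadrants
    vs upper-right + bottom-left quadrants. The three partition ratios are
    combined by arithmetic mean.
    """
    m = region_mask.pixels
    rows, cols = np.mgrid[0 : m.shape[0], 0 : m.shape[1]]
    cr, cc = center
    left, right = m & (cols < cc), m & (cols > cc)
    top, bottom = m & (rows < cr), m & (rows > cr)
    diag_a = (top & left) | (bottom & right)
    diag_b = (top & right) | (bottom & left)
    cells = [(left, right), (top, bottom), (diag_a, diag_b)]
    ratios = []
    for a, b in cells:
        if not a.any() or not b.any():
            raise DegenerateRegionError(f"{region}: empty partition cell")
        mean_a, mean_b = float(image.pixels[a].mean()), float(image.pixels[b].mean())
        if mean_b == 0.0:
            raise DegenerateRegionError(f"{region}: zero-mean partition cell")
        ratios.append(mean_a / mean_b)
    return IntensityResult(
        region=region,
        mean_exposed=float(image.pixels[left].mean()),
        mean_unexposed=float(image.pixels[right].mean()),
        ratio=float(np.mean(ratios)),
        partition_ratios=tuple(ratios),
    )


def pixel_distances(coords: np.ndarray, source: tuple[float, float]) -> np.ndarray:
    """Euclidean distance (pixels) from each (row, col) coordinate to the source."""
    c = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    return np.hypot(c[:, 0] - source[0], c[:, 1] - source[1])


def leading_edge_band(
    periphery: Contour,
    line: SeparatingLine,
    shape: tuple[int, int],
    width: int = 20,
) -> BinaryMask:
    """Exposed-side band of the outermost ``width`` pixels of the colony.

    Pixels inside the periphery whose Euclidean distance to the colony
    boundary is at most ``width``, intersected with the exposed half. If
    the colony is thinner than the band the mask may cover the whole
    exposed half; an empty result warns and returns an empty mask.
    """
    if width < 1:
        raise ValueError(f"band width must be >= 1, got {width}")
    mask = periphery.rasterize(shape)
    dist_in = ndimage.distance_transform_edt(mask)
    s = _signed_grid(shape, line)
    band = mask & (dist_in <= width) & (s > 0)
    if not band.any():
        warnings.warn("leading-edge band is empty", stacklevel=2)
    return BinaryMask(band, role="edge_band")


def edge_regression(
    image: ColonyImage,
    band: BinaryMask,
    source: tuple[float, float],
) -> EdgeRegression:
    """OLS regression of band pixel intensity on distance to the source.

    Constant intensities return slope 0 and R² = 0 by convention; a band
    whose pixels all sit at one distance is rank deficient and raises
    :class:`DegenerateRegionError`.
    """
    coords = np.argwhere(band.pixels)
    if coords.shape[0] < 2:
        raise DegenerateRegionError("leading-edge band has fewer than 2 pixels")
    d = pixel_distances(coords, source)
    y = image.pixels[band.pixels]
    if np.ptp(d) == 0.0:
        raise DegenerateRegionError("all band pixels at one distance: rank deficient")
    if np.ptp(y) == 0.0:
        return EdgeRegression(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, n_pixels=len(y)
        )
    fit = stats.linregress(d, y)
    return EdgeRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_pixels=len(y),
    )
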