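"""Mirrored half-contour ellipse morphometrics.

One-sided exposure to an antimicrobial droplet deforms the side of the
colony facing the droplet. To quantify the deformation, the colony contour
is split by the line through the seeding point perpendicular to the
center→source direction; each half is mirrored across that line into a
closed, symmetric contour; an ellipse is fitted to each mirrored contour;
and the half-extents of the two ellipses along the source axis (and its
perpendicular) are compared as the unexposed/exposed ratio. A perfectly
symmetric colony yields ratios of 1; inhibition on the exposed side pushes
the horizontal ratio above 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.measure import EllipseModel

from .errors import FitError, GeometryError
from .io import ExperimentLayout
from .segmentation import Contour

__all__ = [
    "SeparatingLine",
    "FittedEllipse",
    "DeformationResult",
    "separating_line",
    "split_halves",
    "mirror_half",
    "fit_ellipse",
    "ellipse_extent",
    "deformation_ratios",
]


@dataclass(frozen=True)
class SeparatingLine:
    """Oriented line through the colony center.

    ``axis_u`` is the unit vector from the colony center toward the source
    (the "exposed" direction); the line itself runs perpendicular to it
    through ``center``. The signed coordinate of a point is its projection
    onto ``axis_u``; positive values are on the exposed side.
    """

    center: tuple[float, float]
    axis_u: tuple[float, float]

    @property
    def axis_v(self) -> tuple[float, float]:
        """Unit vector along the line (perpendicular to the source axis)."""
        return (-self.axis_u[1], self.axis_u[0])

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        d = (p - np.asarray(self.center)) @ np.asarray(self.axis_u)
        return d if np.asarray(points).ndim == 2 else d[0]

    def reflect(self, points: np.ndarray) -> np.ndarray:
        """Mirror points across the line."""
        p = np.asarray(points, dtype=np.float64)
        u = np.asarray(self.axis_u)
        s = (np.atleast_2d(p) - np.asarray(self.center)) @ u
        out = np.atleast_2d(p) - 2.0 * s[:, None] * u[None, :]
        return out if p.ndim == 2 else out[0]


@dataclass(frozen=True)
class FittedEllipse:
    """Least-squares ellipse: center, semi-axes, major-axis rotation.

    ``angle`` is the rotation of the major axis from the image horizontal
    (the column axis), in [0, pi).
    """

    center: tuple[float, float]  # (row, col)
    semi_major: float
    semi_minor: float
    angle: float

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise FitError(
                f"invalid semi-axes a={self.semi_major}, b={self.semi_minor}"
            )

    @property
    def major_axis_direction(self) -> tuple[float, float]:
        # angle measured from the column axis toward the row axis
        return (float(np.sin(self.angle)), float(np.cos(self.angle)))


@dataclass(frozen=True)
class DeformationResult:
    """Unexposed/exposed extent ratios for one region of one colony."""

    region: str  # "periphery" or "core"
    horiz_ratio: float  # along the center→source axis
    vert_ratio: float  # along the perpendicular
    ellipse_unexposed: Optional[FittedEllipse] = None
    ellipse_exposed: Optional[FittedEllipse] = None


def separating_line(layout: ExperimentLayout) -> SeparatingLine:
    """Line through the seeding point, perpendicular to center→source.

    Controls have no source; they default to the image-vertical line with
    "exposed" pointing right (increasing column), so that downstream code
    has a consistent geometry to split against.
    """
    center = tuple(map(float, layout.colony_center))
    if layout.source_center is None:
        return SeparatingLine(center=center, axis_u=(0.0, 1.0))
    delta = np.asarray(layout.source_center, dtype=np.float64) - np.asarray(center)
    norm = float(np.hypot(*delta))
    if norm < 1e-9:
        raise GeometryError(
            f"{layout.image_id}: source coincides with the colony center"
        )
    u = delta / norm
    return SeparatingLine(center=center, axis_u=(float(u[0]), float(u[1])))


def _chains_on_side(
    vertices: np.ndarray, s: np.ndarray, keep: np.ndarray
) -> list[np.ndarray]:
    """Maximal runs of contour vertices on one side, with the two
    line-intersection points prepended/appended so every chain terminates
    on the line."""
    n = len(vertices)
    if keep.all() or not keep.any():
        return []
    # rotate so index 0 is the start of a kept run
    starts = np.where(keep & ~np.roll(keep, 1))[0]
    chains = []
    for start in starts:
        idx = [start]
        j = (start + 1) % n
        while keep[j]:
            idx.append(j)
            j = (j + 1) % n
        chain = vertices[idx]
        # entry intersection: between start-1 (off side) and start
        prev = (start - 1) % n
        entry = _interp_crossing(vertices[prev], vertices[start], s[prev], s[start])
        # exit intersection: between last kept and j (off side)
        last = idx[-1]
        exit_ = _interp_crossing(vertices[last], vertices[j], s[last], s[j])
        chains.append(np.vstack([entry, chain, exit_]))
    return chains


def _interp_crossing(p0: np.ndarray, p1: np.ndarray, s0: float, s1: float) -> np.ndarray:
    if s1 == s0:
        return p0.copy()
    t = s0 / (s0 - s1)
    return p0 + t * (p1 - p0)


def _polyline_length(poly: np.ndarray) -> float:
    return float(np.sum(np.hypot(*(np.diff(poly, axis=0).T))))


def split_halves(
    contour: Contour, line: SeparatingLine
) -> tuple[np.ndarray, np.ndarray]:
    """Split a closed contour into (unexposed, exposed) open polylines.

    Vertices are partitioned by the sign of their coordinate along the
    source axis; the two line-intersection points are interpolated so each
    polyline terminates on the separating line. If the boundary crosses the
    line more than twice (small edge wiggles), the longest arc on each side
    is used. Raises :class:`GeometryError` when the contour does not cross
    the line.
    """
    v = contour.vertices
    s = line.signed_distance(v)
    exposed_keep = s > 0
    unexposed_keep = s < 0
    if not exposed_keep.any() or not unexposed_keep.any():
        raise GeometryError("contour lies entirely on one side of the line")
    # vertices exactly on the line join the exposed side for partitioning;
    # they sit on the line so either assignment is geometrically neutral
    exposed_chains = _chains_on_side(v, s, s >= 0)
    unexposed_chains = _chains_on_side(v, s, s < 0)
    if not exposed_chains or not unexposed_chains:
        raise GeometryError("contour is tangent to the separating line")
    exposed = max(exposed_chains, key=_polyline_length)
    unexposed = max(unexposed_chains, key=_polyline_length)
    return unexposed, exposed


def mirror_half(half: np.ndarray, line: SeparatingLine) -> Contour:
    """Close a half-contour by appending its mirror image across the line.

    The reflected vertices are appended in reverse order, producing a
    closed contour symmetric about the separating line.
    """
    half = np.asarray(half, dtype=np.float64)
    reflected = line.reflect(half)[::-1]
    closed = np.vstack([half, reflected])
    return Contour.from_vertices(closed)


def fit_ellipse(contour: Contour | np.ndarray) -> FittedEllipse:
    """Direct least-squares algebraic ellipse fit to contour vertices.

    Needs at least 5 distinct points; collinear input raises
    :class:`FitError`. The returned angle is normalized so the major axis
    rotation lies in [0, pi) measured from the image horizontal.
    """
    pts = contour.vertices if isinstance(contour, Contour) else np.asarray(contour)
    pts = np.asarray(pts, dtype=np.float64)
    distinct = np.unique(np.round(pts, 9), axis=0)
    if distinct.shape[0] < 5:
        raise FitError(f"ellipse fit needs >= 5 distinct points, got {distinct.shape[0]}")
    # EllipseModel works in (x, y); use x=col, y=row so theta is measured
    # from the image horizontal
    xy = pts[:, ::-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = EllipseModel.from_estimate(xy)
        except AttributeError:  # older scikit-image
            model = EllipseModel()
            if not model.estimate(xy):
                model = None
        if model is None or not model:
            raise FitError("degenerate input: ellipse fit failed")
        try:
            xc, yc = (float(x) for x in model.center)
            a, b = (float(x) for x in model.axis_lengths)
            theta = float(model.theta)
        except AttributeError:
            xc, yc, a, b, theta = (float(x) for x in model.params)
    if not all(np.isfinite([xc, yc, a, b, theta])) or a <= 0 or b <= 0:
        raise FitError("degenerate input: ellipse fit returned invalid parameters")
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    theta = float(np.mod(theta, np.pi))
    return FittedEllipse(center=(yc, xc), semi_major=a, semi_minor=b, angle=theta)


def ellipse_extent(ellipse: FittedEllipse, direction: tuple[float, float]) -> float:
    """Half-extent (support) of the ellipse along a unit direction.

    For a direction at angle alpha to the major axis the half-width is
    sqrt(a^2 cos^2(alpha) + b^2 sin^2(alpha)).
    """
    d = np.asarray(direction, dtype=np.float64)
    norm = float(np.hypot(*d))
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ValueError(f"direction must be unit length, got |d|={norm}")
    m = np.asarray(ellipse.major_axis_direction)
    cos_a = float(np.clip(d @ m, -1.0, 1.0))
    sin_a2 = 1.0 - cos_a**2
    return float(np.sqrt(ellipse.semi_major**2 * cos_a**2 + ellipse.semi_minor**2 * sin_a2))


def deformation_ratios(
    contour: Contour,
    layout: ExperimentLayout,
    region: str = "periphery",
    line: Optional[SeparatingLine] = None,
) -> DeformationResult:
    """Horizontal/vertical unexposed-to-exposed deformation ratios.

    "Horizontal" is the center→source axis and "vertical" its
    perpendicular, so off-axis source placements are handled the same way
    as the canonical source-to-the-right geometry. Ratios above 1 indicate
    inhibition (smaller extent) on the exposed side.
    """
    if line is None:
        line = separating_line(layout)
    unexposed, exposed = split_halves(contour, line)
    ell_un = fit_ellipse(mirror_half(unexposed, line))
    ell_ex = fit_ellipse(mirror_half(exposed, line))
    horiz = ellipse_extent(ell_un, line.axis_u) / ellipse_extent(ell_ex, line.axis_u)
    vert = ellipse_extent(ell_un, line.axis_v) / ellipse_extent(ell_ex, line.axis_v)
    return DeformationResult(
        region=region,
        horiz_ratio=horiz,
        vert_ratio=vert,
        ellipse_unexposed=ell_un,
        ellipse_exposed=ell_ex,
    )
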