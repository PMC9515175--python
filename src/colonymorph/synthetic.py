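"""Seeded synthetic macrocolony generator with exact ground truth.

The forward model is deliberately minimal: a colony footprint built from
two half-ellipses that share the vertical axis through the seeding point
(unexposed horizontal semi-axis ``r_unexposed`` on the left, exposed
``r_exposed`` on the right), an inner core that is a scaled copy of the
footprint (symmetric by default, regardless of periphery asymmetry), flat
intensity levels per region, an optional intensity gradient linear in the
Euclidean distance from a virtual source (centered by subtracting the mean
colony distance so the region levels keep their meaning), and additive
Gaussian pixel noise. Every derived quantity the pipeline measures —
areas, deformation ratios, the gradient slope — therefore has an exact
known value.

Two half-ellipses are the smallest shape family for which the mirrored
half-contour ellipse metric has a closed-form answer: the horizontal
deformation ratio of the footprint is exactly ``r_unexposed/r_exposed``.
Crescent (concave) morphologies are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ColonyImage, ExperimentLayout, write_layout

__all__ = [
    "SyntheticSpec",
    "GroupSpec",
    "CohortResult",
    "DEFAULT_GROUPS",
    "generate_colony",
    "generate_cohort",
]

#: Radius growth factor by imaging day (day 3 = mature size).
DAY_SCALE = {1: 0.5, 2: 0.75, 3: 1.0}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic colony image.

    Lengths are in pixels; intensities in [0, 1]. Defaults draw a mature
    (day-3 sized) symmetric colony on a 360x360 grid at 50 µm/pixel, so a
    nominal source distance of 1 cm is 200 px from the seeding point.
    """

    shape: tuple[int, int] = (360, 360)
    center: tuple[float, float] = (180.0, 180.0)
    r_unexposed: float = 100.0  # horizontal semi-axis, left of center
    r_exposed: float = 100.0  # horizontal semi-axis, right of center
    r_vertical: float = 90.0
    core_scale: float = 0.4  # core semi-axes = core_scale x colony semi-axes
    core_asymmetry: float = 1.0  # exposed core semi-axis factor (1 = symmetric)
    background_level: float = 0.08
    periphery_level: float = 0.45
    core_level: float = 0.85
    gradient: float = 0.0  # intensity per px of distance from the source
    source: Optional[tuple[float, float]] = None
    distance_cm: Optional[float] = None
    noise_sd: float = 0.02
    pixel_size_um: float = 50.0
    seed: int = 0
    day: int = 3
    group_label: str = "control"
    image_id: str = "synthetic"

    def __post_init__(self) -> None:
        if min(self.r_unexposed, self.r_exposed, self.r_vertical) <= 0:
            raise ValueError("all semi-axes must be > 0")
        if not (0.0 < self.core_scale < 1.0):
            raise ValueError(f"core_scale must be in (0, 1), got {self.core_scale}")
        if self.core_asymmetry <= 0:
            raise ValueError("core_asymmetry must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("background_level", "periphery_level", "core_level"):
            level = getattr(self, name)
            if level - 3 * self.noise_sd < -1e-9 or level + 3 * self.noise_sd > 1.0 + 1e-9:
                raise ValueError(
                    f"{name}={level} with noise_sd={self.noise_sd}: mean ± 3 sd "
                    "must stay inside [0, 1]"
                )

    @property
    def source_position(self) -> Optional[tuple[float, float]]:
        """Virtual source: explicit position, or placed horizontally to the
        right at the nominal distance converted through the calibration."""
        if self.source is not None:
            return self.source
        if self.distance_cm is not None:
            px = self.distance_cm * 1e4 / self.pixel_size_um
            return (self.center[0], self.center[1] + px)
        return None


def _half_ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    r_left: float,
    r_right: float,
    r_vert: float,
) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    cr, cc = center
    r_h = np.where(cols < cc, r_left, r_right)
    return (rows - cr) ** 2 / r_vert**2 + (cols - cc) ** 2 / r_h**2 <= 1.0


def generate_colony(
    spec: SyntheticSpec, seed: Optional[int] = None
) -> tuple[ColonyImage, ExperimentLayout, dict]:
    """Render one synthetic colony; returns image, layout and ground truth.

    Deterministic given the seed (``spec.seed`` unless overridden). The
    ground-truth dict carries the exact semi-axes, analytic region areas
    and the deformation ratios the pipeline is expected to recover.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    per_mask = _half_ellipse_mask(
        spec.shape, spec.center, spec.r_unexposed, spec.r_exposed, spec.r_vertical
    )
    core_ru = spec.core_scale * spec.r_unexposed
    core_re = core_ru * spec.core_asymmetry
    core_rv = spec.core_scale * spec.r_vertical
    core_mask = _half_ellipse_mask(spec.shape, spec.center, core_ru, core_re, core_rv)

    img = np.full(spec.shape, spec.background_level, dtype=np.float64)
    img[per_mask] = spec.periphery_level
    img[core_mask] = spec.core_level

    source = spec.source_position
    if spec.gradient != 0.0 and source is not None:
        rows, cols = np.mgrid[0 : spec.shape[0], 0 : spec.shape[1]]
        d = np.hypot(rows - source[0], cols - source[1])
        d_mean = d[per_mask].mean()
        img[per_mask] += spec.gradient * (d[per_mask] - d_mean)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    np.clip(img, 0.0, 1.0, out=img)

    image = ColonyImage(
        pixels=img,
        pixel_size_um=spec.pixel_size_um,
        source_path=f"synthetic:{spec.image_id}",
        channel_label="GFP",
    )
    layout = ExperimentLayout(
        image_id=spec.image_id,
        colony_center=spec.center,
        source_center=source,
        nominal_distance_cm=spec.distance_cm,
        day=spec.day,
        group_label=spec.group_label,
    )
    truth = {
        "image_id": spec.image_id,
        "group": spec.group_label,
        "day": spec.day,
        "r_unexposed": spec.r_unexposed,
        "r_exposed": spec.r_exposed,
        "r_vertical": spec.r_vertical,
        "core_r_unexposed": core_ru,
        "core_r_exposed": core_re,
        "core_r_vertical": core_rv,
        "periphery_area_px": np.pi * spec.r_vertical * (spec.r_unexposed + spec.r_exposed) / 2.0,
        "core_area_px": np.pi * core_rv * (core_ru + core_re) / 2.0,
        "horiz_ratio_periphery": spec.r_unexposed / spec.r_exposed,
        "vert_ratio_periphery": 1.0,
        "horiz_ratio_core": 1.0 / spec.core_asymmetry,
        "vert_ratio_core": 1.0,
        "gradient": spec.gradient,
        "noise_sd": spec.noise_sd,
    }
    return image, layout, truth


@dataclass(frozen=True)
class GroupSpec:
    """Per-group cohort parameters.

    ``asymmetry`` is the exposed/unexposed footprint factor f (exposed
    horizontal semi-axis = f x unexposed); the expected horizontal
    deformation ratio of the group is therefore 1/f.
    """

    name: str
    n: int
    distance_cm: Optional[float] = None
    asymmetry: float = 1.0
    gradient: float = 0.0
    core_asymmetry: float = 1.0


#: Study-design defaults: group sizes 12/11/9/12 (1, 1.5, 2 cm, control),
#: inhibition strength falling off with source distance, a near-source
#: intensity gradient ten times the far-source one, and symmetric cores.
DEFAULT_GROUPS = (
    GroupSpec(name="1cm", n=12, distance_cm=1.0, asymmetry=0.70, gradient=5e-4),
    GroupSpec(name="1.5cm", n=11, distance_cm=1.5, asymmetry=0.90, gradient=1.5e-4),
    GroupSpec(name="2cm", n=9, distance_cm=2.0, asymmetry=0.97, gradient=5e-5),
    GroupSpec(name="control", n=12),
)


@dataclass(frozen=True)
class CohortResult:
    colonies: list[tuple[ColonyImage, ExperimentLayout, dict]]
    truth: pd.DataFrame
    layouts: list[ExperimentLayout] = field(default_factory=list)


def _plate_rng(master_seed: int, group_index: int, plate_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, group_index, plate_index])
    return np.random.default_rng(ss)


def generate_cohort(
    groups: Sequence[GroupSpec] = DEFAULT_GROUPS,
    master_seed: int = 0,
    days: Sequence[int] = (3,),
    base_spec: Optional[SyntheticSpec] = None,
    jitter_sd: float = 0.03,
    out_dir: Optional[str | Path] = None,
) -> CohortResult:
    """Generate a cohort of synthetic plates, one image per plate per day.

    Plate-to-plate variability is multiplicative: each plate's semi-axes
    are scaled by independent ``1 + N(0, jitter_sd)`` factors (fixed for
    the plate across days, as a real plate keeps its identity under daily
    imaging); day ``d`` scales all radii by ``DAY_SCALE[d]``. Per-plate
    random streams are derived from ``(master_seed, group, plate)`` so any
    subset of the cohort is reproducible in isolation.

    With ``out_dir`` set, writes 16-bit PNG images plus ``layout.csv`` and
    ``truth.csv`` — everything the CLI pipeline consumes.
    """
    base = base_spec if base_spec is not None else SyntheticSpec()
    colonies: list[tuple[ColonyImage, ExperimentLayout, dict]] = []
    truth_rows: list[dict] = []
    for gi, group in enumerate(groups):
        if group.n <= 0:
            warnings.warn(f"group {group.name!r} has n={group.n}; omitted", stacklevel=2)
            continue
        for ci in range(group.n):
            rng = _plate_rng(master_seed, gi, ci)
            ju, je, jv = 1.0 + rng.normal(0.0, jitter_sd, size=3)
            r_u = base.r_unexposed * ju
            r_e = base.r_unexposed * group.asymmetry * je
            r_v = base.r_vertical * jv
            noise_seeds = rng.integers(0, 2**31 - 1, size=len(days))
            for di, day in enumerate(days):
                scale = DAY_SCALE.get(day, 1.0)
                spec = replace(
                    base,
                    r_unexposed=r_u * scale,
                    r_exposed=r_e * scale,
                    r_vertical=r_v * scale,
                    core_asymmetry=group.core_asymmetry,
                    gradient=group.gradient,
                    distance_cm=group.distance_cm,
                    source=None,
                    day=int(day),
                    group_label=group.name,
                    image_id=f"{group.name}_p{ci:02d}_d{day}",
                    seed=int(noise_seeds[di]),
                )
                image, layout, truth = generate_colony(spec)
                colonies.append((image, layout, truth))
                truth_rows.append(truth)
    truth_df = pd.DataFrame(truth_rows)
    layouts = [lay for _, lay, _ in colonies]
    if out_dir is not None:
        _write_cohort(colonies, truth_df, Path(out_dir))
    return CohortResult(colonies=colonies, truth=truth_df, layouts=layouts)


def _write_cohort(
    colonies: list[tuple[ColonyImage, ExperimentLayout, dict]],
    truth: pd.DataFrame,
    out_dir: Path,
) -> None:
    import imageio.v3 as iio

    out_dir.mkdir(parents=True, exist_ok=True)
    img_dir = out_dir / "images"
    img_dir.mkdir(exist_ok=True)
    for image, layout, _ in colonies:
        samples = np.round(image.pixels * 65535.0).astype(np.uint16)
        iio.imwrite(img_dir / f"{layout.image_id}.png", samples)
    write_layout([lay for _, lay, _ in colonies], out_dir / "layout.csv")
    truth.to_csv(out_dir / "truth.csv", index=False, float_format="%.17g")
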