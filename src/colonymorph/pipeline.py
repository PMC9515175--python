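"""End-to-end orchestration: images + layout → measurements → statistics.

``analyze_image`` turns one (image, layout) pair into the full set of
per-colony scalar measurements; ``run_pipeline`` maps it over a cohort,
writes the tidy measurement CSV, and runs the group-vs-control comparisons.
All randomness lives in the synthetic generator, so reruns with the same
inputs and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .errors import ColonyMorphError, ConfigError
from .group_stats import compare_to_control, comparison_table
from .intensity import (
    control_augmented_ratio,
    edge_regression,
    intensity_ratio,
    leading_edge_band,
    region_masks,
)
from .io import (
    ColonyImage,
    ExperimentLayout,
    MeasurementRecord,
    load_image,
    read_layout,
    write_records,
)
from .morphometrics import deformation_ratios, separating_line
from .segmentation import BinaryMask, coverage_area, segment_colony
from .synthetic import DEFAULT_GROUPS, generate_cohort

logger = logging.getLogger("colonymorph")

__all__ = ["AnalysisParams", "RunConfig", "analyze_image", "run_pipeline", "PipelineError"]


class PipelineError(ColonyMorphError):
    """A stage failed for a specific image."""

    def __init__(self, image_id: str, stage: str, cause: Exception):
        super().__init__(f"image {image_id!r}: stage {stage!r} failed: {cause}")
        self.image_id = image_id
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class AnalysisParams:
    """Per-image analysis knobs (segmentation, morphometrics, intensity)."""

    kernel: int = 5
    min_core_area_frac: float = 0.01
    max_core_area_frac: float = 0.90
    min_core_contrast: float = 0.10
    band_width: int = 20
    center_mode: str = "layout"  # or "centroid"

    def __post_init__(self) -> None:
        if self.center_mode not in ("layout", "centroid"):
            raise ConfigError(f"unknown center_mode {self.center_mode!r}")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs."""

    images_dir: Optional[str] = None
    layout_csv: Optional[str] = None
    out_dir: str = "results"
    params: AnalysisParams = field(default_factory=AnalysisParams)
    control_label: str = "control"
    welch: bool = False
    pixel_size_um: float = 1.0
    seed: int = 0
    simulate_demo: bool = False  # generate the default 44-plate cohort first


def analyze_image(
    image: ColonyImage,
    layout: ExperimentLayout,
    params: AnalysisParams = AnalysisParams(),
) -> list[MeasurementRecord]:
    """All scalar measurements for one colony image.

    Controls get augmented intensity ratios and no edge regression (there
    is no source to measure distances from); colonies without a detectable
    core get periphery metrics only.
    """
    stage = "segmentation"
    try:
        seg = segment_colony(
            image,
            kernel=params.kernel,
            min_core_area_frac=params.min_core_area_frac,
            max_core_area_frac=params.max_core_area_frac,
            min_core_contrast=params.min_core_contrast,
        )
        if params.center_mode == "centroid":
            centroid = seg.periphery.representative_point()
            layout = replace(layout, colony_center=(float(centroid[0]), float(centroid[1])))
        layout.validate_against(image)

        def rec(metric: str, value: float) -> MeasurementRecord:
            return MeasurementRecord(
                image_id=layout.image_id, group_label=layout.group_label,
                day=layout.day, metric=metric, value=float(value),
            )

        records = [rec("coverage_area_um2", coverage_area(seg.periphery, image.pixel_size_um))]

        stage = "morphometrics"
        line = separating_line(layout)
        per_def = deformation_ratios(seg.periphery, layout, "periphery", line=line)
        records += [
            rec("horiz_ratio_periphery", per_def.horiz_ratio),
            rec("vert_ratio_periphery", per_def.vert_ratio),
        ]
        if seg.core is not None:
            core_def = deformation_ratios(seg.core, layout, "core", line=line)
            records += [
                rec("horiz_ratio_core", core_def.horiz_ratio),
                rec("vert_ratio_core", core_def.vert_ratio),
            ]

        stage = "intensity"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            masks = region_masks(seg.periphery, seg.core, line, image.pixels.shape)
        regions = ["periphery"] + (["core"] if seg.core is not None else [])
        for region in regions:
            if layout.is_control:
                union = BinaryMask(
                    masks[f"{region}_exposed"].pixels | masks[f"{region}_unexposed"].pixels,
                    role=region,
                )
                result = control_augmented_ratio(image, union, layout.colony_center, region)
            else:
                result = intensity_ratio(
                    image, masks[f"{region}_exposed"], masks[f"{region}_unexposed"], region
                )
            records.append(rec(f"intensity_ratio_{region}", result.ratio))

        if not layout.is_control:
            stage = "edge_regression"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                band = leading_edge_band(
                    seg.periphery, line, image.pixels.shape, width=params.band_width
                )
            if band.count >= 2:
                fit = edge_regression(image, band, layout.source_center)
                records += [
                    rec("edge_slope", fit.slope),
                    rec("edge_intercept", fit.intercept),
                    rec("edge_r2", fit.r_squared),
                ]
        return records
    except ColonyMorphError as exc:
        raise PipelineError(layout.image_id, stage, exc) from exc


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write measurement and comparison CSVs.

    Returns the paths of the written artifacts. Raises
    :class:`PipelineError` (naming image and stage) on the first failing
    image, and :class:`ConfigError` for missing inputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate_demo:
        sim_dir = out_dir / "simulated"
        generate_cohort(DEFAULT_GROUPS, master_seed=config.seed, out_dir=sim_dir)
        images_dir = sim_dir / "images"
        layout_csv = sim_dir / "layout.csv"
        pixel_size = 50.0  # calibration of the synthetic generator
    else:
        if config.images_dir is None or config.layout_csv is None:
            raise ConfigError("images_dir and layout_csv are required unless simulating")
        images_dir = Path(config.images_dir)
        layout_csv = Path(config.layout_csv)
        pixel_size = config.pixel_size_um
    if not images_dir.is_dir():
        raise ConfigError(f"images directory not found: {images_dir}")

    layouts = read_layout(layout_csv)
    records: list[MeasurementRecord] = []
    for layout in layouts:
        path = _find_image(images_dir, layout.image_id)
        if path is None:
            raise ConfigError(f"no image file for id {layout.image_id!r} in {images_dir}")
        image = load_image(path, pixel_size_um=pixel_size)
        logger.info("analyzing %s (group=%s day=%d)", layout.image_id,
                    layout.group_label, layout.day)
        records.extend(analyze_image(image, layout, config.params))

    measurements_csv = out_dir / "measurements.csv"
    write_records(records, measurements_csv)

    comparisons = compare_to_control(
        records, control_label=config.control_label, welch=config.welch
    )
    comparisons_csv = out_dir / "comparisons.csv"
    comparison_table(comparisons).to_csv(
        comparisons_csv, index=False, float_format="%.17g"
    )

    run_log = out_dir / "run_log.json"
    run_log.write_text(
        json.dumps(
            {
                "version": __version__,
                "config": _config_dict(config),
                "n_images": len(layouts),
                "n_records": len(records),
            },
            indent=2,
            sort_keys=True,
        )
    )
    return {
        "measurements": measurements_csv,
        "comparisons": comparisons_csv,
        "run_log": run_log,
    }


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _find_image(images_dir: Path, image_id: str) -> Optional[Path]:
    for ext in (".png", ".tif", ".tiff", ".nd2"):
        candidate = images_dir / f"{image_id}{ext}"
        if candidate.exists():
            return candidate
    return None
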