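"""Image and tabular I/O.

Images are normalized to float64 intensities in [0, 1] at load time: integer
samples are divided by the full-scale value of their bit depth (255 for 8-bit,
65535 for 16-bit), mirroring the usual fluorescence-microscopy convention of
treating detector counts as a fraction of the dynamic range. Experiment
layouts (seeding-point and antimicrobial-source coordinates) travel in a flat
CSV so that no GUI step is needed to mark colony centers.

Coordinate convention used throughout the package: ``(row, col)``, 0-based,
origin at the top-left image corner.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ImageReadError, LayoutError, UnsupportedFormatError

__all__ = [
    "ColonyImage",
    "ExperimentLayout",
    "MeasurementRecord",
    "METRIC_NAMES",
    "load_image",
    "to_grayscale",
    "read_layout",
    "write_layout",
    "write_records",
    "read_records",
]

#: Fixed vocabulary of per-colony scalar outputs.
METRIC_NAMES = frozenset(
    {
        "coverage_area_um2",
        "horiz_ratio_periphery",
        "vert_ratio_periphery",
        "horiz_ratio_core",
        "vert_ratio_core",
        "intensity_ratio_periphery",
        "intensity_ratio_core",
        "edge_slope",
        "edge_intercept",
        "edge_r2",
    }
)

#: RGB → luminance weights (ITU-R BT.601), the standard grayscale convention.
GRAY_WEIGHTS_RGB = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class ColonyImage:
    """A single-channel 2D intensity grid with pixel calibration.

    Parameters
    ----------
    pixels : ndarray of float64, shape (H, W)
        Intensities in [0, 1].
    pixel_size_um : float
        Physical size of one pixel in micrometers (> 0).
    source_path : str
        Provenance string (file the image came from, or "synthetic").
    channel_label : str
        Free-text channel name, e.g. ``"GFP"``.
    """

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    source_path: str = ""
    channel_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must all be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "ColonyImage":
        """Copy of this image with a new pixel grid, same calibration."""
        return replace(self, pixels=pixels)


def _is_control_label(label: str) -> bool:
    return label.strip().lower() == "control"


@dataclass(frozen=True)
class ExperimentLayout:
    """Per-image experiment geometry: seeding point, source, day, group.

    ``source_center is None`` marks a control colony (no antimicrobial
    droplet); this must coincide with a control ``group_label``.
    """

    image_id: str
    colony_center: tuple[float, float]
    source_center: Optional[tuple[float, float]] = None
    nominal_distance_cm: Optional[float] = None
    day: int = 1
    group_label: str = "control"

    def __post_init__(self) -> None:
        if self.day < 1:
            raise LayoutError(f"{self.image_id}: day must be >= 1, got {self.day}")
        if self.nominal_distance_cm is not None and not (self.nominal_distance_cm > 0):
            raise LayoutError(
                f"{self.image_id}: nominal_distance_cm must be > 0, "
                f"got {self.nominal_distance_cm}"
            )
        if self.is_control != (self.source_center is None):
            raise LayoutError(
                f"{self.image_id}: source_center must be absent if and only if "
                f"the group label is 'control' (group={self.group_label!r}, "
                f"source={self.source_center!r})"
            )

    @property
    def is_control(self) -> bool:
        return _is_control_label(self.group_label)

    def validate_against(self, image: ColonyImage) -> None:
        """Check that the colony center lies inside the image bounds."""
        r, c = self.colony_center
        if not (0 <= r < image.height and 0 <= c < image.width):
            raise LayoutError(
                f"{self.image_id}: colony_center {self.colony_center} outside "
                f"image bounds {image.height}x{image.width}"
            )


@dataclass(frozen=True)
class MeasurementRecord:
    """One colony-day scalar output — the row type of all result CSVs."""

    image_id: str
    group_label: str
    day: int
    metric: str
    value: float

    def __post_init__(self) -> None:
        if self.metric not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not math.isfinite(self.value):
            raise ValueError(f"{self.image_id}/{self.metric}: value must be finite")


def _scale_integer_samples(arr: np.ndarray) -> np.ndarray:
    info = np.iinfo(arr.dtype)
    return arr.astype(np.float64) / float(info.max)


def load_image(
    path: str | Path,
    channel: Optional[int] = None,
    pixel_size_um: float = 1.0,
    channel_label: str = "",
) -> ColonyImage:
    """Load a PNG/TIFF (or, if a reader is installed, ND2) image.

    Integer samples are scaled by ``1 / (2**bitdepth - 1)`` into [0, 1];
    floating-point input is assumed to already be normalized. Multi-channel
    data is reduced to ``channel`` when given, otherwise converted to
    grayscale with the fixed luminance weights.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"image file not found: {path}")
    if path.suffix.lower() == ".nd2":
        arr = _read_nd2(path)
    else:
        try:
            import imageio.v3 as iio

            arr = iio.imread(path)
        except ImageReadError:
            raise
        except Exception as exc:  # noqa: BLE001 - wrap reader-specific errors
            raise ImageReadError(f"could not read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = _scale_integer_samples(arr)
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        if channel is not None:
            if not (0 <= channel < arr.shape[-1]):
                raise ValueError(
                    f"channel index {channel} out of range for {arr.shape[-1]} channels"
                )
            arr = arr[..., channel]
        else:
            arr = _gray_from_channels(arr)
    elif arr.ndim != 2:
        raise ImageReadError(f"{path}: expected a 2D or 3D image, got shape {arr.shape}")
    arr = np.clip(arr, 0.0, 1.0)
    return ColonyImage(
        pixels=arr,
        pixel_size_um=pixel_size_um,
        source_path=str(path),
        channel_label=channel_label,
    )


def _read_nd2(path: Path) -> np.ndarray:
    """Load an ND2 file through whichever optional reader is installed."""
    for mod_name in ("nd2", "nd2reader"):
        try:
            mod = __import__(mod_name)
        except ImportError:
            continue
        if mod_name == "nd2":
            return np.asarray(mod.imread(str(path)))
        with mod.ND2Reader(str(path)) as reader:  # pragma: no cover - optional
            return np.asarray(reader[0])
    raise UnsupportedFormatError(
        f"{path}: ND2 support requires the optional 'nd2' or 'nd2reader' package; "
        "convert the file to TIFF/PNG or install one of them"
    )


def _gray_from_channels(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[-1]
    if n == 1:
        return arr[..., 0]
    if n == 2:
        w: Sequence[float] = (0.5, 0.5)
    elif n in (3, 4):
        arr = arr[..., :3]
        w = GRAY_WEIGHTS_RGB
    else:
        raise ValueError(f"cannot convert {n}-channel image to grayscale")
    return np.tensordot(arr, np.asarray(w, dtype=np.float64), axes=([-1], [0]))


def to_grayscale(image: ColonyImage | np.ndarray, pixel_size_um: float = 1.0) -> ColonyImage:
    """Collapse a 2- or 3-channel image to one channel with fixed weights.

    Single-channel input is returned unchanged. RGB uses the BT.601
    luminance weights (0.299, 0.587, 0.114); 2-channel input is averaged.
    """
    if isinstance(image, ColonyImage):
        return image  # already single-channel by construction
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        return ColonyImage(pixels=np.clip(arr, 0.0, 1.0), pixel_size_um=pixel_size_um)
    if arr.ndim != 3:
        raise ValueError(f"expected 2D or 3D array, got shape {arr.shape}")
    gray = _gray_from_channels(arr)
    return ColonyImage(pixels=np.clip(gray, 0.0, 1.0), pixel_size_um=pixel_size_um)


# --- layout tables ---------------------------------------------------------

LAYOUT_COLUMNS = [
    "image_id",
    "center_row",
    "center_col",
    "source_row",
    "source_col",
    "distance_cm",
    "day",
    "group",
]


def read_layout(path: str | Path) -> list[ExperimentLayout]:
    """Parse a layout CSV (one row per image) into validated layouts.

    Empty ``source_row``/``source_col``/``distance_cm`` fields produce a
    control layout. Malformed rows raise :class:`LayoutError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise LayoutError(f"layout file not found: {path}")
    df = pd.read_csv(path, dtype={"image_id": str, "group": str})
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"{path}: missing layout columns {missing}")
    layouts = []
    for i, row in df.iterrows():
        try:
            src = None
            if not (pd.isna(row["source_row"]) or pd.isna(row["source_col"])):
                src = (float(row["source_row"]), float(row["source_col"]))
            dist = None if pd.isna(row["distance_cm"]) else float(row["distance_cm"])
            layouts.append(
                ExperimentLayout(
                    image_id=str(row["image_id"]),
                    colony_center=(float(row["center_row"]), float(row["center_col"])),
                    source_center=src,
                    nominal_distance_cm=dist,
                    day=int(row["day"]),
                    group_label=str(row["group"]),
                )
            )
        except (ValueError, TypeError, LayoutError) as exc:
            raise LayoutError(f"{path}: row {i + 2}: {exc}") from exc
    return layouts


def write_layout(layouts: Sequence[ExperimentLayout], path: str | Path) -> None:
    """Write layouts to CSV; inverse of :func:`read_layout`."""
    rows = []
    for lay in layouts:
        sr, sc = (lay.source_center if lay.source_center is not None else (None, None))
        rows.append(
            {
                "image_id": lay.image_id,
                "center_row": lay.colony_center[0],
                "center_col": lay.colony_center[1],
                "source_row": sr,
                "source_col": sc,
                "distance_cm": lay.nominal_distance_cm,
                "day": lay.day,
                "group": lay.group_label,
            }
        )
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


RECORD_COLUMNS = ["image_id", "group", "day", "metric", "value"]


def write_records(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    """Write measurement records as CSV with a fixed header.

    Values are printed with 17 significant digits so the write/read cycle is
    lossless for float64.
    """
    try:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(RECORD_COLUMNS)
            for rec in records:
                writer.writerow(
                    [rec.image_id, rec.group_label, rec.day, rec.metric,
                     format(rec.value, ".17g")]
                )
    except OSError as exc:
        raise ImageReadError(f"cannot write records to {path}: {exc}") from exc


def read_records(path: str | Path) -> list[MeasurementRecord]:
    """Read a records CSV written by :func:`write_records`."""
    df = pd.read_csv(path, dtype={"image_id": str, "group": str},
                     float_precision="round_trip")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing record columns {missing}")
    return [
        MeasurementRecord(
            image_id=str(r["image_id"]),
            group_label=str(r["group"]),
            day=int(r["day"]),
            metric=str(r["metric"]),
            value=float(r["value"]),
        )
        for _, r in df.iterrows()
    ]


def records_to_frame(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    """Convenience: records as a tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "group": r.group_label,
                "day": r.day,
                "metric": r.metric,
                "value": r.value,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )
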