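import numpy as np
import pytest

from colonymorph import ColonyImage, ExperimentLayout
from colonymorph.synthetic import SyntheticSpec, generate_colony


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def treated_colony():
    """Asymmetric colony (f=0.7) with a source 1 cm to the right."""
    spec = SyntheticSpec(
        group_label="1cm", distance_cm=1.0, r_exposed=70.0, gradient=5e-4, seed=11
    )
    return generate_colony(spec)


@pytest.fixture
def symmetric_colony():
    """Line-symmetric treated colony (no deformation, no gradient)."""
    spec = SyntheticSpec(group_label="1cm", distance_cm=1.0, seed=4)
    return generate_colony(spec)


@pytest.fixture
def control_colony():
    spec = SyntheticSpec(group_label="control", seed=5)
    return generate_colony(spec)


def disk_image(shape=(240, 240), center=(120.0, 120.0), radius=80.0,
               level=0.5, background=0.08) -> ColonyImage:
    """Plain bright disk, no core — hand-rolled so tests don't depend on
    the generator for the simplest shapes."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    r = np.hypot(rows - center[0], cols - center[1])
    px = np.where(r <= radius, level, background)
    return ColonyImage(px, pixel_size_um=1.0)


def circle_contour(center=(0.0, 0.0), radius=10.0, n=360) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.sin(t),
                            center[1] + radius * np.cos(t)])


def right_source_layout(image_id="img", center=(120.0, 120.0), source_col_offset=300.0,
                        group="1cm", day=3) -> ExperimentLayout:
    return ExperimentLayout(
        image_id=image_id,
        colony_center=center,
        source_center=(center[0], center[1] + source_col_offset),
        nominal_distance_cm=1.0,
        day=day,
        group_label=group,
    )
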