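"""Region intensity ratios, control augmentation, leading-edge regression."""

import numpy as np
import pytest

from colonymorph import (
    ColonyImage,
    DegenerateRegionError,
    GeometryError,
    control_augmented_ratio,
    edge_regression,
    intensity_ratio,
    leading_edge_band,
    pixel_distances,
    region_masks,
    segment_colony,
    separating_line,
)
from colonymorph.segmentation import BinaryMask, Contour
from colonymorph.synthetic import SyntheticSpec, generate_colony

from conftest import circle_contour, disk_image, right_source_layout


@pytest.fixture
def disk_regions():
    """Disk periphery r=100 with core r=40, vertical line through center."""
    periphery = Contour.from_vertices(circle_contour((120.0, 120.0), 100.0, n=720))
    core = Contour.from_vertices(circle_contour((120.0, 120.0), 40.0, n=720))
    line = separating_line(right_source_layout(center=(120.0, 120.0)))
    return periphery, core, line


class TestRegionMasks:
    def test_half_annulus_and_half_disk_pixel_counts(self, disk_regions):
        periphery, core, line = disk_regions
        masks = region_masks(periphery, core, line, (240, 240))
        half_annulus = np.pi * (100**2 - 40**2) / 2
        half_core = np.pi * 40**2 / 2
        for key, expected in [
            ("periphery_exposed", half_annulus),
            ("periphery_unexposed", half_annulus),
            ("core_exposed", half_core),
            ("core_unexposed", half_core),
        ]:
            assert abs(masks[key].count / expected - 1) < 0.02

    def test_absent_core_yields_periphery_only_with_warning(self, disk_regions):
        periphery, _, line = disk_regions
        with pytest.warns(UserWarning, match="core"):
            masks = region_masks(periphery, None, line, (240, 240))
        assert set(masks) == {"periphery_exposed", "periphery_unexposed"}

    def test_line_outside_colony_is_geometry_error(self, disk_regions):
        periphery, core, _ = disk_regions
        layout = right_source_layout(center=(120.0, 230.0))
        with pytest.raises(GeometryError):
            region_masks(periphery, core, separating_line(layout), (240, 240))


class TestIntensityRatio:
    def test_uniform_image_gives_unit_ratio(self, disk_regions):
        periphery, core, line = disk_regions
        masks = region_masks(periphery, core, line, (240, 240))
        img = ColonyImage(np.full((240, 240), 0.6))
        res = intensity_ratio(
            img, masks["periphery_exposed"], masks["periphery_unexposed"], "periphery"
        )
        assert res.ratio == 1.0

    def test_half_levels_give_their_quotient(self, disk_regions):
        periphery, core, line = disk_regions
        masks = region_masks(periphery, core, line, (240, 240))
        px = np.where(np.arange(240)[None, :] > 120, 0.4, 0.8)
        px = np.broadcast_to(px, (240, 240)).copy()
        px[:, 120] = 0.8
        res = intensity_ratio(
            ColonyImage(px), masks["periphery_exposed"], masks["periphery_unexposed"],
            "periphery",
        )
        assert res.ratio == pytest.approx(0.5)

    def test_matches_per_pixel_summation_oracle(self, disk_regions, rng):
        periphery, core, line = disk_regions
        masks = region_masks(periphery, core, line, (240, 240))
        img = ColonyImage(rng.uniform(0.1, 0.9, (240, 240)))
        res = intensity_ratio(
            img, masks["core_exposed"], masks["core_unexposed"], "core"
        )
        sums = {}
        for key in ("core_exposed", "core_unexposed"):
            total, count = 0.0, 0
            for r, c in np.argwhere(masks[key].pixels):
                total += float(img.pixels[r, c])
                count += 1
            sums[key] = total / count
        assert res.ratio == pytest.approx(
            sums["core_exposed"] / sums["core_unexposed"], abs=1e-9
        )

    def test_empty_mask_is_degenerate(self, disk_regions):
        periphery, core, line = disk_regions
        masks = region_masks(periphery, core, line, (240, 240))
        empty = BinaryMask(np.zeros((240, 240), dtype=bool))
        with pytest.raises(DegenerateRegionError):
            intensity_ratio(ColonyImage(np.full((240, 240), 0.5)),
                            empty, masks["core_unexposed"], "core")

    def test_mirrored_image_inverts_the_ratio(self):
        # symmetric footprint, gradient left-to-right, exact integer center
        spec = SyntheticSpec(
            shape=(361, 361), center=(180.0, 180.0), gradient=4e-4,
            distance_cm=1.0, group_label="1cm", noise_sd=0.0,
        )
        image, layout, _ = generate_colony(spec)
        seg = segment_colony(image)
        line = separating_line(layout)
        masks = region_masks(seg.periphery, seg.core, line, image.pixels.shape)
        args = (masks["periphery_exposed"], masks["periphery_unexposed"], "periphery")
        forward = intensity_ratio(image, *args)
        mirrored = ColonyImage(image.pixels[:, ::-1].copy(),
                               pixel_size_um=image.pixel_size_um)
        backward = intensity_ratio(mirrored, *args)
        assert backward.ratio == pytest.approx(1.0 / forward.ratio, abs=1e-6)


class TestControlAugmentation:
    def test_uniform_image_gives_exactly_one(self, disk_regions):
        periphery, _, line = disk_regions
        mask = BinaryMask(periphery.rasterize((240, 240)))
        res = control_augmented_ratio(
            ColonyImage(np.full((240, 240), 0.5)), mask, (120.0, 120.0), "periphery"
        )
        assert res.ratio == 1.0
        assert res.partition_ratios == (1.0, 1.0, 1.0)

    def test_left_bright_fixture_averages_to_four_thirds(self, disk_regions):
        # left half 1.0, right half 0.5: partitions give {2, 1, 1} -> 4/3
        periphery, _, line = disk_regions
        mask = BinaryMask(periphery.rasterize((240, 240)))
        px = np.where(np.arange(240)[None, :] < 120, 1.0, 0.5)
        px = np.broadcast_to(px, (240, 240)).copy()
        res = control_augmented_ratio(
            ColonyImage(px), mask, (120.0, 120.0), "periphery"
        )
        assert res.partition_ratios[0] == pytest.approx(2.0, abs=1e-3)
        assert res.partition_ratios[1] == pytest.approx(1.0, abs=1e-3)
        assert res.partition_ratios[2] == pytest.approx(1.0, abs=1e-3)
        assert res.ratio == pytest.approx(4.0 / 3.0, abs=2e-3)

    def test_mirror_symmetric_image_has_unit_left_right_and_diagonal_ratios(self):
        # mirror symmetry about the vertical axis swaps TL<->TR and BL<->BR,
        # so both the left/right and the diagonal partitions balance exactly
        rng = np.random.default_rng(3)
        half = rng.uniform(0.2, 0.8, (241, 120))
        px = np.hstack([half, np.full((241, 1), 0.5), half[:, ::-1]])
        mask = BinaryMask(np.ones(px.shape, dtype=bool))
        res = control_augmented_ratio(ColonyImage(px), mask, (120.0, 120.0), "colony")
        assert res.partition_ratios[0] == pytest.approx(1.0, abs=1e-9)
        assert res.partition_ratios[2] == pytest.approx(1.0, abs=1e-9)


class TestPixelDistances:
    def test_three_four_five(self):
        assert pixel_distances(np.array([[0.0, 0.0]]), (3.0, 4.0))[0] == 5.0

    def test_zero_at_source(self):
        assert pixel_distances(np.array([[7.0, 2.0]]), (7.0, 2.0))[0] == 0.0

    def test_matches_naive_formula(self, rng):
        coords = rng.uniform(0, 500, size=(1000, 2))
        source = (123.4, 456.7)
        d = pixel_distances(coords, source)
        naive = np.array(
            [((r - 123.4) ** 2 + (c - 456.7) ** 2) ** 0.5 for r, c in coords]
        )
        assert np.max(np.abs(d - naive)) < 1e-12


class TestLeadingEdgeBand:
    def test_half_annulus_width_twenty(self):
        periphery = Contour.from_vertices(circle_contour((120.0, 120.0), 50.0, n=720))
        line = separating_line(right_source_layout(center=(120.0, 120.0)))
        band = leading_edge_band(periphery, line, (240, 240), width=20)
        expected = np.pi * (50**2 - 30**2) / 2
        assert abs(band.count / expected - 1) < 0.03
        # all band pixels on the exposed (right) side
        assert (np.argwhere(band.pixels)[:, 1] > 120).all()

    def test_width_exceeding_radius_saturates_to_exposed_half(self):
        periphery = Contour.from_vertices(circle_contour((120.0, 120.0), 40.0, n=720))
        line = separating_line(right_source_layout(center=(120.0, 120.0)))
        band = leading_edge_band(periphery, line, (240, 240), width=100)
        half = np.pi * 40**2 / 2
        assert abs(band.count / half - 1) < 0.03

    def test_width_one_is_a_thin_rim(self):
        periphery = Contour.from_vertices(circle_contour((120.0, 120.0), 50.0, n=720))
        line = separating_line(right_source_layout(center=(120.0, 120.0)))
        band = leading_edge_band(periphery, line, (240, 240), width=1)
        # a 1-px rim over half the circumference
        assert 0 < band.count < np.pi * 50 * 3


class TestEdgeRegression:
    def _band_image(self, intensities_from_distance, shape=(200, 200),
                    source=(100.0, 400.0)):
        periphery = Contour.from_vertices(circle_contour((100.0, 100.0), 60.0, n=720))
        line = separating_line(
            right_source_layout(center=(100.0, 100.0), source_col_offset=300.0)
        )
        band = leading_edge_band(periphery, line, shape, width=20)
        coords = np.argwhere(band.pixels)
        d = pixel_distances(coords, source)
        px = np.full(shape, 0.1)
        px[band.pixels] = intensities_from_distance(d)
        return ColonyImage(px), band, source

    def test_exact_linear_data_recovers_slope_and_unit_r2(self):
        img, band, source = self._band_image(lambda d: 0.5 - 0.001 * d)
        fit = edge_regression(img, band, source)
        assert fit.slope == pytest.approx(-0.001, abs=1e-12)
        assert fit.intercept == pytest.approx(0.5, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_intensity_has_zero_slope_and_zero_r2(self):
        img, band, source = self._band_image(lambda d: np.full_like(d, 0.3))
        fit = edge_regression(img, band, source)
        assert fit.slope == 0.0 and fit.r_squared == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        noise = None

        def f(d):
            nonlocal noise
            noise = rng.normal(0, 0.02, size=d.shape)
            return np.clip(0.5 - 0.0008 * d + noise, 0, 1)

        img, band, source = self._band_image(f)
        fit = edge_regression(img, band, source)
        coords = np.argwhere(band.pixels)
        d = pixel_distances(coords, source)
        y = img.pixels[band.pixels]
        # normal equations, written out
        n = len(d)
        sx, sy, sxx, sxy = d.sum(), y.sum(), (d * d).sum(), (d * y).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        ss_res = float(((y - slope * d - intercept) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-9)

    def test_single_distance_is_rank_deficient(self):
        px = np.full((10, 10), 0.5)
        px[5, 5] = 0.6
        px[5, 6] = 0.4
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = mask[5, 6] = True
        # both pixels equidistant from a source centered between them
        with pytest.raises(DegenerateRegionError):
            edge_regression(ColonyImage(px), BinaryMask(mask), (0.0, 5.5))

    def test_positive_gradient_recovers_positive_slope(self):
        hits = 0
        for seed in range(20):
            spec = SyntheticSpec(
                group_label="1cm", distance_cm=1.0, r_exposed=70.0,
                gradient=5e-4, noise_sd=0.05, background_level=0.15, seed=seed,
            )
            image, layout, _ = generate_colony(spec)
            seg = segment_colony(image)
            line = separating_line(layout)
            band = leading_edge_band(seg.periphery, line, image.pixels.shape, 20)
            fit = edge_regression(image, band, layout.source_center)
            hits += fit.slope > 0
        assert hits >= 19
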