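"""Segmentation, shape measurement and variety aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endograin import morphometry as M


def make_micrograph(pixels, pixel_size=1.0, **kw):
    return M.Micrograph(np.asarray(pixels, dtype=float), pixel_size=pixel_size, **kw)


class TestMicrographValidation:
    def test_rejects_missing_calibration(self):
        with pytest.raises(ValueError, match="pixel_size"):
            make_micrograph(np.ones((4, 4)), pixel_size=0.0)

    def test_rejects_non_finite_intensities(self):
        img = np.ones((4, 4))
        img[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            make_micrograph(img)

    def test_rejects_empty_image(self):
        with pytest.raises(ValueError):
            make_micrograph(np.ones((0, 4)))


class TestSegmentation:
    def test_constant_image_signals_no_structure(self):
        with pytest.raises(M.NoStructureError):
            M.segment_micrograph(make_micrograph(np.full((64, 64), 0.7)))

    def test_uniform_bright_field_is_one_granule_no_pores(self):
        rng = np.random.default_rng(0)
        img = 0.75 + rng.normal(0, 0.02, (96, 96))
        labels = M.segment_micrograph(make_micrograph(img))
        assert labels.granule_labels.max() == 1
        assert not labels.pore_mask.any()
        assert labels.porosity() == 0.0

    def test_two_bright_squares_counted_by_pixels(self):
        img = np.zeros((100, 100))
        img[5:45, 5:45] = 1.0
        img[60:80, 60:80] = 1.0
        micro = make_micrograph(img)
        params = M.SegmentationParams(
            smooth_sigma_px=0, min_area_um2=1, min_void_area_um2=0.5, split_touching=False
        )
        labels = M.segment_micrograph(micro, params)
        shapes = M.measure_granules(labels, micro.pixel_size)
        assert sorted(s.area_um2 for s in shapes) == [400.0, 1600.0]

    def test_partition_is_conserved(self):
        from endograin.synthetic_data import MicrographParams, generate_micrograph

        micro, _ = generate_micrograph(
            MicrographParams(shape=(192, 192), n_granules=25, target_porosity_pct=4.0),
            seed=11,
        )
        labels = M.classify_voids(micro, M.segment_micrograph(micro))
        n = labels.granule_labels.size
        total = (
            (labels.granule_labels > 0).sum()
            + labels.pore_mask.sum()
            + labels.shadow_mask.sum()
            + labels.background_mask.sum()
        )
        assert total == n

    def test_small_regions_merged_into_surroundings(self):
        img = np.zeros((80, 80))
        img[10:70, 10:70] = 1.0
        img[40, 40] = 0.0  # 1-px void speck
        micro = make_micrograph(img)
        labels = M.segment_micrograph(
            micro, M.SegmentationParams(smooth_sigma_px=0, min_void_area_um2=4.0,
                                        split_touching=False)
        )
        assert not labels.pore_mask[40, 40]


class TestShapeDescriptors:
    def test_disc_is_round(self, labels_from_mask):
        yy, xx = np.mgrid[0:201, 0:201]
        disc = (yy - 100) ** 2 + (xx - 100) ** 2 <= 50**2
        s = M.measure_granules(labels_from_mask(disc), 0.02)[0]
        assert s.eccentricity < 0.10
        assert s.circularity > 0.90

    def test_ellipse_axis_ratio_two_gives_analytic_eccentricity(self, labels_from_mask):
        yy, xx = np.mgrid[0:201, 0:201]
        ell = ((xx - 100) / 80.0) ** 2 + ((yy - 100) / 40.0) ** 2 <= 1
        s = M.measure_granules(labels_from_mask(ell), 0.02)[0]
        assert s.eccentricity == pytest.approx(math.sqrt(1 - 0.25), abs=0.03)

    def test_square_has_isoperimetric_circularity(self, labels_from_mask):
        sq = np.zeros((200, 200), bool)
        sq[50:150, 50:150] = True
        s = M.measure_granules(labels_from_mask(sq), 0.02)[0]
        assert s.circularity == pytest.approx(math.pi / 4, abs=0.05)

    def test_scale_equivariance(self, labels_from_mask):
        yy, xx = np.mgrid[0:101, 0:101]
        disc = (yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2
        s1 = M.measure_granules(labels_from_mask(disc), 0.05)[0]
        s2 = M.measure_granules(labels_from_mask(disc), 0.10)[0]
        assert s2.area_um2 == pytest.approx(4 * s1.area_um2)
        assert s2.perimeter_um == pytest.approx(2 * s1.perimeter_um)
        assert s2.equivalent_diameter_um == pytest.approx(2 * s1.equivalent_diameter_um)
        assert s2.eccentricity == s1.eccentricity
        assert s2.circularity == s1.circularity

    def test_border_granules_flagged(self, labels_from_mask):
        mask = np.zeros((50, 50), bool)
        mask[0:10, 0:10] = True  # touches border
        mask[20:30, 20:30] = True  # interior
        shapes = M.measure_granules(labels_from_mask(mask), 1.0)
        assert sorted(s.touches_border for s in shapes) == [False, True]

    def test_zero_granules_gives_empty_list(self):
        z = np.zeros((10, 10), bool)
        labels = M.SegmentationLabels(z.astype(int), ~z, np.zeros_like(z), np.zeros_like(z))
        assert M.measure_granules(labels, 1.0) == []


class TestEquivalentDiameter:
    @pytest.mark.parametrize(
        "area,expected",
        [(43.02, 7.40), (123.20, 12.52), (26.69, 5.83), (89.17, 10.66), (math.pi, 2.00)],
    )
    def test_examples(self, area, expected):
        assert M.equivalent_diameter(area) == expected

    def test_rejects_non_positive_area(self):
        with pytest.raises(ValueError):
            M.equivalent_diameter(0.0)

    @given(st.floats(min_value=0.01, max_value=1e4))
    @settings(max_examples=50, derandomize=True)
    def test_inverts_circle_area_and_is_increasing(self, area):
        d = 2.0 * math.sqrt(area / math.pi)
        assert math.pi * (d / 2) ** 2 == pytest.approx(area, rel=1e-12)
        assert 2.0 * math.sqrt((area * 1.1) / math.pi) > d


class TestFieldSummary:
    def _labels(self, granule_px, pore_px, shadow_px, side=40):
        g = np.zeros((side, side), dtype=int)
        flat = g.ravel()
        flat[:granule_px] = 1
        pore = np.zeros(side * side, bool)
        pore[granule_px : granule_px + pore_px] = True
        shadow = np.zeros(side * side, bool)
        shadow[granule_px + pore_px : granule_px + pore_px + shadow_px] = True
        bg = ~(flat > 0) & ~pore & ~shadow
        return M.SegmentationLabels(
            flat.reshape(side, side), pore.reshape(side, side),
            shadow.reshape(side, side), bg.reshape(side, side),
        )

    def test_porosity_arithmetic(self):
        labels = self._labels(900, 50, 50)
        fs = M.field_summary([], labels)
        assert fs.porosity_pct == pytest.approx(5.0)

    def test_single_granule_sd_zero(self, labels_from_mask):
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        labels = labels_from_mask(mask)
        shapes = M.measure_granules(labels, 1.0)
        fs = M.field_summary(shapes, labels)
        assert fs.sd_area_um2 == 0.0

    def test_all_border_granules_flags_shapes_undefined(self, labels_from_mask):
        mask = np.zeros((30, 30), bool)
        mask[0:10, 0:10] = True
        labels = labels_from_mask(mask)
        fs = M.field_summary(M.measure_granules(labels, 1.0), labels)
        assert fs.shape_undefined
        assert np.isnan(fs.mean_area_um2)
        assert np.isfinite(fs.porosity_pct)

    def test_compact_field_reports_missing_shapes_but_valid_porosity(self):
        # one granule covering >95 % of the non-void area
        g = np.ones((50, 50), dtype=int)
        g[0, :10] = 0
        pore = g == 0
        labels = M.SegmentationLabels(g, pore, np.zeros_like(pore), np.zeros_like(pore))
        fs = M.field_summary(M.measure_granules(labels, 1.0), labels)
        assert fs.compact and fs.shape_undefined
        assert fs.porosity_pct == pytest.approx(100 * 10 / 2500)


class TestVarietyAggregation:
    def _field(self, porosity, area=10.0):
        return M.FieldMorphometry(
            porosity_pct=porosity, n_granules=5,
            mean_area_um2=area, sd_area_um2=1.0,
            mean_perimeter_um=10.0, sd_perimeter_um=1.0,
            mean_eccentricity=0.7, sd_eccentricity=0.01,
            mean_circularity=0.4, sd_circularity=0.01,
        )

    def test_zero_chalky_fraction_is_crystalline_mean(self):
        recs = [
            M.FieldRecord("g1", "crystalline", self._field(2.0)),
            M.FieldRecord("g2", "crystalline", self._field(4.0)),
        ]
        v = M.aggregate_variety("v", recs, chalky_fraction_pct=0.0)
        assert v.mean_porosity_pct == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "chalky_pct,por_chalky,por_cryst,expected",
        [(50.0, 6.0, 2.0, 4.0), (10.0, 6.0, 1.0, 1.5)],
    )
    def test_chalky_weighting(self, chalky_pct, por_chalky, por_cryst, expected):
        recs = [
            M.FieldRecord("g1", "chalky", self._field(por_chalky)),
            M.FieldRecord("g1", "crystalline", self._field(por_cryst)),
        ]
        v = M.aggregate_variety("v", recs, chalky_fraction_pct=chalky_pct)
        assert v.mean_porosity_pct == pytest.approx(expected)

    def test_region_weight_mismatch_rejected(self):
        recs = [M.FieldRecord("g1", "crystalline", self._field(2.0))]
        with pytest.raises(ValueError, match="mismatch"):
            M.aggregate_variety("v", recs, chalky_fraction_pct=20.0)

    def test_fields_average_within_grain_before_across_grains(self):
        recs = [
            M.FieldRecord("g1", "crystalline", self._field(1.0)),
            M.FieldRecord("g1", "crystalline", self._field(3.0)),
            M.FieldRecord("g2", "crystalline", self._field(6.0)),
        ]
        v = M.aggregate_variety("v", recs, 0.0)
        # grain means 2.0 and 6.0 -> variety 4.0 (not the pooled 10/3)
        assert v.mean_porosity_pct == pytest.approx(4.0)
        assert v.n_grains == 2 and v.n_fields == 3
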