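"""Phantom generator: geometry, compartment partition, parameter assignment,
congestion masks, cohorts and synthetic histology."""

import numpy as np
import pytest

import renalqmri as rq
from renalqmri.phantom import LABELS, _elliptical_radius


class TestGeometry:
    def test_nominal_pixel_size(self, cd0h_zero_sd_phantom):
        ph = cd0h_zero_sd_phantom
        assert ph.pixel_size == (100.0 / 256, 50.0 / 128)
        assert round(ph.pixel_size[0], 2) == 0.39 == round(ph.pixel_size[1], 2)

    def test_labels_partition_kidney(self, cd0h_zero_sd_phantom):
        label = cd0h_zero_sd_phantom.label_map
        kidney = label > 0
        n_labeled = sum(int((label == v).sum()) for v in LABELS.values())
        assert n_labeled == int(kidney.sum())

    def test_compartments_nested_by_radius(self, cd0h_zero_sd_phantom):
        """IM is innermost, CTX outermost: max radius of inner band stays
        below min radius of the next band out."""
        label = cd0h_zero_sd_phantom.label_map
        r = _elliptical_radius(label.shape)
        order = ["IM", "IS", "OS", "CTX"]
        for inner, outer in zip(order, order[1:]):
            assert r[label == LABELS[inner]].max() < r[label == LABELS[outer]].min() + 1e-12

    def test_band_area_fractions(self, label_map):
        kidney = (label_map > 0).sum()
        fracs = {c: (label_map == LABELS[c]).sum() / kidney for c in rq.COMPARTMENTS}
        for comp, expected in (("CTX", 0.40), ("OS", 0.15), ("IS", 0.15), ("IM", 0.30)):
            assert fracs[comp] == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize(
        "grid,fov", [((16, 16), (10, 10)), ((64, 32), (0.0, 50.0)), ((64, 32), (-1, 50))]
    )
    def test_bad_grid_or_fov_rejected(self, grid, fov):
        with pytest.raises(ValueError):
            rq.make_kidney_phantom(grid=grid, fov_mm=fov)


class TestParameterAssignment:
    def test_zero_sd_maps_equal_preset_means(self, cd0h_zero_sd_phantom):
        preset = rq.table_preset("CD0h")
        for comp in rq.COMPARTMENTS:
            region = cd0h_zero_sd_phantom.label_map == LABELS[comp]
            assert np.all(cd0h_zero_sd_phantom.t2star_map[region] == preset.t2star[comp].mean)
            assert np.all(cd0h_zero_sd_phantom.adc_map[region] == preset.adc[comp].mean)

    def test_zero_severity_gives_empty_rcc_mask(self, small_grid):
        preset = rq.ConditionPreset(
            condition="CD0h", perfusion="none",
            t2star={c: rq.GaussianParam(100, 0) for c in rq.COMPARTMENTS},
            adc={c: rq.GaussianParam(0.7, 0) for c in rq.COMPARTMENTS},
        )
        ph = rq.make_kidney_phantom(grid=small_grid, fov_mm=(25, 12.5), preset=preset)
        assert not ph.rcc_mask.any()

    def test_rcc_fraction_matches_severity(self):
        """Realized congested fraction within 0.01 of request for compartments
        with >= 1000 pixels."""
        preset = rq.table_preset("CD2h").with_zero_sd()
        ph = rq.make_kidney_phantom(preset=preset, seed=3)
        for comp, sev in preset.rcc_severity.items():
            region = ph.label_map == LABELS[comp]
            if region.sum() >= 1000:
                frac = (ph.rcc_mask & region).sum() / region.sum()
                assert abs(frac - sev) <= 0.01

    def test_rcc_reduces_t2star_when_factor_below_one(self, small_grid):
        preset = rq.ConditionPreset(
            condition="CD1h", perfusion="none",
            t2star={c: rq.GaussianParam(100, 0) for c in rq.COMPARTMENTS},
            adc={c: rq.GaussianParam(0.7, 0) for c in rq.COMPARTMENTS},
            rcc_severity={"CTX": 0, "OS": 0, "IS": 0.3, "IM": 0},
            rcc_t2star_factor=0.35,
        )
        ph = rq.make_kidney_phantom(grid=small_grid, fov_mm=(25, 12.5), preset=preset, seed=1)
        assert ph.rcc_mask.any()
        assert np.allclose(ph.t2star_map[ph.rcc_mask], 35.0)
        ph.validate()


class TestCohort:
    def test_zero_variance_cohort_identical(self, small_grid):
        preset = rq.table_preset("CD0h").with_zero_sd()
        cohort = rq.make_cohort([(preset, 3)], seed=5, grid=small_grid, fov_mm=(25, 12.5))
        assert len(cohort) == 3
        for ph in cohort[1:]:
            np.testing.assert_array_equal(ph.t2star_map, cohort[0].t2star_map)
            np.testing.assert_array_equal(ph.adc_map, cohort[0].adc_map)

    def test_same_seed_bitwise_identical(self, small_grid):
        design = [(rq.table_preset("CD1h"), 2), (rq.table_preset("CD2h"), 2)]
        a = rq.make_cohort(design, seed=11, grid=small_grid, fov_mm=(25, 12.5))
        b = rq.make_cohort(design, seed=11, grid=small_grid, fov_mm=(25, 12.5))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.t2star_map, pb.t2star_map)
            np.testing.assert_array_equal(pa.rcc_mask, pb.rcc_mask)

    def test_sampled_ctx_adc_spread_matches_preset_sd(self, small_grid):
        """Empirical SD of the per-kidney CTX ADC over 200 cohorts of 3
        approaches the preset SD (0.043)."""
        preset = rq.table_preset("CD0h")
        vals = []
        for rep in range(200):
            for ph in rq.make_cohort([(preset, 3)], seed=rep, grid=small_grid, fov_mm=(25, 12.5)):
                vals.append(ph.compartment_values["CTX"]["adc_e3mm2s"])
        sd = np.std(vals, ddof=1)
        # MC error on an SD estimate from 600 draws is ~ sd/sqrt(2*599) ~ 0.0012
        assert sd == pytest.approx(0.043, abs=0.005)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            rq.make_cohort([], seed=0)
        with pytest.raises(ValueError):
            rq.make_cohort([(rq.table_preset("CD0h"), 0)], seed=0)


class TestHistologySample:
    def test_zero_fractions_give_empty_truth(self, label_map):
        h = rq.make_histology_sample(label_map, {c: 0.0 for c in rq.COMPARTMENTS}, seed=0)
        assert not h.rcc_truth.any()

    def test_half_is_congested(self, label_map):
        h = rq.make_histology_sample(label_map, {"IS": 0.5}, seed=1)
        is_region = label_map == LABELS["IS"]
        frac = (h.rcc_truth & is_region).sum() / is_region.sum()
        assert frac == pytest.approx(0.50, abs=0.01)
        assert not (h.rcc_truth & ~is_region).any()

    def test_congested_pixels_redder_than_tissue(self, label_map):
        h = rq.make_histology_sample(label_map, {"IS": 0.3, "OS": 0.05}, seed=2)
        tissue = (label_map > 0) & ~h.rcc_truth
        red = h.rgb_image[..., 0].astype(float)
        assert red[h.rcc_truth].mean() > red[tissue].mean()
        from renalqmri.histology import redness_score

        score = redness_score(h.rgb_image)
        assert score[h.rcc_truth].mean() > score[tissue].mean()

    def test_fraction_out_of_range_rejected(self, label_map):
        with pytest.raises(ValueError):
            rq.make_histology_sample(label_map, {"IS": 1.5}, seed=0)
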