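"""k-sigma granule detection, per-granule measurement, population summaries."""

import numpy as np
import pytest

from nanoxrf.granules import (
    SIZE_SPLIT_UM2,
    GranuleRecord,
    colocalize,
    detect_granules,
    measure_granules,
    records_table,
    summarize,
)
from nanoxrf.maps import ElementMap
from nanoxrf.phantom import generate_phantom, neuron_phantom_spec
from nanoxrf.quantify import CalibrationStandard


def emap(arr, element="Fe", px=50.0):
    return ElementMap(element, np.asarray(arr, float), px)


class TestDetect:
    def test_block_example_threshold_and_single_granule(self):
        """A 3x3 block at 500 on a flat 100-count cytoplasm: the
        threshold (block included in the statistics) is ~124.35 and
        exactly one 9-pixel granule is found."""
        fe = np.full((100, 100), 100.0)
        fe[50:53, 50:53] = 500.0
        s = np.full((100, 100), 100.0)
        labels, thr = detect_granules(emap(fe), emap(s, "S"), np.ones((100, 100), bool))
        # brute-force oracle for mean + 2 SD with the block included
        n = 10000
        mean = (9991 * 100 + 9 * 500) / n
        sd = np.sqrt((9991 * (100 - mean) ** 2 + 9 * (500 - mean) ** 2) / n)
        assert thr["Fe"] == pytest.approx(mean + 2 * sd, rel=1e-12)
        assert thr["Fe"] == pytest.approx(124.35, abs=0.01)
        assert labels.max() == 1
        assert (labels == 1).sum() == 9

    def test_single_pixel_exceedances_rejected(self):
        fe = np.full((50, 50), 100.0)
        fe[10, 10] = 1000.0  # singleton
        fe[30, 30:32] = 1000.0  # pair
        s = np.full((50, 50), 100.0)
        labels, _ = detect_granules(emap(fe), emap(s, "S"), np.ones((50, 50), bool))
        assert labels.max() == 1
        assert (labels > 0).sum() == 2

    def test_detection_confined_to_cytoplasm(self):
        fe = np.full((40, 40), 10.0)
        fe[0:3, 0:3] = 500.0  # outside the mask
        fe[20:23, 20:23] = 500.0
        s = np.full((40, 40), 10.0)
        cyto = np.zeros((40, 40), bool)
        cyto[10:35, 10:35] = True
        labels, _ = detect_granules(emap(fe), emap(s, "S"), cyto)
        assert labels.max() == 1
        assert (labels[~cyto] == 0).all()

    def test_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(4)
        fe = rng.poisson(100, (60, 60)).astype(float)
        fe[20:24, 20:24] = 600.0
        s = rng.poisson(80, (60, 60)).astype(float)
        cyto = np.ones((60, 60), bool)
        l1, _ = detect_granules(emap(fe), emap(s, "S"), cyto)
        l2, _ = detect_granules(emap(fe * 7.5), emap(s * 7.5, "S"), cyto)
        np.testing.assert_array_equal(l1, l2)

    def test_bad_inputs_rejected(self):
        fe, s = emap(np.ones((5, 5))), emap(np.ones((5, 5)), "S")
        with pytest.raises(ValueError, match="empty cytoplasm"):
            detect_granules(fe, s, np.zeros((5, 5), bool))
        with pytest.raises(ValueError, match="k must be positive"):
            detect_granules(fe, s, np.ones((5, 5), bool), k=0)

    def test_s_only_enrichment_also_detected(self):
        fe = np.full((50, 50), 100.0)
        s = np.full((50, 50), 100.0)
        s[5:8, 5:8] = 900.0
        labels, _ = detect_granules(emap(fe), emap(s, "S"), np.ones((50, 50), bool))
        assert labels.max() == 1

    def test_conservation_of_counts(self):
        """Granule-summed plus background-summed counts equal the
        cytoplasm total exactly on integer maps."""
        rng = np.random.default_rng(9)
        fe = rng.poisson(50, (80, 80)).astype(float)
        fe[10:14, 10:14] = 400
        s = rng.poisson(50, (80, 80)).astype(float)
        cyto = np.zeros((80, 80), bool)
        cyto[5:75, 5:75] = True
        labels, _ = detect_granules(emap(fe), emap(s, "S"), cyto)
        granule_sum = fe[(labels > 0)].sum()
        background_sum = fe[cyto & (labels == 0)].sum()
        assert granule_sum + background_sum == fe[cyto].sum()


class TestMeasure:
    def setup_scene(self):
        fe = np.full((60, 60), 100.0)
        s = np.full((60, 60), 100.0)
        si = np.full((60, 60), 1000.0)
        # granule A: disk of radius 4 with a broad S-rich core and a thin
        # Fe-rich rim (the core occupies most of the footprint, the Fe
        # enhancement only its outer shell)
        rr, cc = np.meshgrid(np.arange(60), np.arange(60), indexing="ij")
        dist = np.sqrt((rr - 15.0) ** 2 + (cc - 15.0) ** 2)
        s[dist <= 3.2] = 500.0
        fe[(dist > 2.8) & (dist <= 4.2)] = 600.0
        # granule B: uniform Fe blob
        fe[40:43, 40:43] = 500.0
        cyto = np.ones((60, 60), bool)
        maps = {"Fe": emap(fe), "S": emap(s, "S"), "Si": emap(si, "Si")}
        labels, _ = detect_granules(maps["Fe"], maps["S"], cyto)
        return maps, labels, cyto

    def test_area_from_pixel_pitch(self):
        maps, labels, cyto = self.setup_scene()
        records = measure_granules(labels, maps, 50.0, cyto)
        assert len(records) == 2
        blob = max(records, key=lambda r: r.centroid[0])  # 3x3 granule B
        assert blob.area_um2 == pytest.approx(9 * 0.05**2)  # 0.0225 um^2
        assert blob.size_class == "small"
        for r in records:
            assert r.area_um2 == pytest.approx(r.n_pixels * 0.05**2)

    def test_rim_core_morphology_has_higher_fe_heterogeneity(self):
        maps, labels, cyto = self.setup_scene()
        records = measure_granules(labels, maps, 50.0, cyto)
        rim = min(records, key=lambda r: r.centroid[0])  # granule A
        assert rim.rsd["Fe"] > rim.rsd["S"]

    def test_over_background_ratios(self):
        maps, labels, cyto = self.setup_scene()
        records = measure_granules(labels, maps, 50.0, cyto)
        blob = max(records, key=lambda r: r.centroid[0])  # granule B
        assert blob.over_background["Fe"] == pytest.approx(5.0, rel=0.01)
        assert blob.over_background["S"] == pytest.approx(1.0, rel=0.01)

    def test_mass_ratio_uses_calibration_when_available(self):
        maps, labels, cyto = self.setup_scene()
        std = CalibrationStandard(98.1, 12.8, 5200, 41000, 2e-5, 2e-5)
        records = measure_granules(labels, maps, 50.0, cyto, standard=std)
        for r in records:
            assert r.am["Fe"] > 0
            count_ratio = r.counts["Fe"] / r.counts["S"]
            f_ratio = std.constants.f("S") / std.constants.f("Fe")
            assert r.fe_s_ratio == pytest.approx(count_ratio * f_ratio, rel=1e-9)

    def test_zero_s_granule_retained_with_undefined_ratio(self):
        fe = np.full((30, 30), 10.0)
        fe[5:8, 5:8] = 500.0
        s = np.zeros((30, 30))
        maps = {"Fe": emap(fe), "S": emap(s, "S")}
        labels, _ = detect_granules(maps["Fe"], maps["S"], np.ones((30, 30), bool))
        records = measure_granules(labels, maps, 50.0, np.ones((30, 30), bool))
        assert len(records) == 1
        assert records[0].fe_s_ratio is None


class TestSummarize:
    def make_record(self, area, fe_over=2.0, s_over=2.0, ratio=1.0, cond="ctrl"):
        return GranuleRecord(
            label=1, area_um2=area, n_pixels=int(area / 0.0025), centroid=(0, 0),
            counts={"Fe": 10, "S": 10}, am={}, fe_s_ratio=ratio,
            over_background={"Fe": fe_over, "S": s_over},
            rsd={"Fe": 0.1, "S": 0.1}, condition=cond,
        )

    def test_mean_area_and_size_split(self):
        records = [self.make_record(a) for a in (0.02, 0.04, 0.09)]
        s = summarize(records, "ctrl")
        assert s.n == 3
        assert s.mean_area_um2 == pytest.approx(0.05)
        assert s.n_small == 2 and s.n_large == 1

    def test_empty_condition_is_n_zero(self):
        s = summarize([], "asyn")
        assert s.n == 0 and s.mean_area_um2 is None

    def test_boundary_area_counts_as_large(self):
        s = summarize([self.make_record(SIZE_SPLIT_UM2)] * 3, "ctrl")
        assert s.n_large == 3

    def test_condition_presets_reproduce_fe_shift_ordering(self):
        """The alpha-synuclein-like phantom preset must yield granules
        with a higher mean Fe/S mass ratio and higher across-granule Fe
        variability than the control-like preset."""
        summaries = {}
        for cond in ("ctrl", "asyn"):
            spec = neuron_phantom_spec(cond, grid_shape=(160, 160), seed=17)
            maps, truth = generate_phantom(spec)
            cyto = truth.mask("cytoplasm") | (truth.granule_labels > 0)
            labels, _ = detect_granules(maps["Fe"], maps["S"], cyto)
            records = measure_granules(labels, maps, 50.0, cyto, condition=cond)
            summaries[cond] = summarize(records, cond)
        assert summaries["asyn"].mean_fe_s_ratio > summaries["ctrl"].mean_fe_s_ratio
        assert summaries["asyn"].rsd_fe > summaries["ctrl"].rsd_fe
        assert summaries["asyn"].n > 0 and summaries["ctrl"].n > 0


def test_records_table_columns():
    fe = np.full((30, 30), 10.0)
    fe[5:8, 5:8] = 500.0
    s = np.full((30, 30), 10.0)
    maps = {"Fe": emap(fe), "S": emap(s, "S")}
    labels, _ = detect_granules(maps["Fe"], maps["S"], np.ones((30, 30), bool))
    df = records_table(measure_granules(labels, maps, 50.0, np.ones((30, 30), bool)))
    assert {"area_um2", "FeS_ratio", "Fe_over_bgd", "size_class"} <= set(df.columns)
    assert len(df) == 1


def test_colocalization_fractions_bounded():
    labels = np.zeros((20, 20), int)
    labels[2:5, 2:5] = 1
    labels[10:13, 10:13] = 2
    tem = np.zeros((20, 20), bool)
    tem[2:5, 2:4] = True  # partial overlap with granule 1 only
    df = colocalize(labels, tem)
    assert ((df.overlap_fraction >= 0) & (df.overlap_fraction <= 1)).all()
    assert not df.matched.iloc[1]
    assert df.overlap_fraction.iloc[0] == pytest.approx(6 / 9)
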