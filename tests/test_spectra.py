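"""Sum-spectrum extraction and the Gaussian K-line fitter."""

import numpy as np
import pytest

from nanoxrf.phantom import generate_phantom, render_spectra
from nanoxrf.spectra import (
    DetectorModel,
    Spectrum,
    SpectrumStack,
    _design_matrix,
    fit_spectrum,
    per_pixel_maps,
    sum_spectrum,
)

from conftest import flat_spec


def make_spectrum(areas, elements, detector, background=0.0, seed=0, n_channels=1024):
    """Poisson spectrum with known per-element K-line areas."""
    energies = 0.012 * np.arange(n_channels)
    profiles = _design_matrix(energies, elements, detector, 0.012)
    expected = profiles @ np.asarray(areas, dtype=float) + background
    counts = np.random.default_rng(seed).poisson(expected)
    return Spectrum(counts, 0.0, 0.012)


class TestSumSpectrum:
    def test_single_pixel_mask_is_identity(self, detector):
        maps, _ = generate_phantom(flat_spec({"Fe": 50.0}, shape=(6, 6), seed=1))
        stack = render_spectra(maps, detector, seed=1, n_channels=256)
        mask = np.zeros((6, 6), bool)
        mask[2, 3] = True
        spec = sum_spectrum(stack, mask)
        np.testing.assert_array_equal(spec.counts, stack.counts[2, 3])
        assert spec.n_pixels == 1

    def test_additive_over_disjoint_masks(self, detector):
        maps, _ = generate_phantom(flat_spec({"Fe": 50.0}, shape=(6, 6), seed=2))
        stack = render_spectra(maps, detector, seed=2, n_channels=256)
        m1 = np.zeros((6, 6), bool)
        m2 = np.zeros((6, 6), bool)
        m1[:3] = True
        m2[3:] = True
        union = sum_spectrum(stack, m1 | m2)
        np.testing.assert_array_equal(
            union.counts, sum_spectrum(stack, m1).counts + sum_spectrum(stack, m2).counts
        )
        assert union.n_pixels == 36

    def test_empty_mask_raises(self, detector):
        maps, _ = generate_phantom(flat_spec({"Fe": 5.0}, shape=(4, 4)))
        stack = render_spectra(maps, detector, seed=0, n_channels=128)
        with pytest.raises(ValueError, match="zero pixels"):
            sum_spectrum(stack, np.zeros((4, 4), bool))

    def test_mask_sum_matches_phantom_truth(self, detector):
        maps, truth = generate_phantom(flat_spec({"Fe": 80.0}, shape=(32, 32), seed=3))
        stack = render_spectra(maps, detector, seed=3, n_channels=1024)
        region = truth.mask("cytoplasm")
        spec = sum_spectrum(stack, region)
        expected = 80.0 * region.sum()
        assert abs(spec.counts.sum() - expected) < 5 * np.sqrt(expected)


class TestFitSpectrum:
    @pytest.mark.parametrize("element,area", [("Fe", 5e4), ("Zn", 2e4), ("Ca", 1e4)])
    def test_single_element_recovered_within_3_sigma(self, detector, element, area):
        spec = make_spectrum([area], [element], detector, background=10.0, seed=42)
        fit = fit_spectrum(spec, [element], detector)
        assert abs(fit.s(element) - area) < 3 * fit.sigma_s(element)

    def test_overlapping_p_s_ca_triple_separated(self, detector):
        """P, S and Ca K-lines overlap at SDD resolution; the joint fit
        must still recover each area within 3 sigma."""
        spec = make_spectrum([1e4, 1e4, 1e4], ["P", "S", "Ca"], detector, 5.0, seed=7)
        fit = fit_spectrum(spec, ["P", "S", "Ca"], detector)
        for el in ("P", "S", "Ca"):
            assert abs(fit.s(el) - 1e4) < 3 * fit.sigma_s(el)

    def test_pure_background_is_consistent_with_zero(self, detector):
        counts = np.random.default_rng(3).poisson(20.0, size=1024)
        fit = fit_spectrum(Spectrum(counts, 0.0, 0.012), ["Fe"], detector)
        assert fit.s("Fe") <= 3 * fit.sigma_s("Fe")

    def test_snip_background_variant_also_recovers(self):
        det = DetectorModel(background="snip")
        spec = make_spectrum([5e4], ["Fe"], det, background=30.0, seed=8)
        fit = fit_spectrum(spec, ["Fe"], det)
        assert abs(fit.s("Fe") - 5e4) < 4 * fit.sigma_s("Fe")

    def test_coincident_lines_rejected_by_name(self):
        det = DetectorModel()
        det.lines["Xq"] = (6.41, 7.06, 0.13)  # indistinguishable from Fe
        spec = make_spectrum([1e4], ["Fe"], det, 5.0)
        with pytest.raises(ValueError, match="Fe.*Xq|Xq.*Fe"):
            fit_spectrum(spec, ["Fe", "Xq"], det)

    def test_empty_inputs_rejected(self, detector):
        spec = make_spectrum([1e3], ["Fe"], detector, seed=1)
        with pytest.raises(ValueError):
            fit_spectrum(spec, [], detector)
        with pytest.raises(ValueError, match="zero total"):
            fit_spectrum(Spectrum(np.zeros(128), 0.0, 0.012), ["Fe"], detector)

    def test_amplitude_solve_is_linear_in_pixel_count(self, detector):
        """Fitting the noiseless sum of N identical spectra returns N
        times the single-spectrum amplitudes."""
        energies = 0.012 * np.arange(1024)
        profile = _design_matrix(energies, ["Fe"], detector, 0.012)[:, 0]
        one = np.rint(1e4 * profile + 5)
        fit1 = fit_spectrum(Spectrum(one, 0.0, 0.012), ["Fe"], detector)
        fitN = fit_spectrum(Spectrum(8 * one, 0.0, 0.012, n_pixels=8), ["Fe"], detector)
        assert fitN.s("Fe") == pytest.approx(8 * fit1.s("Fe"), rel=0.02)

    def test_sum_then_fit_matches_fit_then_sum_on_noiseless_data(self, detector):
        """The headline SNR strategy: for a linear amplitude model the
        mask-sum fit equals the sum of per-pixel fits (noiseless)."""
        energies = 0.012 * np.arange(1024)
        profiles = _design_matrix(energies, ["Fe", "Ca"], detector, 0.012)
        px_areas = [(500.0, 200.0), (800.0, 100.0), (300.0, 400.0)]
        pixel_specs = [
            np.rint(profiles @ np.array(a) * 10) / 10 for a in px_areas
        ]
        per_pixel = [
            fit_spectrum(Spectrum(np.rint(s), 0.0, 0.012), ["Fe", "Ca"], detector)
            for s in pixel_specs
        ]
        summed = fit_spectrum(
            Spectrum(np.rint(sum(pixel_specs)), 0.0, 0.012, n_pixels=3),
            ["Fe", "Ca"],
            detector,
        )
        for el in ("Fe", "Ca"):
            assert summed.s(el) == pytest.approx(
                sum(f.s(el) for f in per_pixel), rel=0.05
            )

    def test_relative_sigma_shrinks_as_sqrt_n_pixels(self, detector):
        """sigma_S/S of a mask-sum fit improves ~1/sqrt(n) at a fixed
        per-pixel rate."""
        rel = {}
        for n in (64, 1024):
            maps, _ = generate_phantom(
                flat_spec({"Fe": 50.0}, shape=(32, 32), seed=5)
            )
            mask = np.zeros((32, 32), bool)
            mask.ravel()[:n] = True
            stack = render_spectra(maps, detector, seed=5, n_channels=1024)
            fit = fit_spectrum(sum_spectrum(stack, mask), ["Fe"], detector)
            rel[n] = fit.sigma_s("Fe") / fit.s("Fe")
        assert rel[1024] < rel[64]
        assert rel[64] / rel[1024] == pytest.approx(4.0, rel=0.35)


class TestPerPixelMaps:
    def test_uniform_rate_recovered_in_map_mean(self, detector):
        maps_in, _ = generate_phantom(flat_spec({"Fe": 50.0}, shape=(12, 12), seed=6))
        stack = render_spectra(maps_in, detector, seed=6, n_channels=1024)
        maps = per_pixel_maps(stack, ["Fe"], detector)
        vals = maps["Fe"].counts
        assert np.isfinite(vals).all()
        se = np.sqrt(50.0 / vals.size)  # Poisson SE of the mean rate
        assert abs(np.nanmean(vals) - 50.0) < 5 * se

    def test_all_zero_stack_gives_zero_maps(self, detector):
        stack = SpectrumStack(np.zeros((4, 4, 128), np.uint32), 0.0, 0.012)
        maps = per_pixel_maps(stack, ["Fe", "S"], detector)
        assert not np.nan_to_num(maps["Fe"].counts).any()
        assert not np.nan_to_num(maps["S"].counts).any()
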