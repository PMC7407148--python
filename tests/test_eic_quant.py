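import numpy as np
import pytest

from lipiddose.eic_quant import (
    PeakArea,
    QuantError,
    SampleMeta,
    Scan,
    area_ratio,
    blank_correct,
    extract_eic,
    integrate_peak,
    read_scans_mzml,
    read_scans_tsv,
    to_concentration,
    validate_scan_series,
    write_scans_tsv,
)
from lipiddose.mz_targets import MzTarget
from lipiddose.synthetic_data import PeakSpec, simulate_scans, write_scans_mzml


def gaussian_trace(apex=2.0, sigma=0.05, amplitude=1e5, dt=0.25 / 60, length=4.0):
    t = np.arange(0.0, length, dt)
    return t, amplitude * np.exp(-0.5 * ((t - apex) / sigma) ** 2)


class TestExtractEic:
    def test_single_product_exact_match(self):
        scans = [Scan(0.5, "+ve", [400.0, 500.0], [10.0, 99.0])]
        target = MzTarget("a", ((500.0, "+ve"),), expected_rt=0.5)
        times, trace = extract_eic(scans, target)
        assert times.tolist() == [0.5]
        assert trace.tolist() == [99.0]

    def test_product_outside_tolerance_gives_zero(self):
        scans = [Scan(0.5, "+ve", [500.1], [99.0])]
        target = MzTarget("a", ((500.0, "+ve"),), expected_rt=0.5)
        _, trace = extract_eic(scans, target, tol_ppm=10.0)
        assert trace.tolist() == [0.0]

    def test_polarity_filtering(self):
        scans = [Scan(0.5, "-ve", [500.0], [99.0]), Scan(0.6, "+ve", [500.0], [42.0])]
        target = MzTarget("a", ((500.0, "+ve"),), expected_rt=0.5)
        times, trace = extract_eic(scans, target)
        assert times.tolist() == [0.6]
        assert trace.tolist() == [42.0]

    def test_coeluting_adducts_sum(self):
        """Two product channels of one analyte add up in the EIC."""
        peak = PeakSpec("a", amount=2.0, apex_rt=1.0, sigma=0.05,
                        products=((500.0, "+ve"), (522.0, "+ve")))
        scans = simulate_scans([peak], run_length=2.0, scan_interval_s=1.0)
        target_both = MzTarget("a", ((500.0, "+ve"), (522.0, "+ve")), expected_rt=1.0)
        target_one = MzTarget("a", ((500.0, "+ve"),), expected_rt=1.0)
        _, both = extract_eic(scans, target_both)
        _, one = extract_eic(scans, target_one)
        assert np.allclose(both, 2 * one)


class TestIntegratePeak:
    def test_gaussian_area_within_two_percent(self):
        sigma, amplitude = 0.05, 1e5
        t, y = gaussian_trace(apex=2.0, sigma=sigma, amplitude=amplitude)
        peak = integrate_peak(t, y, expected_rt=2.0)
        exact = amplitude * sigma * np.sqrt(2 * np.pi)
        assert peak.found
        assert peak.area == pytest.approx(exact, rel=0.02)

    def test_rt_drift_beyond_tolerance_not_found(self):
        t, y = gaussian_trace(apex=2.15)
        peak = integrate_peak(t, y, expected_rt=2.0, rt_tolerance=0.1)
        assert not peak.found
        assert peak.area == 0.0

    def test_drift_within_tolerance_found(self):
        t, y = gaussian_trace(apex=2.08)
        peak = integrate_peak(t, y, expected_rt=2.0, rt_tolerance=0.1)
        assert peak.found

    def test_flat_zero_trace_not_found(self):
        t = np.linspace(0, 4, 100)
        peak = integrate_peak(t, np.zeros_like(t), expected_rt=2.0)
        assert not peak.found

    def test_linearity_in_amplitude(self):
        """Doubling the peak amplitude doubles the area to 1e-9 relative error."""
        t, y = gaussian_trace()
        a1 = integrate_peak(t, y, expected_rt=2.0).area
        a2 = integrate_peak(t, 2 * y, expected_rt=2.0).area
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_window_must_cover_tolerance(self):
        t, y = gaussian_trace()
        with pytest.raises(ValueError):
            integrate_peak(t, y, expected_rt=2.0, rt_tolerance=0.2, window=0.1)


class TestRatiosAndConcentration:
    def test_area_ratio(self):
        analyte = PeakArea("a", 10.0, 1.0, True)
        standard = PeakArea("is", 20.0, 1.0, True)
        assert area_ratio(analyte, standard) == 0.5

    def test_not_found_analyte_is_zero(self):
        standard = PeakArea("is", 20.0, 1.0, True)
        assert area_ratio(PeakArea("a", 0.0, None, False), standard) == 0.0

    def test_missing_standard_raises(self):
        with pytest.raises(QuantError):
            area_ratio(PeakArea("a", 1.0, 1.0, True), PeakArea("is", 0.0, None, False))

    def test_fluid_and_tissue_concentration(self):
        fluid = SampleMeta("s1", "sample", fluid_volume=20.0)
        tissue = SampleMeta("s2", "sample", tissue_mass=10.0)
        assert to_concentration(1.0, 5.0, fluid) == 5.0
        assert to_concentration(1.0, 5.0, tissue) == 0.5
        assert to_concentration(0.0, 5.0, tissue) == 0.0

    def test_sample_meta_requires_one_amount(self):
        with pytest.raises(ValueError):
            SampleMeta("s", "sample")
        with pytest.raises(ValueError):
            SampleMeta("s", "sample", tissue_mass=1.0, fluid_volume=1.0)


class TestBlankCorrection:
    def test_threshold_rule(self):
        corrected, censored = blank_correct([2.9, 3.1], [1.0, 1.0])
        assert corrected.tolist() == [0.0, 3.1]
        assert censored.tolist() == [True, False]

    def test_all_zero_blanks_keep_values(self):
        corrected, censored = blank_correct([0.5, 2.0], [0.0, 0.0])
        assert corrected.tolist() == [0.5, 2.0]
        assert not censored.any()

    def test_no_blanks_warns_and_skips(self):
        with pytest.warns(UserWarning, match="skipped"):
            corrected, censored = blank_correct([1.0, 2.0], [])
        assert corrected.tolist() == [1.0, 2.0]
        assert not censored.any()

    def test_idempotent(self):
        values = np.array([0.5, 2.9, 3.1, 10.0])
        blanks = [1.0]
        once, _ = blank_correct(values, blanks)
        twice, _ = blank_correct(once, blanks)
        assert np.array_equal(once, twice)

    @pytest.mark.parametrize("low, high", [(0.5, 1.0), (1.0, 2.0), (0.1, 5.0)])
    def test_censoring_monotone_in_blank_level(self, low, high):
        """Raising the blank level never un-censors a value."""
        values = np.linspace(0.0, 20.0, 50)
        _, cens_low = blank_correct(values, [low])
        _, cens_high = blank_correct(values, [high])
        assert np.all(cens_low <= cens_high)


class TestScanIO:
    def test_tsv_round_trip(self, tmp_path):
        peak = PeakSpec("a", 1.0, 0.5, 0.05, ((500.0, "+ve"),))
        scans = simulate_scans([peak], run_length=1.0, scan_interval_s=2.0,
                               noise_floor=5.0, seed=1)
        path = tmp_path / "run.tsv"
        write_scans_tsv(scans, path)
        back = read_scans_tsv(path)
        assert len(back) == len(scans)
        for a, b in zip(scans, back):
            assert a.time == b.time and a.polarity == b.polarity
            assert np.allclose(a.intensity, b.intensity)

    def test_mzml_round_trip(self, tmp_path):
        peaks = [
            PeakSpec("a", 1.0, 0.5, 0.05, ((500.0, "+ve"),)),
            PeakSpec("b", 1.0, 0.5, 0.05, ((600.0, "-ve"),)),
        ]
        scans = simulate_scans(peaks, run_length=1.0, scan_interval_s=2.0,
                               noise_floor=3.0, seed=2)
        path = tmp_path / "run.mzML"
        write_scans_mzml(scans, path)
        back = read_scans_mzml(path)
        assert len(back) == len(scans)
        for a, b in zip(scans, back):
            assert b.time == pytest.approx(a.time, abs=1e-9)
            assert a.polarity == b.polarity
            assert np.allclose(a.mz, b.mz)
            assert np.allclose(a.intensity, b.intensity)

    def test_validate_scan_series(self):
        good = [Scan(0.1, "+ve", [500.0], [1.0]), Scan(0.2, "+ve", [500.0], [1.0])]
        validate_scan_series(good)
        with pytest.raises(ValueError, match="increasing"):
            validate_scan_series(list(reversed(good)))
        with pytest.raises(ValueError, match="m/z"):
            validate_scan_series([Scan(0.1, "+ve", [50.0], [1.0])])
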