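"""Ground-truth structure and noise statistics of the study generator."""

import math

import numpy as np
import pandas as pd
import pytest

from chiralquant.peaks import PEAK_TABLE_COLUMNS
from chiralquant.simulate import (AnalyteSpec, MatrixSpec, StudyDesign,
                                  CALIBRANT_ISTD_CONCENTRATION,
                                  DEFAULT_CALIBRATION_LEVELS,
                                  DEFAULT_SPIKE_LEVELS,
                                  emit_peak_table,
                                  generate_calibration_series,
                                  generate_spiked_matrix_set,
                                  ground_truth_frame, render_chromatogram)


class TestAnalyteSpec:
    def test_chiral_needs_two_increasing_retention_times(self):
        with pytest.raises(ValueError):
            AnalyteSpec("x", (2.0, 1.5), is_chiral=True)
        with pytest.raises(ValueError):
            AnalyteSpec("x", (2.0,), is_chiral=True)

    @pytest.mark.parametrize("field,value", [
        ("peak_sigma", 0.0), ("response_factor", -1.0)])
    def test_positive_shape_parameters(self, field, value):
        with pytest.raises(ValueError):
            AnalyteSpec("x", (1.0,), **{field: value})

    def test_chiral_channels_labelled_by_elution_order(self):
        spec = AnalyteSpec("x", (1.0, 1.4), is_chiral=True)
        assert [c[:2] for c in spec.channels()] == [
            ("E1-x", "E1"), ("E2-x", "E2")]


class TestMatrixSpec:
    def test_mobile_phase_must_be_clean(self):
        with pytest.raises(ValueError):
            MatrixSpec("mobile_phase", recovery_fraction=0.9)

    def test_recovery_fraction_bounds(self):
        m = MatrixSpec("river_water", recovery_fraction={"a": -0.1})
        with pytest.raises(ValueError):
            m.recovery("a")
        assert m.recovery("unlisted") == 1.0


class TestStudyDesign:
    def test_non_increasing_levels_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign(calibration_levels=(0.0, 1.0, 1.0))

    def test_defaults_match_standard_series(self):
        d = StudyDesign()
        assert d.calibration_levels == DEFAULT_CALIBRATION_LEVELS
        assert len([x for x in d.calibration_levels if x > 0]) == 15
        assert d.spike_levels == DEFAULT_SPIKE_LEVELS
        assert d.concentration_factor == 100.0


class TestCalibrationSeries:
    def test_default_series_levels_and_chiral_halving(self, analytes, istds):
        samples = generate_calibration_series(analytes, istds, StudyDesign())
        truth = ground_truth_frame(samples, analytes)
        levels = sorted(truth["nominal_level"].unique())
        assert levels == sorted(DEFAULT_CALIBRATION_LEVELS)
        top = truth[(truth["nominal_level"] == 1000.0)
                    & (truth["compound"] == "E1-atenolol")]
        assert (top["true_vial_concentration"] == 500.0).all()
        # internal standard present in every calibrant, including the blank
        for s in samples:
            assert s.vial_concentrations["carbamazepine-d10"] == \
                CALIBRANT_ISTD_CONCENTRATION

    def test_blank_only_series_is_zero_with_istd(self, analytes, istds):
        samples = generate_calibration_series(
            analytes, istds, StudyDesign(calibration_levels=(0.0,)))
        truth = ground_truth_frame(samples, analytes)
        assert (truth["true_vial_concentration"] == 0.0).all()
        assert all(s.vial_concentrations["cocaine-d3"] > 0 for s in samples)

    def test_empty_panel_rejected(self, istds):
        with pytest.raises(ValueError):
            generate_calibration_series([], istds, StudyDesign())

    def test_ground_truth_reproducible(self, analytes, istds, design):
        a = ground_truth_frame(
            generate_calibration_series(analytes, istds, design), analytes)
        b = ground_truth_frame(
            generate_calibration_series(analytes, istds, design), analytes)
        pd.testing.assert_frame_equal(a, b)


class TestSpikedMatrixSet:
    def test_expected_extracted_amount(self, analytes, istds):
        matrix = MatrixSpec("river_water", recovery_fraction=0.5)
        samples = generate_spiked_matrix_set(
            analytes, istds, matrix, (2.0,), 1, concentration_factor=100.0)
        # spike 2 ug/L at 50% recovery -> 1 ug/L equivalent -> vial 100 ug/L
        assert samples[0].vial_concentrations["carbamazepine"] == \
            pytest.approx(100.0)
        assert samples[0].vial_concentrations["carbamazepine"] / 100.0 == \
            pytest.approx(1.0)

    def test_zero_spike_zero_background_gives_zero(self, analytes, istds):
        matrix = MatrixSpec("effluent")
        samples = generate_spiked_matrix_set(analytes, istds, matrix, (0.0,), 2)
        for s in samples:
            for a in analytes:
                for cid, _, _ in a.channels():
                    assert s.vial_concentrations[cid] == 0.0

    def test_default_spike_groups_present(self, analytes, istds, river_water):
        samples = generate_spiked_matrix_set(analytes, istds, river_water)
        assert sorted({s.nominal_level for s in samples}) == [0.0, 0.05, 0.5, 2.0]

    def test_negative_spike_rejected(self, analytes, istds, river_water):
        with pytest.raises(ValueError):
            generate_spiked_matrix_set(analytes, istds, river_water, (-1.0,), 1)


class TestRenderChromatogram:
    def test_noise_free_trace_area_matches_request(self, istds):
        spec = AnalyteSpec("a", (2.0,), response_factor=1000.0)
        sample_set = generate_calibration_series(
            [spec], istds, StudyDesign(calibration_levels=(0.0, 10.0),
                                       replicates_per_level=1))
        sample = [s for s in sample_set if s.nominal_level == 10.0][0]
        trace = render_chromatogram(sample, spec, 0.002, noise_sd=0.0)
        area = float(np.trapezoid(trace.intensities, trace.times))
        assert area == pytest.approx(1000.0 * 10.0, rel=1e-3)

    def test_zero_concentration_flat_trace(self, istds):
        spec = AnalyteSpec("a", (2.0,))
        sample_set = generate_calibration_series(
            [spec], istds, StudyDesign(calibration_levels=(0.0,),
                                       replicates_per_level=1))
        trace = render_chromatogram(sample_set[0], spec, 0.002, noise_sd=0.0)
        assert np.all(trace.intensities == 0.0)

    def test_racemic_chiral_gives_equal_peak_areas(self, istds):
        spec = AnalyteSpec("x", (1.5, 2.5), is_chiral=True, peak_sigma=0.03)
        sample_set = generate_calibration_series(
            [spec], istds, StudyDesign(calibration_levels=(0.0, 100.0),
                                       replicates_per_level=1))
        sample = [s for s in sample_set if s.nominal_level == 100.0][0]
        trace = render_chromatogram(sample, spec, 0.002, noise_sd=0.0)
        mid = 2.0
        left = trace.times <= mid
        a1 = np.trapezoid(trace.intensities[left], trace.times[left])
        a2 = np.trapezoid(trace.intensities[~left], trace.times[~left])
        assert a1 == pytest.approx(a2, rel=1e-6)

    def test_coarse_sampling_rejected(self, analytes, istds, design):
        sample = generate_calibration_series(analytes, istds, design)[0]
        with pytest.raises(ValueError):
            render_chromatogram(sample, analytes[0],
                                sampling_interval=analytes[0].peak_sigma)


class TestEmitPeakTable:
    def test_zero_noise_matches_model_expectation(self, analytes, istds, design):
        samples = generate_calibration_series(analytes, istds, design)
        pt = emit_peak_table(samples, analytes, istds, 0, area_cv=0.0)
        row = pt[(pt["compound"] == "carbamazepine")
                 & (pt["nominal_level"] == 100.0)].iloc[0]
        assert row["area"] == pytest.approx(2500.0 * 100.0)

    def test_empirical_cv_matches_nominal(self, analytes, istds):
        spec = AnalyteSpec("a", (2.0,))
        design = StudyDesign(calibration_levels=(0.0, 10.0),
                             replicates_per_level=1000)
        samples = [s for s in generate_calibration_series([spec], [], design)
                   if s.nominal_level > 0]
        pt = emit_peak_table(samples, [spec], [], seed=5, area_cv=0.05)
        cv = pt["area"].std(ddof=1) / pt["area"].mean()
        assert 0.04 <= cv <= 0.06

    def test_schema_matches_peaks_module(self, analytes, istds, design):
        samples = generate_calibration_series(analytes, istds, design)
        pt = emit_peak_table(samples[:3], analytes, istds, 0)
        assert set(PEAK_TABLE_COLUMNS) <= set(pt.columns)

    def test_bit_reproducible_with_fixed_seed(self, analytes, istds, design,
                                              river_water):
        samples = generate_spiked_matrix_set(analytes, istds, river_water)
        a = emit_peak_table(samples, analytes, istds, seed=42, injection_cv=0.03)
        b = emit_peak_table(samples, analytes, istds, seed=42, injection_cv=0.03)
        pd.testing.assert_frame_equal(a, b)

    def test_injection_noise_shared_within_sample(self, analytes, istds, design):
        samples = generate_calibration_series(
            analytes, istds, StudyDesign(calibration_levels=(0.0, 100.0)))
        pt = emit_peak_table(samples, analytes, istds, seed=9,
                             area_cv=0.0, injection_cv=0.10)
        expected = {"carbamazepine": 2500.0 * 100,
                    "cocaine": 3200.0 * 100,
                    "E1-atenolol": 1800.0 * 50,
                    "E2-atenolol": 1800.0 * 50}
        top = pt[(pt["nominal_level"] == 100.0)
                 & pt["compound"].isin(expected)]
        for _, grp in top.groupby("sample_id"):
            scales = [r["area"] / expected[r["compound"]]
                      for _, r in grp.iterrows()]
            assert np.ptp(scales) == pytest.approx(0.0, abs=1e-12)
            assert scales[0] != pytest.approx(1.0)  # noise did apply

    def test_linear_response_at_zero_noise(self, istds):
        spec = AnalyteSpec("a", (2.0,), response_factor=1500.0)
        matrix = MatrixSpec("river_water", recovery_fraction=0.8,
                            suppression_percent=10.0)
        samples = generate_spiked_matrix_set(
            [spec], istds, matrix, (0.5, 1.0, 2.0), 1)
        pt = emit_peak_table(samples, [spec], istds, 0, area_cv=0.0)
        pt = pt[pt["compound"] == "a"]
        fit = np.polyfit(pt["nominal_level"], pt["area"], 1)
        # slope = Rf x recovery x CF x (1 - SS/100)
        assert fit[0] == pytest.approx(1500.0 * 0.8 * 100.0 * 0.9, rel=1e-3)

    def test_racemic_ef_exact_at_zero_noise(self, analytes, istds, design):
        samples = generate_calibration_series(
            analytes, istds, StudyDesign(calibration_levels=(0.0, 50.0)))
        pt = emit_peak_table(samples, analytes, istds, 0, area_cv=0.0)
        sub = pt[(pt["analyte"] == "atenolol") & (pt["nominal_level"] == 50.0)]
        wide = sub.pivot(index="sample_id", columns="compound", values="area")
        ef = wide["E1-atenolol"] / (wide["E1-atenolol"] + wide["E2-atenolol"])
        assert np.allclose(ef, 0.5)
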