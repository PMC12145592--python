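"""Truncation, region removal, SNV, Savitzky-Golay and the full chain."""

import dataclasses
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirferm import (
    PreprocessConfig,
    SpectralAxis,
    SpectraSet,
    default_preprocess_config,
    mean_center,
    remove_regions,
    run_preprocess,
    savitzky_golay,
    select_sg_window,
    simulate_feasibility_design,
    simulate_reference_measurement,
    snv_transform,
    truncate_axis,
    render_spectra,
)
from nirferm.errors import (
    AxisError,
    DegenerateSpectrumError,
    DimensionError,
    EmptySpectrumError,
    ParameterError,
)
from conftest import make_meta, make_spectra


def uniform_spectra(n=3, p=30, lo=4000.0, step=8.0, seed=0):
    rng = np.random.default_rng(seed)
    axis = SpectralAxis(lo + step * np.arange(p), "cm-1")
    return SpectraSet(axis, rng.normal(1.0, 0.3, size=(n, p)), make_meta(n))


class TestTruncateAndRemove:
    def test_truncation_window_inclusive(self, profiles, library):
        conc = simulate_feasibility_design(n=12, seed=0)
        sp = render_spectra(conc, library, profiles["lab_at_line"], seed=1)
        out = truncate_axis(sp, 4000.0, 9000.0)
        assert out.axis.values.min() >= 4000.0
        assert out.axis.values.max() <= 9000.0
        assert out.n_samples == sp.n_samples

    def test_full_window_is_identity(self):
        sp = uniform_spectra()
        out = truncate_axis(sp, 0.0, 1e6)
        assert np.array_equal(out.absorbance, sp.absorbance)

    def test_empty_truncation_raises(self):
        with pytest.raises(EmptySpectrumError):
            truncate_axis(uniform_spectra(), 10.0, 20.0)

    def test_remove_saturated_regions(self):
        axis = SpectralAxis(np.arange(4000.0, 9504.0, 8.0), "cm-1")
        sp = SpectraSet(axis, np.ones((2, len(axis.values))), make_meta(2))
        out = remove_regions(sp, [(4800.0, 5400.0), (axis.values.min(), 4300.0)])
        v = out.axis.values
        assert not np.any((v >= 4800.0) & (v <= 5400.0))
        assert not np.any(v <= 4300.0)

    def test_empty_interval_list_identity(self):
        sp = uniform_spectra()
        assert remove_regions(sp, []) is sp

    def test_total_removal_raises(self):
        sp = uniform_spectra()
        with pytest.raises(EmptySpectrumError):
            remove_regions(sp, [(0.0, 1e6)])


class TestSNV:
    def test_known_row(self):
        axis = SpectralAxis([1.0, 2.0, 3.0], "cm-1")
        sp = SpectraSet(axis, np.array([[1.0, 2.0, 3.0]]), make_meta(1))
        out = snv_transform(sp)
        assert np.allclose(out.absorbance[0], [-1.0, 0.0, 1.0])

    def test_rows_have_zero_mean_unit_sd(self, rng):
        sp = uniform_spectra(n=6, p=40, seed=3)
        out = snv_transform(sp)
        assert np.all(np.abs(out.absorbance.mean(axis=1)) < 1e-12)
        assert np.all(np.abs(out.absorbance.std(axis=1, ddof=1) - 1) < 1e-12)

    @settings(deadline=None, max_examples=30)
    @given(a=st.floats(min_value=0.1, max_value=10.0),
           b=st.floats(min_value=-5.0, max_value=5.0))
    def test_affine_invariance(self, a, b):
        sp = uniform_spectra(n=2, p=20, seed=1)
        scaled = SpectraSet(sp.axis, a * sp.absorbance + b, sp.meta)
        assert np.allclose(snv_transform(scaled).absorbance,
                           snv_transform(sp).absorbance, atol=1e-10)

    def test_constant_row_names_sample(self):
        axis = SpectralAxis([1.0, 2.0, 3.0, 4.0], "cm-1")
        sp = SpectraSet(axis, np.full((1, 4), 2.0), make_meta(1))
        with pytest.raises(DegenerateSpectrumError, match="S0"):
            snv_transform(sp)


class TestSavitzkyGolay:
    def test_exact_for_linear_ramp(self):
        p = 40
        axis = SpectralAxis(4000.0 + 8.0 * np.arange(p), "cm-1")
        row = 5.0 * np.arange(p) + 2.0
        sp = SpectraSet(axis, row[None, :], make_meta(1))
        for window in (5, 11, 21):
            out = savitzky_golay(sp, window, polyorder=2, deriv=1)
            assert np.allclose(out.absorbance, 5.0, atol=1e-9)

    def test_quadratic_derivative_matches_analytic(self):
        p = 30
        axis = SpectralAxis(4000.0 + 8.0 * np.arange(p), "cm-1")
        i = np.arange(p, dtype=float)
        sp = SpectraSet(axis, (i**2)[None, :], make_meta(1))
        out = savitzky_golay(sp, 5, polyorder=2, deriv=1)
        interior_i = i[2:-2]
        assert np.allclose(out.absorbance[0], 2 * interior_i, atol=1e-9)

    def test_quadratic_derivative_matches_local_least_squares(self):
        # direct polyfit oracle at one interior window
        rng = np.random.default_rng(0)
        row = rng.normal(size=31)
        p = 31
        axis = SpectralAxis(4000.0 + 8.0 * np.arange(p), "cm-1")
        sp = SpectraSet(axis, row[None, :], make_meta(1))
        out = savitzky_golay(sp, 7, polyorder=2, deriv=1)
        center = 15
        local = np.arange(-3, 4, dtype=float)
        coef = np.polynomial.polynomial.polyfit(local, row[center - 3:center + 4], 2)
        assert out.absorbance[0, center - 3] == pytest.approx(coef[1], abs=1e-9)

    def test_smoothing_reproduces_polynomial(self):
        p = 25
        axis = SpectralAxis(4000.0 + 8.0 * np.arange(p), "cm-1")
        i = np.arange(p, dtype=float)
        row = 3.0 + 0.5 * i - 0.02 * i**2
        sp = SpectraSet(axis, row[None, :], make_meta(1))
        out = savitzky_golay(sp, 9, polyorder=2, deriv=0)
        assert np.allclose(out.absorbance[0], row[4:-4], atol=1e-9)

    def test_edge_trimming_bookkeeping(self):
        sp = uniform_spectra(p=30)
        out = savitzky_golay(sp, 11, 2, 1)
        assert out.n_channels == 30 - (11 - 1)
        assert np.array_equal(out.axis.values, sp.axis.values[5:-5])

    @pytest.mark.parametrize("window", [4, 2, 1, 23])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ParameterError):
            savitzky_golay(uniform_spectra(p=30), window, 2, 1)

    def test_non_uniform_axis_rejected(self):
        axis = SpectralAxis([4000.0, 4010.0, 4015.0, 4030.0, 4031.0, 4055.0,
                             4070.0, 4090.0], "cm-1")
        sp = SpectraSet(axis, np.ones((1, 8)), make_meta(1))
        with pytest.raises(AxisError):
            savitzky_golay(sp, 3, 2, 1)

    def test_wavelength_native_grid_accepted(self):
        lam = np.arange(2000.0, 2100.0)  # uniform in nm
        axis = SpectralAxis(np.sort(1e7 / lam), "cm-1")
        sp = SpectraSet(axis, np.ones((1, len(lam))), make_meta(1))
        out = savitzky_golay(sp, 5, 2, 1)
        assert np.allclose(out.absorbance, 0.0, atol=1e-9)

    def test_gapped_grid_filtered_per_segment(self):
        sp = uniform_spectra(p=60)
        gapped = remove_regions(sp, [(sp.axis.values[25], sp.axis.values[33])])
        out = savitzky_golay(gapped, 5, 2, 1)
        # each of the two runs loses (window-1) channels
        assert out.n_channels == gapped.n_channels - 2 * 4
        v = out.axis.values
        assert not np.any((v >= sp.axis.values[25]) & (v <= sp.axis.values[33]))


class TestMeanCenter:
    def test_calibration_mode_zero_column_means(self, rng):
        x = rng.normal(size=(8, 5))
        centered, center = mean_center(x)
        assert np.all(np.abs(centered.mean(axis=0)) < 1e-12)
        assert np.allclose(center, x.mean(axis=0))

    def test_validation_mode_uses_given_center(self, rng):
        x = rng.normal(size=(4, 5))
        c = np.arange(5, dtype=float)
        centered, back = mean_center(x, c)
        assert np.array_equal(centered, x - c)
        assert np.array_equal(back, c)

    def test_wrong_center_length_rejected(self, rng):
        with pytest.raises(DimensionError):
            mean_center(rng.normal(size=(4, 5)), np.zeros(3))


class TestRunPreprocess:
    def test_snv_only_chain_equals_snv(self):
        sp = uniform_spectra(n=4, p=25, seed=2)
        cfg = PreprocessConfig(pre_truncation=None, snv=True, sg_window=None)
        pm = run_preprocess(sp, cfg)
        assert np.allclose(pm.matrix, snv_transform(sp).absorbance)

    def test_lab_at_line_default_truncates(self, profiles, library):
        conc = simulate_feasibility_design(n=12, seed=1)
        sp = render_spectra(conc, library, profiles["lab_at_line"], seed=0)
        pm = run_preprocess(sp, default_preprocess_config("lab_at_line"))
        assert pm.axis_cm1.min() >= 4000.0
        assert pm.axis_cm1.max() <= 9000.0

    def test_low_cost_default_keeps_full_range(self, profiles, library):
        conc = simulate_feasibility_design(n=12, seed=1)
        sp = render_spectra(conc, library, profiles["low_cost_at_line"], seed=0)
        pm = run_preprocess(sp, default_preprocess_config("low_cost_at_line"))
        full = sp.to_wavenumber().axis.values
        # only SG edge channels are lost, nothing is truncated
        assert pm.matrix.shape[1] == len(full) - 10

    def test_provenance_serializes_and_orders_steps(self):
        sp = uniform_spectra(n=4, p=40)
        cfg = PreprocessConfig(pre_truncation=(4000.0, 4300.0), snv=True, sg_window=5)
        pm = run_preprocess(sp, cfg)
        steps = [s["step"] for s in pm.provenance]
        assert steps == ["to_wavenumber", "pre_truncation", "snv", "savitzky_golay"]
        assert json.loads(json.dumps(pm.provenance)) == pm.provenance

    def test_deterministic(self):
        sp = uniform_spectra(n=4, p=40, seed=5)
        cfg = PreprocessConfig(sg_window=7)
        a = run_preprocess(sp, cfg).matrix
        b = run_preprocess(sp, cfg).matrix
        assert np.array_equal(a, b)

    def test_config_round_trips(self):
        cfg = PreprocessConfig(pre_truncation=(4000.0, 9000.0),
                               removed_regions=((4800.0, 5400.0),), sg_window=9)
        assert PreprocessConfig.from_dict(cfg.to_dict()) == cfg

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            PreprocessConfig(sg_window=4)
        with pytest.raises(ParameterError):
            PreprocessConfig(pre_truncation=(9000.0, 4000.0))


class TestSelectSGWindow:
    @staticmethod
    def _dataset(seed, noise_sd):
        import dataclasses as dc
        from nirferm.synthetic import get_profile, build_default_library
        prof = dc.replace(get_profile("lab_at_line"),
                          axis=SpectralAxis(np.arange(4000.0, 5000.0, 8.0), "cm-1"),
                          noise_sd=noise_sd)
        conc = simulate_feasibility_design(n=14, seed=seed)
        sp = render_spectra(conc, build_default_library(), prof, seed=seed + 1)
        meas = simulate_reference_measurement(conc, 0.3, seed=seed + 2)
        return sp, meas

    def test_single_candidate_returned(self):
        sp, meas = self._dataset(0, 1e-4)
        cfg = PreprocessConfig(sg_window=5)
        assert select_sg_window(sp, meas, cfg, [11], a_max=4) == 11

    def test_empty_candidates_rejected(self):
        sp, meas = self._dataset(0, 1e-4)
        with pytest.raises(ParameterError):
            select_sg_window(sp, meas, PreprocessConfig(), [], a_max=4)

    def test_noise_pushes_selection_toward_wider_windows(self):
        wins = 0
        for seed in range(10):
            sp_lo, meas = self._dataset(100 + seed, 1e-5)
            sp_hi = SpectraSet(sp_lo.axis,
                               sp_lo.absorbance + np.random.default_rng(seed).normal(
                                   0, 5e-3, sp_lo.absorbance.shape),
                               sp_lo.meta)
            cfg = PreprocessConfig()
            w_lo = select_sg_window(sp_lo, meas, cfg, [5, 17], a_max=5)
            w_hi = select_sg_window(sp_hi, meas, cfg, [5, 17], a_max=5)
            wins += w_hi >= w_lo
        assert wins >= 8
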