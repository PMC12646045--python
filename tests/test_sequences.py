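"""Sequence designer: TD dwell schedules, k-linear sweeps, exposure shaping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from octshaper.sequences import (
    BLACKMAN_FWHM_FRACTION,
    TargetSpectrum,
    VoltageSequence,
    apply_timing_delays,
    design_exposure_shaping,
    design_k_linear_sweep,
    design_td_sequence,
    predict_integrated_spectrum,
)
from octshaper.source import Spectrum, instantaneous_spectrum, wavelength_for_voltage


def _led_target():
    grid = np.linspace(750.0, 950.0, 1201)
    dens = np.exp(-4 * np.log(2) * ((grid - 850.0) / 32.0) ** 2)
    return TargetSpectrum(shape="tabulated", table=Spectrum(grid, dens))


class TestTargetShapes:
    @pytest.mark.parametrize("shape", ["rectangular", "gaussian", "blackman"])
    def test_density_fwhm_equals_requested(self, shape):
        t = TargetSpectrum(shape=shape, center_wavelength=800.0, fwhm=100.0)
        grid = np.linspace(600, 1000, 40001)
        d = t.density(grid)
        above = grid[d >= 0.5]
        assert above[-1] - above[0] == pytest.approx(100.0, rel=5e-3)

    def test_blackman_support_is_fwhm_scaled(self):
        t = TargetSpectrum(shape="blackman", center_wavelength=800.0, fwhm=100.0)
        lo, hi = t.support
        assert hi - lo == pytest.approx(100.0 / BLACKMAN_FWHM_FRACTION)


class TestTdDesign:
    def test_rect_flat_efficiency_equal_dwells(self, flat_table):
        t = TargetSpectrum(shape="rectangular", center_wavelength=800.0, fwhm=120.0)
        seq = design_td_sequence(t, flat_table, exposure=3000.0, n_steps=50)
        assert np.ptp(seq.dwells) <= seq.min_dwell  # equal within one quantum

    def test_gaussian_dwell_ratio_at_half_width(self, flat_table):
        t = TargetSpectrum(shape="gaussian", center_wavelength=800.0, fwhm=120.0)
        seq = design_td_sequence(t, flat_table, exposure=30000.0, n_steps=61)
        lam = seq.wavelengths
        d_center = seq.dwells[np.argmin(np.abs(lam - 800.0))]
        d_half = seq.dwells[np.argmin(np.abs(lam - 860.0))]
        assert d_center / d_half == pytest.approx(2.0, rel=0.05)

    def test_efficiency_compensation_identity(self, make_table):
        # triangular efficiency peak: dwell * efficiency constant across steps
        tri = lambda lam: 1.0 - 0.8 * np.abs(lam - 800.0) / 240.0
        tab = make_table(5.0, efficiency=tri)
        t = TargetSpectrum(shape="rectangular", center_wavelength=800.0, fwhm=150.0)
        seq = design_td_sequence(t, tab, exposure=60000.0, n_steps=40)
        product = seq.dwells * tab.efficiency_at(seq.wavelengths)
        assert np.ptp(product) / product.mean() < 0.05  # within quantization

    @given(
        shape=st.sampled_from(["rectangular", "gaussian", "blackman"]),
        exposure=st.floats(500.0, 5000.0),
        n_steps=st.integers(8, 96),
    )
    def test_dwell_conservation(self, table, shape, exposure, n_steps):
        t = TargetSpectrum(shape=shape, center_wavelength=820.0, fwhm=80.0)
        if n_steps * 3.0 > exposure:
            return
        seq = design_td_sequence(t, table, exposure=exposure, n_steps=n_steps)
        assert abs(seq.dwells.sum() - exposure) <= seq.min_dwell

    def test_dead_band_raises(self, make_table):
        eff = lambda lam: np.where(np.abs(lam - 800) < 60, 0.0, 1.0)
        tab = make_table(5.0, efficiency=eff)
        t = TargetSpectrum(shape="rectangular", center_wavelength=800.0, fwhm=150.0)
        with pytest.raises(ValueError, match="efficiency is zero"):
            design_td_sequence(t, tab, exposure=3000.0, n_steps=64)

    def test_sub_linewidth_target_warns(self, make_table):
        tab = make_table(8.0)
        t = TargetSpectrum(shape="gaussian", center_wavelength=800.0, fwhm=4.0)
        with pytest.warns(UserWarning, match="cannot narrow"):
            design_td_sequence(t, tab, exposure=3000.0, n_steps=32)


class TestPredictedSpectrum:
    def test_single_step_is_instantaneous_line(self, table):
        seq = VoltageSequence(
            voltages=np.array([5.0]), dwells=np.array([100.0]), exposure=100.0,
            wavelengths=np.array([wavelength_for_voltage(table, 5.0)]),
        )
        lam0 = float(seq.wavelengths[0])
        grid = np.linspace(lam0 - 30, lam0 + 30, 1501)
        pred = predict_integrated_spectrum(seq, table, grid)
        line = instantaneous_spectrum(table, lam0, grid).peak_normalized()
        assert np.allclose(pred.density, line.density, atol=1e-12)

    @pytest.mark.parametrize(
        "target_fn",
        [
            lambda: TargetSpectrum(shape="rectangular", center_wavelength=800.0, fwhm=100.0),
            lambda: TargetSpectrum(shape="gaussian", center_wavelength=800.0, fwhm=100.0),
            lambda: TargetSpectrum(shape="blackman", center_wavelength=800.0, fwhm=100.0),
            _led_target,
        ],
        ids=["rect", "gauss", "blackman", "led"],
    )
    def test_designer_error_below_5pct_of_peak(self, target_fn, make_table):
        # predicted spectrum vs the achievable one (target convolved with the
        # instantaneous line): isolates discretization/quantization error
        # from the unavoidable linewidth blur
        target = target_fn()
        tab = make_table(10.0)
        seq = design_td_sequence(target, tab, exposure=6000.0, n_steps=64)
        lo, hi = target.support
        span = hi - lo
        grid = np.linspace(lo - 0.3 * span, hi + 0.3 * span, 2000)
        pred = predict_integrated_spectrum(seq, tab, grid)
        # achievable spectrum: dense convolution of the target with the line
        fine = np.linspace(lo - 0.4 * span, hi + 0.4 * span, 8192)
        dx = fine[1] - fine[0]
        sigma = 10.0 / (2 * np.sqrt(2 * np.log(2)))
        half = int(np.ceil(5 * sigma / dx))
        kern = np.exp(-0.5 * ((np.arange(-half, half + 1) * dx) / sigma) ** 2)
        ach = np.convolve(target.density(fine), kern / kern.sum(), mode="same")
        ach = np.interp(grid, fine, ach / ach.max())
        rms = np.sqrt(np.mean((pred.density - ach) ** 2))
        assert rms < 0.05

    @pytest.mark.parametrize(
        "target_fn",
        [
            lambda: TargetSpectrum(shape="gaussian", center_wavelength=800.0, fwhm=100.0),
            lambda: TargetSpectrum(shape="blackman", center_wavelength=800.0, fwhm=100.0),
            _led_target,
        ],
        ids=["gauss", "blackman", "led"],
    )
    def test_smooth_targets_round_trip_below_5pct(self, target_fn, make_table):
        target = target_fn()
        tab = make_table(10.0)
        seq = design_td_sequence(target, tab, exposure=6000.0, n_steps=64)
        lo, hi = target.support
        span = hi - lo
        grid = np.linspace(lo - 0.3 * span, hi + 0.3 * span, 2000)
        pred = predict_integrated_spectrum(seq, tab, grid)
        rms = np.sqrt(np.mean((pred.density - target.density(grid)) ** 2))
        assert rms < 0.05


class TestKLinearSweep:
    def test_two_frames_are_endpoints(self, table):
        plan = design_k_linear_sweep(650.0, 950.0, 2, table)
        assert plan.wavelengths[0] == pytest.approx(950.0)
        assert plan.wavelengths[-1] == pytest.approx(650.0)

    def test_three_frame_midpoint_is_harmonic_mean(self, table):
        plan = design_k_linear_sweep(650.0, 950.0, 3, table)
        assert plan.wavelengths[1] == pytest.approx(2 * 650 * 950 / (650 + 950))

    def test_k_spacing_uniform_to_1e12(self, table):
        plan = design_k_linear_sweep(650.0, 950.0, 250, table)
        dk = np.diff(plan.wavenumbers)
        assert np.max(np.abs(dk - dk[0])) < 1e-12 * dk[0]

    def test_band_outside_calibration_raises(self, table):
        with pytest.raises(ValueError, match="calibrated range"):
            design_k_linear_sweep(500.0, 950.0, 10, table)


class TestExposureShaping:
    def test_flat_efficiency_gives_unit_weights(self, flat_table):
        plan = design_k_linear_sweep(650.0, 950.0, 20, flat_table)
        shaped = design_exposure_shaping(plan, flat_table)
        assert np.allclose(shaped.exposure_weights, 1.0)

    def test_half_efficiency_edges_get_double_weight(self, make_table):
        eff = lambda lam: np.where((lam < 700) | (lam > 900), 0.5, 1.0)
        tab = make_table(5.0, efficiency=eff)
        # 3-frame sweep whose end frames fall in the half-efficiency bands
        plan = design_k_linear_sweep(660.0, 940.0, 3, tab)
        shaped = design_exposure_shaping(plan, tab)
        w_edge_long, w_center, w_edge_short = shaped.exposure_weights
        # node interpolation softens the step slightly at the short edge
        assert w_edge_long == pytest.approx(1.0, rel=0.02)
        assert w_edge_short == pytest.approx(1.0, rel=0.02)
        assert w_edge_long / w_center == pytest.approx(2.0, rel=0.02)

    def test_reciprocal_rule(self, table):
        plan = design_k_linear_sweep(650.0, 950.0, 20, table)
        shaped = design_exposure_shaping(plan, table)
        inv = 1.0 / table.efficiency_at(plan.wavelengths)
        assert np.allclose(shaped.exposure_weights, inv / inv.max(), rtol=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_flattens_any_positive_profile(self, table, make_table, seed):
        rng = np.random.default_rng(seed)
        plan = design_k_linear_sweep(650.0, 950.0, 40, table)
        eff_nodes = rng.uniform(0.05, 1.0, 12)
        tab = make_table(5.0, efficiency=eff_nodes)
        shaped = design_exposure_shaping(plan, tab)
        product = tab.efficiency_at(shaped.wavelengths) * shaped.exposure_weights
        assert np.ptp(product) / product.max() < 1e-9


class TestTimingDelays:
    def test_default_delays_shift_53us(self, flat_table):
        t = TargetSpectrum(shape="rectangular", center_wavelength=800.0, fwhm=100.0)
        seq = design_td_sequence(t, flat_table, exposure=3000.0, n_steps=32)
        shifted = apply_timing_delays(seq)
        assert shifted.start_times[0] == pytest.approx(-53.0)
        assert shifted.dwells.sum() == seq.dwells.sum()

    def test_zero_delays_noop(self):
        seq = VoltageSequence(
            voltages=np.array([1.0]), dwells=np.array([30.0]), exposure=30.0,
            rf_delay=0.0, acoustic_delay=0.0,
        )
        assert apply_timing_delays(seq) == seq

    def test_idempotent(self, flat_table):
        t = TargetSpectrum(shape="gaussian", center_wavelength=800.0, fwhm=100.0)
        seq = design_td_sequence(t, flat_table, exposure=3000.0, n_steps=32)
        once = apply_timing_delays(seq)
        assert apply_timing_delays(once) == once


class TestExport:
    def test_sequence_csv_and_sidecar(self, tmp_path, flat_table):
        t = TargetSpectrum(shape="rectangular", center_wavelength=800.0, fwhm=100.0)
        seq = design_td_sequence(t, flat_table, exposure=3000.0, n_steps=16)
        out = tmp_path / "seq.csv"
        seq.to_csv(out, flat_table)
        import json
        import pandas as pd

        df = pd.read_csv(out)
        assert list(df.columns) == ["t_start_us", "voltage_V", "wavelength_nm", "dwell_us"]
        assert len(df) == seq.n_steps
        meta = json.loads(out.with_suffix(".json").read_text())
        assert meta["rf_delay_us"] == 50.0 and meta["acoustic_delay_us"] == 3.0

    def test_plan_csv(self, tmp_path, table):
        plan = design_k_linear_sweep(650.0, 950.0, 25, table)
        out = tmp_path / "plan.csv"
        plan.to_csv(out)
        import pandas as pd

        df = pd.read_csv(out)
        assert len(df) == 25
        assert np.allclose(df["wavenumber_rad_per_nm"], plan.wavenumbers)
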