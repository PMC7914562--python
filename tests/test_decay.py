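"""Lifetime fitting, shift estimation and parameter images."""
import numpy as np
import pytest

from fiberhdim.decay import (
    binned_histogram,
    estimate_time_shift,
    fit_multiexp,
    parameter_image,
    shift_to_wavelength,
    spectral_estimate,
)
from fiberhdim.forward import (
    convolve_irf,
    expected_pixel_profile,
    fractional_shift,
    render_stack,
)
from fiberhdim.types import DecayStack, FiberHdimError, InstrumentConfig, ScenePhantom

from conftest import mono


@pytest.fixture
def small_stack(config):
    counts = np.arange(4 * 5 * config.n_bins, dtype=np.int64).reshape(4, 5, config.n_bins)
    return DecayStack(counts=counts % 7, config=config)


class TestBinnedHistogram:
    def test_kernel_one_returns_own_histogram(self, small_stack):
        assert np.array_equal(binned_histogram(small_stack, 2, 3, 1),
                              small_stack.counts[2, 3].astype(float))

    def test_interior_kernel_five_equals_loop_oracle(self, config):
        rng = np.random.default_rng(4)
        stack = DecayStack(rng.poisson(5, (7, 7, config.n_bins)).astype(np.uint16),
                           config)
        got = binned_histogram(stack, 3, 3, 5)
        oracle = np.zeros(config.n_bins)
        for i in range(1, 6):
            for j in range(1, 6):
                oracle += stack.counts[i, j]
        assert np.array_equal(got, oracle)

    def test_corner_kernel_clips_to_in_bounds(self, small_stack):
        got = binned_histogram(small_stack, 0, 0, 5)
        oracle = small_stack.counts[:3, :3].sum(axis=(0, 1)).astype(float)
        assert np.array_equal(got, oracle)

    def test_even_kernel_and_outside_pixel_rejected(self, small_stack):
        with pytest.raises(FiberHdimError):
            binned_histogram(small_stack, 0, 0, 4)
        with pytest.raises(FiberHdimError):
            binned_histogram(small_stack, 99, 0, 5)


class TestFitMultiexp:
    def test_noiseless_mono_exponential_is_exact(self, config):
        hist = expected_pixel_profile([(mono(2.0), 1.0)], 1e6, config, disperse=False)
        fit = fit_multiexp(hist, 1, config)
        assert fit.t1 == pytest.approx(2.0, rel=1e-6)
        assert fit.converged

    def test_noiseless_biexponential_recovery_and_grid_oracle(self, config):
        # truth: 0.8 / 2.5 ns with 2:1 pre-exponential ratio
        from fiberhdim.types import FluorSpecies

        sp = FluorSpecies("b", (0.8, 2.5), (2.0, 1.0), 630.0, 0.0)
        hist = expected_pixel_profile([(sp, 1.0)], 1e6, config, disperse=False)
        fit = fit_multiexp(hist, 2, config)
        assert fit.t1 == pytest.approx(0.8, rel=1e-3)
        assert fit.t2 == pytest.approx(2.5, rel=1e-3)
        assert fit.a1 / fit.a2 == pytest.approx(2.0, rel=1e-3)
        # derived scalars from their defining formulas
        assert fit.f1_pct == pytest.approx(100 * 1.6 / (1.6 + 2.5), rel=1e-3)
        assert fit.t_m == pytest.approx((2 * 0.8 + 2.5) / 3, rel=1e-3)
        assert fit.it_m == pytest.approx((2 * 0.64 + 6.25) / (1.6 + 2.5), rel=1e-3)

        # independent oracle: dense lifetime grid with linear amplitude solve,
        # polished by golden-section-free local refinement of the grid best
        t = config.bin_centers
        best = None
        for t1 in np.linspace(0.5, 1.1, 25):
            for t2 in np.linspace(2.0, 3.0, 25):
                basis = np.column_stack([
                    convolve_irf(np.exp(-t / t1), config),
                    convolve_irf(np.exp(-t / t2), config),
                ])
                coef, *_ = np.linalg.lstsq(basis, hist, rcond=None)
                rss = float(((basis @ coef - hist) ** 2).sum())
                if best is None or rss < best[0]:
                    best = (rss, t1, t2, coef)
        _, g1, g2, gc = best
        assert fit.t1 == pytest.approx(g1, abs=0.03)
        assert fit.t2 == pytest.approx(g2, abs=0.05)
        assert fit.a1 / fit.a2 == pytest.approx(gc[0] / gc[1], rel=0.1)

    def test_poisson_mono_3ns_recovered_within_2pct(self, config):
        rng = np.random.default_rng(42)
        hist = rng.poisson(
            expected_pixel_profile([(mono(3.0), 1.0)], 1e6, config, disperse=False))
        fit = fit_multiexp(hist, 1, config)
        assert fit.t1 == pytest.approx(3.0, rel=0.02)

    def test_canonical_order_and_invariants(self, config):
        from fiberhdim.types import FluorSpecies

        sp = FluorSpecies("b", (2.5, 0.8), (1.0, 2.0), 630.0, 0.0)  # reversed order
        hist = expected_pixel_profile([(sp, 1.0)], 1e6, config, disperse=False)
        fit = fit_multiexp(hist, 2, config)
        assert fit.t1 <= fit.t2
        assert fit.a1 >= 0 and fit.a2 >= 0
        assert 0 <= fit.f1_pct <= 100
        assert fit.t1 <= fit.t_m <= fit.t2
        assert fit.t_m <= fit.it_m

    def test_degenerate_two_component_collapses_with_warning(self, config):
        hist = expected_pixel_profile([(mono(2.0), 1.0)], 1e6, config, disperse=False)
        with pytest.warns(RuntimeWarning):
            fit = fit_multiexp(hist, 2, config)
        assert fit.n_components == 1
        assert fit.t1 == pytest.approx(2.0, rel=1e-4)

    def test_count_floor_enforced(self, config):
        with pytest.raises(FiberHdimError):
            fit_multiexp(np.ones(config.n_bins) * 0.1, 1, config)

    def test_free_shift_recovers_shift_and_lifetime_jointly(self, config):
        # width-0 spectrum 15 nm red of reference -> 300 ps fiber delay
        hist = expected_pixel_profile(
            [(mono(1.5, peak=config.ref_wavelength + 15.0), 1.0)], 1e5, config)
        fit = fit_multiexp(hist, 1, config, free_shift=True)
        assert fit.shift == pytest.approx(300.0, abs=5.0)
        assert fit.t1 == pytest.approx(1.5, rel=0.01)


class TestTimeShift:
    def test_identity_gives_zero(self, config):
        h = expected_pixel_profile([(mono(2.0), 1.0)], 1e5, config)
        assert estimate_time_shift(h, h, config=config) == 0.0

    def test_integer_bin_shift(self, config):
        h = expected_pixel_profile([(mono(2.0), 1.0)], 1e5, config, disperse=False)
        shifted = fractional_shift(h, 4.0)
        est = estimate_time_shift(shifted, h, config=config)
        assert est == pytest.approx(4 * config.dt * 1000, abs=1.0)

    def test_fractional_shift_recovered_subbin(self, config):
        h = expected_pixel_profile([(mono(2.0), 1.0)], 1e5, config, disperse=False)
        shifted = fractional_shift(h, 0.37)
        est_bins = estimate_time_shift(shifted, h, config=config) / (config.dt * 1000)
        assert est_bins == pytest.approx(0.37, abs=0.1)
        # antisymmetry within one interpolation step
        rev = estimate_time_shift(h, shifted, config=config) / (config.dt * 1000)
        assert rev == pytest.approx(-est_bins, abs=0.05)

    def test_dense_lag_oracle_agrees(self, config):
        # oracle: integer-lag correlation on 50x-oversampled signals (both
        # channels smoothed identically, so the peak is unbiased)
        from scipy.signal import correlate, correlation_lags

        h = expected_pixel_profile([(mono(2.0), 1.0)], 1e5, config, disperse=False)
        shifted = fractional_shift(h, 1.63)
        oversample = 50
        idx = np.arange(config.n_bins * oversample) / oversample
        hf = np.interp(idx, np.arange(config.n_bins), h)
        sf = np.interp(idx, np.arange(config.n_bins), shifted)
        c = correlate(sf, hf, mode="full")
        lags = correlation_lags(sf.size, hf.size, mode="full")
        oracle_bins = lags[int(np.argmax(c))] / oversample
        est_bins = estimate_time_shift(shifted, h, config=config) / (config.dt * 1000)
        assert est_bins == pytest.approx(oracle_bins, abs=0.1)

    def test_all_zero_rejected(self, config):
        with pytest.raises(FiberHdimError):
            estimate_time_shift(np.zeros(config.n_bins), np.ones(config.n_bins),
                                config=config)


class TestShiftToWavelength:
    def test_paper_calibration_200ps_is_10nm(self):
        cfg = InstrumentConfig(ref_wavelength=600.0)
        assert shift_to_wavelength(200.0, cfg) == pytest.approx(610.0)

    def test_zero_shift_is_reference(self, config):
        assert shift_to_wavelength(0.0, config) == config.ref_wavelength

    def test_linearity(self, config):
        assert shift_to_wavelength(500.0, config) == pytest.approx(
            config.ref_wavelength + 25.0)

    def test_zero_dispersion_rejected(self):
        cfg = InstrumentConfig(dispersion_coeff=0.0)
        with pytest.raises(FiberHdimError):
            shift_to_wavelength(100.0, cfg)


class TestSpectralEstimate:
    def test_reference_and_fit_routes_agree(self, config):
        target = expected_pixel_profile(
            [(mono(2.0, peak=config.ref_wavelength + 12.0), 1.0)], 1e5, config)
        ref = expected_pixel_profile(
            [(mono(2.0, peak=config.ref_wavelength), 1.0)], 1e5, config)
        via_ref = spectral_estimate(target, config, reference=ref)
        via_fit = spectral_estimate(target, config)
        assert via_ref.peak_wavelength == pytest.approx(config.ref_wavelength + 12.0, abs=0.5)
        assert via_fit.peak_wavelength == pytest.approx(config.ref_wavelength + 12.0, abs=0.5)
        assert via_fit.peak_width == "unresolved"


class TestParameterImage:
    def _uniform_stack(self, photons=4000.0, seed=0):
        labels = np.ones((12, 12), dtype=np.int32)
        phantom = ScenePhantom(labels, {1: [(mono(2.0), 1.0)]}, {1: 1.0})
        cfg = InstrumentConfig(photons_per_pixel_scale=photons)
        return render_stack(phantom, cfg, seed=seed)

    def test_uniform_phantom_low_cv(self):
        # ~1e5 photons per 5x5 kernel -> tight per-pixel lifetime map
        stack = self._uniform_stack()
        img = parameter_image(stack, "t_m", kernel=5, n_components=1)
        vals = img[np.isfinite(img)]
        assert vals.size == img.size
        assert np.std(vals) / np.mean(vals) < 0.05

    def test_sum_image_of_empty_stack_is_zero(self, config):
        stack = DecayStack(np.zeros((6, 6, config.n_bins), dtype=np.uint16), config)
        img = parameter_image(stack, "sum", kernel=3)
        assert np.all(img == 0)

    def test_below_count_floor_pixels_are_nan(self, config):
        counts = np.zeros((6, 6, config.n_bins), dtype=np.uint16)
        stack = DecayStack(counts, config)
        img = parameter_image(stack, "t_m", kernel=3)
        assert np.all(np.isnan(img))

    def test_two_roi_peak_wavelength_recovers_true_separation(self):
        # gutter keeps 5x5 kernels from mixing the two species
        labels = np.zeros((10, 20), dtype=np.int32)
        labels[:, :8] = 1
        labels[:, 12:] = 2
        sp1 = mono(2.0, peak=624.0)
        sp2 = mono(2.0, peak=638.0)
        phantom = ScenePhantom(labels, {1: [(sp1, 1.0)], 2: [(sp2, 1.0)]},
                               {1: 1.0, 2: 1.0})
        cfg = InstrumentConfig(photons_per_pixel_scale=800.0)
        stack = render_stack(phantom, cfg, seed=2)
        img = parameter_image(stack, "peak_wavelength", kernel=5,
                              n_components=1, stride=2)
        m1 = np.nanmean(img[labels == 1])
        m2 = np.nanmean(img[labels == 2])
        assert m2 - m1 == pytest.approx(14.0, abs=1.0)

    def test_unknown_parameter_rejected(self, config):
        stack = DecayStack(np.zeros((4, 4, config.n_bins), dtype=np.uint16), config)
        with pytest.raises(FiberHdimError):
            parameter_image(stack, "bogus")
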