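"""Preprocessing pipeline: airPLS baselines, solvent zeroing, normalization,
interval cutting, and their interactions."""

import numpy as np
import pytest

from nmrmixid import (
    PreprocessConfig,
    Spectrum,
    airpls_baseline,
    correct_baseline,
    cut_interval,
    normalize,
    preprocess_library,
    zero_solvent,
)
from nmrmixid.synthetic import PeakSpec, lorentzian


def _spiky_spectrum(n=2048, seed=0, n_peaks=3):
    """Known quadratic baseline + narrow Lorentzians (ground truth kept).

    Widths follow the 1H linewidth scale of the generator (0.002-0.01 ppm):
    broad Lorentzians would contribute heavy tails that no baseline
    estimator could separate from the true drift.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 11, n)
    baseline = 2.0 + 0.3 * x - 0.02 * (x - 5) ** 2
    y = baseline.copy()
    for _ in range(n_peaks):
        y += lorentzian(x, rng.uniform(1, 10), rng.uniform(0.002, 0.01), rng.uniform(5, 20))
    return Spectrum(x, y), baseline


class TestAirPLS:
    def test_constant_spectrum_is_fixed_point(self):
        y = np.full(512, 3.7)
        base = airpls_baseline(Spectrum(np.linspace(0, 1, 512), y))
        assert np.max(np.abs(base - y)) < 1e-6 * 3.7

    def test_zero_spectrum_zero_baseline(self):
        base = airpls_baseline(np.zeros(256))
        assert np.allclose(base, 0.0)

    @pytest.mark.parametrize("n_peaks", [3, 6, 10])
    def test_recovers_quadratic_baseline(self, n_peaks):
        spec, truth = _spiky_spectrum(seed=n_peaks, n_peaks=n_peaks)
        est = airpls_baseline(spec, lam=1e5, max_iter=15)
        rmse = np.sqrt(np.mean((est - truth) ** 2))
        assert rmse < 0.02 * (truth.max() - truth.min())

    def test_non_finite_input_rejected(self):
        y = np.ones(64)
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            airpls_baseline(y)


class TestCorrectBaseline:
    def test_constant_corrects_to_zero(self):
        s = Spectrum(np.linspace(0, 1, 256), np.full(256, 5.0))
        corrected = correct_baseline(s)
        assert np.max(np.abs(corrected.intensity)) < 1e-5

    def test_off_peak_median_near_zero(self):
        spec, truth = _spiky_spectrum(seed=1)
        corrected = correct_baseline(spec)
        off_peak = np.abs(spec.intensity - truth) < 1e-3  # oracle mask
        assert abs(np.median(corrected.intensity[off_peak])) < 0.02 * truth.max()

    def test_idempotent_within_tolerance(self):
        spec, _ = _spiky_spectrum(seed=2)
        once = correct_baseline(spec)
        twice = correct_baseline(once)
        scale = np.abs(once.intensity).max()
        assert np.max(np.abs(twice.intensity - once.intensity)) < 0.02 * scale


class TestZeroSolvent:
    def test_empty_region_list_is_identity(self, raw_library):
        s = raw_library.spectrum(raw_library.names[0])
        assert np.array_equal(zero_solvent(s, []).intensity, s.intensity)

    def test_whole_axis_region_zeroes_everything(self, raw_library):
        s = raw_library.spectrum(raw_library.names[0])
        z = zero_solvent(s, [(float(s.ppm[0]), float(s.ppm[-1]))])
        assert np.all(z.intensity == 0)

    def test_window_zeroed_complement_unchanged(self, raw_library):
        s = raw_library.spectrum(raw_library.names[0])
        z = zero_solvent(s, [(3.28, 3.34)])
        mask = (s.ppm >= 3.28) & (s.ppm <= 3.34)  # oracle mask
        assert mask.any()
        assert np.all(z.intensity[mask] == 0)
        assert np.array_equal(z.intensity[~mask], s.intensity[~mask])

    def test_region_outside_axis_is_error(self, raw_library):
        s = raw_library.spectrum(raw_library.names[0])
        with pytest.raises(ValueError, match="outside"):
            zero_solvent(s, [(100.0, 101.0)])


class TestNormalize:
    def test_unit_max_input_unchanged(self):
        y = np.linspace(0, 1, 64)
        s = Spectrum(np.linspace(0, 1, 64), y)
        assert np.allclose(normalize(s).intensity, y)

    def test_scale_invariance(self, raw_library):
        s = raw_library.spectrum(raw_library.names[0])
        scaled = s.copy(intensity=5.0 * s.intensity)
        assert np.allclose(normalize(scaled).intensity, normalize(s).intensity)

    def test_max_becomes_exactly_one(self, rng):
        s = Spectrum(np.linspace(0, 1, 128), rng.random(128) + 0.1)
        assert normalize(s).intensity.max() == 1.0

    def test_nonpositive_spectrum_is_error(self):
        s = Spectrum(np.linspace(0, 1, 16), np.full(16, -1.0))
        with pytest.raises(ValueError):
            normalize(s)


class TestCutInterval:
    def test_full_axis_is_identity(self, raw_library):
        s = raw_library.spectrum(raw_library.names[0])
        c = cut_interval(s, float(s.ppm[0]), float(s.ppm[-1]))
        assert len(c) == len(s)

    def test_closed_interval_point_count(self):
        # 0.0..11.0 in 0.1 steps; [0.300, 10.700] keeps 0.3, 0.4, ..., 10.7
        s = Spectrum(np.linspace(0.0, 11.0, 111), np.zeros(111))
        assert len(cut_interval(s, 0.300, 10.700)) == 105

    def test_idempotent(self, raw_library):
        s = raw_library.spectrum(raw_library.names[0])
        once = cut_interval(s, 1.0, 9.0)
        twice = cut_interval(once, 1.0, 9.0)
        assert np.array_equal(once.ppm, twice.ppm)
        assert np.array_equal(once.intensity, twice.intensity)

    def test_empty_result_is_error(self, raw_library):
        s = raw_library.spectrum(raw_library.names[0])
        with pytest.raises(ValueError):
            cut_interval(s, 20.0, 21.0)

    def test_commutes_with_zero_solvent(self, raw_library):
        s = raw_library.spectrum(raw_library.names[0])
        a = cut_interval(zero_solvent(s, [(3.28, 3.34)]), 1.0, 9.0)
        b = zero_solvent(cut_interval(s, 1.0, 9.0), [(3.28, 3.34)])
        assert np.array_equal(a.intensity, b.intensity)


class TestPreprocessLibrary:
    def test_row_count_and_grid_shared(self, raw_library, processed_library):
        assert len(processed_library) == len(raw_library)
        assert processed_library.matrix.shape[0] == len(raw_library)

    def test_rows_max_normalized(self, processed_library):
        assert np.allclose(processed_library.matrix.max(axis=1), 1.0)

    def test_scale_invariance_of_pipeline(self, raw_library):
        from nmrmixid import SpectralLibrary

        scaled = SpectralLibrary(
            list(raw_library.names), raw_library.grid, 7.5 * raw_library.matrix
        )
        a = preprocess_library(raw_library)
        b = preprocess_library(scaled)
        assert np.allclose(a.matrix, b.matrix, atol=1e-8)

    def test_normalize_after_zeroing_amplifies_flavor_peaks(self, raw_library):
        # on solvent-dominated spectra, zeroing the solvent before
        # normalizing rescales to the tallest flavor peak; the reverse order
        # leaves flavor peaks at a small fraction of full scale
        cfg = PreprocessConfig()
        s = correct_baseline(raw_library.spectrum(raw_library.names[0]), cfg)
        zero_then_norm = normalize(zero_solvent(s, cfg.solvent_regions))
        norm_then_zero = zero_solvent(normalize(s), cfg.solvent_regions)
        assert zero_then_norm.intensity.max() > norm_then_zero.intensity.max()
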