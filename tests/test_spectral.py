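"""Spectral estimation: evoked removal, oracle equivalence of the tapered
sliding-window power, normalization and baseline invariants, band
extraction."""

import numpy as np
import pytest
from helpers import make_epochs, naive_sliding_power

from numecog import spectral
from numecog.spectral import (
    baseline_correct,
    extract_hfb,
    normalize_power,
    remove_evoked,
    timefreq_power,
)


class TestRemoveEvoked:
    def test_per_condition_mean_is_zero(self, rng):
        data = rng.standard_normal((12, 2, 100)) + 5.0
        epochs = make_epochs(data, 200.0, -0.25, conditions=["1"] * 6 + ["2"] * 6)
        out = remove_evoked(epochs)
        for cond in ("1", "2"):
            idx = out.trials["trial_type"] == cond
            assert np.abs(out.data[idx.to_numpy()].mean(axis=0)).max() < 1e-12

    def test_identical_trials_become_zero(self):
        data = np.tile(np.arange(50.0), (4, 1, 1))
        epochs = make_epochs(data, 100.0, 0.0)
        out = remove_evoked(epochs)
        assert np.abs(out.data).max() == 0.0

    def test_single_trial_condition_rejected(self, rng):
        data = rng.standard_normal((3, 1, 20))
        epochs = make_epochs(data, 100.0, 0.0, conditions=["1", "1", "2"])
        with pytest.raises(ValueError, match="'2'"):
            remove_evoked(epochs)

    def test_variance_drops_at_evoked_latency(self, rng):
        # identical injected waveform + noise: evoked removal must not
        # inflate cross-trial variance, and the mean must vanish
        n_t = 400
        wave = np.sin(2 * np.pi * 8 * np.arange(n_t) / 400.0) * 5
        data = rng.standard_normal((30, 1, n_t)) + wave
        epochs = make_epochs(data, 400.0, 0.0)
        out = remove_evoked(epochs)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12
        assert out.data.std() <= data.std()


class TestTimefreqOracle:
    def test_matches_naive_direct_sum(self, rng):
        fs = 512.0
        data = rng.standard_normal((5, 2, int(0.5 * fs) + 1))
        epochs = make_epochs(data, fs, -0.25)
        freqs = np.arange(2.0, 123.0, 2.0)
        times = np.round(np.arange(-0.08, 0.081, 0.04), 10)
        got = timefreq_power(epochs, 0.300, freqs, times)
        want = naive_sliding_power(epochs, 0.300, freqs, times)
        denom = np.maximum(np.abs(want), 1e-30)
        assert np.max(np.abs(got.power - want) / denom) < 1e-9

    def test_stationary_sinusoid_constant_power(self):
        fs = 2048.0
        t = np.arange(int(1.5 * fs) + 1) / fs - 0.5
        data = np.sin(2 * np.pi * 80.0 * t)[None, None, :]
        epochs = make_epochs(data, fs, -0.5)
        tfp = timefreq_power(epochs)
        course = tfp.power[0, 0, tfp.freqs == 80.0, :][0]
        assert (course.max() - course.min()) / course.mean() < 0.01
        assert tfp.freqs[tfp.power[0, 0, :, 45].argmax()] == 80.0

    def test_zero_input_zero_power(self):
        epochs = make_epochs(np.zeros((2, 1, 3073)), 2048.0, -0.5)
        tfp = timefreq_power(epochs)
        assert np.abs(tfp.power).max() == 0.0
        assert tfp.power.shape == (2, 1, 61, 91)

    def test_window_outside_epoch_rejected(self):
        epochs = make_epochs(np.zeros((1, 1, 205)), 2048.0, -0.05)
        with pytest.raises(ValueError, match="outside the epoch"):
            timefreq_power(epochs, 0.300, np.array([10.0]), np.array([0.0]))


class TestNormalization:
    def test_grand_mean_one_per_frequency(self, rng):
        epochs = make_epochs(rng.standard_normal((6, 2, 3073)), 2048.0, -0.5)
        tfp = normalize_power(timefreq_power(epochs))
        gm = tfp.power.mean(axis=(0, 3))
        assert np.allclose(gm, 1.0, atol=1e-12)

    def test_scale_invariance(self, rng):
        data = rng.standard_normal((4, 1, 3073))
        a = normalize_power(timefreq_power(make_epochs(data, 2048.0, -0.5)))
        b = normalize_power(timefreq_power(make_epochs(2.0 * data, 2048.0, -0.5)))
        assert np.allclose(a.power, b.power, rtol=1e-9)

    def test_double_normalization_rejected(self, rng):
        epochs = make_epochs(rng.standard_normal((3, 1, 3073)), 2048.0, -0.5)
        tfp = normalize_power(timefreq_power(epochs))
        with pytest.raises(ValueError, match="already normalized"):
            normalize_power(tfp)

    def test_zero_power_rejected(self):
        epochs = make_epochs(np.zeros((2, 1, 3073)), 2048.0, -0.5)
        with pytest.raises(ValueError, match="zero"):
            normalize_power(timefreq_power(epochs))


class TestBaseline:
    @pytest.fixture()
    def norm_tfp(self, rng):
        epochs = make_epochs(rng.standard_normal((5, 2, 3073)), 2048.0, -0.5)
        return normalize_power(timefreq_power(epochs))

    def test_window_mode_zeroes_window_mean(self, norm_tfp):
        out = baseline_correct(norm_tfp, "window", (-0.200, -0.050))
        mask = (out.times >= -0.2 - 1e-9) & (out.times <= -0.05 + 1e-9)
        base = out.power[..., mask].mean(axis=-1)
        assert np.abs(base).max() < 1e-12

    def test_point_mode_zeroes_the_point(self, norm_tfp):
        out = baseline_correct(norm_tfp, "point", point_s=-0.200)
        i = int(np.argmin(np.abs(out.times + 0.2)))
        assert np.abs(out.power[..., i]).max() == 0.0

    def test_constant_course_becomes_zero(self):
        from helpers import make_hfb

        times = np.round(np.arange(-0.2, 0.701, 0.01), 10)
        hfb = make_hfb(np.full((3, 1, times.size), 4.2), times)
        out = baseline_correct(hfb, "window", (-0.200, -0.050))
        assert np.abs(out.course).max() < 1e-12

    def test_double_correction_rejected(self, norm_tfp):
        out = baseline_correct(norm_tfp)
        with pytest.raises(ValueError, match="already baseline-corrected"):
            baseline_correct(out)

    def test_unnormalized_input_rejected(self, rng):
        tfp = timefreq_power(make_epochs(rng.standard_normal((2, 1, 3073)), 2048.0, -0.5))
        with pytest.raises(ValueError, match="normalized"):
            baseline_correct(tfp)


class TestExtractHfb:
    @pytest.fixture()
    def norm_tfp(self, rng):
        epochs = make_epochs(rng.standard_normal((4, 1, 3073)), 2048.0, -0.5)
        return normalize_power(timefreq_power(epochs))

    def test_default_band_averages_31_bins(self, norm_tfp):
        mask = (norm_tfp.freqs >= 60) & (norm_tfp.freqs <= 120)
        assert mask.sum() == 31
        hfb = extract_hfb(norm_tfp)
        want = norm_tfp.power[:, :, mask, :].mean(axis=2)
        assert np.array_equal(hfb.course, want)

    def test_constant_band_power(self, norm_tfp):
        tfp = norm_tfp.copy()
        tfp.power[:] = 0.7
        hfb = extract_hfb(tfp)
        assert np.allclose(hfb.course, 0.7)

    def test_degenerate_single_bin_band(self, norm_tfp):
        hfb = extract_hfb(norm_tfp, band_hz=(4.0, 4.0))
        assert np.array_equal(hfb.course, norm_tfp.power[:, :, norm_tfp.freqs == 4.0, :][:, :, 0, :])

    def test_band_off_grid_rejected(self, norm_tfp):
        with pytest.raises(ValueError, match="no grid frequencies"):
            extract_hfb(norm_tfp, band_hz=(500.0, 600.0))

    def test_scalar_is_mean_over_tuning_window(self, norm_tfp):
        hfb = extract_hfb(norm_tfp, tuning_window_s=(0.100, 0.350))
        mask = (hfb.times >= 0.1 - 1e-9) & (hfb.times <= 0.35 + 1e-9)
        assert np.allclose(hfb.scalar, hfb.course[:, :, mask].mean(axis=2))


def test_default_grids():
    assert spectral.DEFAULT_FREQS_HZ.size == 61
    assert spectral.DEFAULT_TIMES_S.size == 91
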