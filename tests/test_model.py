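import numpy as np
import pytest

from peakfill import (
    PeakFillParams,
    PeakFiller,
    SpectraSet,
    fill_peaks,
    generate,
    subtract_baseline,
    SyntheticSpec,
)


def _flat_set(c=4.2, n=100):
    return SpectraSet(np.arange(n, dtype=float), np.full((1, n), c))


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(hwi=0),
            dict(hwi=2, it=0),
            dict(hwi=2, bins=1),
            dict(hwi=2, interp="nearest"),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PeakFillParams(**kwargs)

    def test_hwi_required(self, small_spectra):
        with pytest.raises(ValueError, match="hwi"):
            PeakFiller(small_spectra)

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            PeakFiller(_flat_set(n=30), hwi=2, bins=20)

    def test_default_bins_one_per_ten_channels(self, small_spectra):
        model = PeakFiller(small_spectra, hwi=2)
        assert model.bin_scheme.n_bins == 12


class TestPipeline:
    def test_flat_spectrum_recovers_constant(self):
        """Every stage preserves a constant, so the baseline is the input."""
        s = _flat_set(c=4.2)
        res = PeakFiller(s, hwi=3, lam=4.0, it=5).fit()
        np.testing.assert_allclose(res.baseline, s.intensities, atol=1e-9)
        np.testing.assert_allclose(
            subtract_baseline(s, res).intensities, 0.0, atol=1e-9
        )

    def test_no_smoothing_sentinel_bypasses_whittaker(self, small_spectra):
        res = PeakFiller(small_spectra, hwi=2, lam=None).fit()
        np.testing.assert_array_equal(res.smoothed, small_spectra.intensities)

    def test_suppressed_never_exceeds_subsampled(self, small_spectra):
        res = PeakFiller(small_spectra, hwi=3, it=6).fit()
        assert np.all(res.suppressed <= res.subsampled)

    def test_baseline_passes_through_suppressed_bins(self, small_spectra):
        res = PeakFiller(small_spectra, hwi=3, interp="spline").fit()
        for i in range(small_spectra.n_spectra):
            np.testing.assert_allclose(
                res.baseline_at(res.bin_scheme.centres, i),
                res.suppressed[i],
                atol=1e-10,
            )

    def test_linear_baseline_recovered_between_isolated_peaks(self):
        """Noise-free line + narrow peaks: the baseline hugs the line
        away from the peaks."""
        spec = SyntheticSpec(
            n_channels=600,
            baseline_kind="linear",
            baseline_params=(10.0, 5.0),
            peaks=((100, 50, 3.0), (300, 80, 4.0), (480, 30, 2.5)),
            noise_sigma=0.0,
            seed=0,
        )
        spectra, truth, peak_free = generate(spec)
        res = PeakFiller(spectra, hwi=2, lam=None, bins=60, it=10).fit()
        err = (res.baseline[0] - truth)[peak_free]
        assert np.sqrt(np.mean(err**2)) < 0.15

    def test_rows_processed_independently(self, rng):
        y = rng.normal(10, 1, (2, 80))
        both = PeakFiller(SpectraSet(np.arange(80.0), y), hwi=2, it=3).fit()
        solo = PeakFiller(SpectraSet(np.arange(80.0), y[1]), hwi=2, it=3).fit()
        np.testing.assert_array_equal(both.baseline[1], solo.baseline[0])

    def test_fill_peaks_matches_model_surface(self, small_spectra):
        params = PeakFillParams(hwi=2, lam=4.0, it=4)
        a = fill_peaks(small_spectra, params)
        b = PeakFiller(small_spectra, params).fit()
        np.testing.assert_array_equal(a.baseline, b.baseline)

    def test_subtraction_is_channelwise_difference(self, small_spectra):
        res = PeakFiller(small_spectra, hwi=2).fit()
        corrected = res.subtract()
        np.testing.assert_array_equal(
            corrected.intensities,
            small_spectra.intensities - res.baseline,
        )

    def test_subtract_shape_mismatch_rejected(self, small_spectra):
        res = PeakFiller(small_spectra, hwi=2).fit()
        other = _flat_set(n=50)
        with pytest.raises(ValueError):
            subtract_baseline(other, res)

    def test_summary_mentions_schedule_and_shape(self, small_spectra):
        res = PeakFiller(small_spectra, hwi=4, it=3).fit()
        text = res.summary()
        assert "window schedule" in text
        assert str(small_spectra.n_channels) in text


class TestEquivariance:
    @pytest.mark.parametrize("seed", range(10))
    def test_positive_affine_equivariance(self, seed):
        """fit(a*y + c) == a*fit(y) + c for a > 0: smoothing is linear and
        shift-preserving; min, mean and interpolation commute with
        increasing affine maps."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 300))
        y = rng.normal(0, 5, n)
        a, c = float(rng.uniform(0.1, 10)), float(rng.uniform(-50, 50))
        axis = np.arange(n, dtype=float)
        kwargs = dict(hwi=int(rng.integers(1, 6)), it=int(rng.integers(1, 8)),
                      lam=float(rng.uniform(0, 6)))
        base = PeakFiller(SpectraSet(axis, y), **kwargs).fit().baseline[0]
        scaled = PeakFiller(SpectraSet(axis, a * y + c), **kwargs).fit().baseline[0]
        np.testing.assert_allclose(scaled, a * base + c, rtol=1e-8, atol=1e-8)
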