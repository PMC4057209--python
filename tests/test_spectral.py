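"""Welch cross-spectral estimation against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerebtfa import (
    BandDefinition,
    BandResolutionError,
    BandSummary,
    InsufficientDataError,
    SpectralEstimate,
    WelchConfig,
    band_average,
    interpret_direction,
    transfer_function,
    welch_cross_spectra,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracle: direct Hann-windowed DFT periodogram.


def dft_periodogram_oracle(x, y, fs):
    """One-segment auto/cross periodogram via an explicit DFT.

    Periodic Hann taper, segment mean removal, density scaling with
    window power correction, one-sided doubling — computed from the
    definitions, with no spectral library calls.
    """
    n = x.size
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))  # periodic Hann
    xd, yd = (x - x.mean()) * w, (y - y.mean()) * w
    k = np.arange(n // 2 + 1)
    dft = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    X, Y = dft @ xd, dft @ yd
    scale = 1.0 / (fs * np.sum(w**2))
    sxx = (np.abs(X) ** 2) * scale
    syy = (np.abs(Y) ** 2) * scale
    sxy = (np.conj(X) * Y) * scale
    # one-sided: double everything except DC and (for even n) Nyquist
    sl = slice(1, -1) if n % 2 == 0 else slice(1, None)
    for s in (sxx, syy, sxy):
        s[sl] *= 2.0
    freqs = k * fs / n
    return freqs, sxx, syy, sxy


class TestWelchCrossSpectra:
    def test_single_segment_equals_brute_force_dft(self):
        rng = np.random.default_rng(3)
        n = 600
        x = 88 + rng.normal(size=n)
        y = 72 + rng.normal(size=n)
        cfg = WelchConfig(segment_length=n, overlap_s=0.0)
        est = welch_cross_spectra(x, y, cfg)
        f0, sxx, syy, sxy = dft_periodogram_oracle(x, y, 10.0)
        np.testing.assert_allclose(est.frequencies, f0, atol=1e-12)
        np.testing.assert_allclose(est.s_map, sxx, rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(est.s_mcav, syy, rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(est.s_cross, sxy, rtol=1e-10, atol=1e-14)
        assert est.n_segments == 1

    def test_constant_input_gives_zero_spectra(self):
        x = np.full(6000, 88.0)
        est = welch_cross_spectra(x, x)
        assert np.allclose(est.s_map, 0) and np.allclose(est.s_mcav, 0)
        assert np.allclose(np.abs(est.s_cross), 0)

    def test_parseval_total_power_of_unit_sinusoid(self):
        t = np.arange(6000) / 10
        x = np.sin(2 * np.pi * 0.1 * t)
        est = welch_cross_spectra(x, x)
        total = np.sum(est.s_map) * est.df
        assert total == pytest.approx(0.5, rel=0.05)

    def test_nine_segments_for_600s_default_config(self):
        x = np.zeros(6000)
        assert welch_cross_spectra(x, x).n_segments == 9

    def test_too_short_series_errors(self):
        with pytest.raises(InsufficientDataError):
            welch_cross_spectra(np.zeros(1000), np.zeros(1000))

    def test_means_recorded(self):
        est = welch_cross_spectra(np.full(1200, 88.0), np.full(1200, 72.0))
        assert (est.mean_map, est.mean_mcav) == (88.0, 72.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25)
    def test_cauchy_schwarz_and_coherence_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=3000)
        y = 0.5 * x + rng.normal(size=3000)
        est = welch_cross_spectra(x, y)
        assert np.all(est.s_map >= 0) and np.all(est.s_mcav >= 0)
        assert np.all(
            np.abs(est.s_cross) ** 2 <= est.s_map * est.s_mcav * (1 + 1e-9) + 1e-300
        )
        coh = transfer_function(est).coherence
        ok = np.isfinite(coh)
        assert np.all(coh[ok] >= 0) and np.all(coh[ok] <= 1 + 1e-12)


class TestTransferFunction:
    def test_identity_system(self, map_600s):
        est = welch_cross_spectra(map_600s, map_600s)
        tf = transfer_function(est)
        m = (est.frequencies > 0.02) & (est.frequencies <= 0.3)
        np.testing.assert_allclose(tf.gain[m], 1.0, rtol=1e-9)
        np.testing.assert_allclose(tf.phase[m], 0.0, atol=1e-9)
        np.testing.assert_allclose(tf.coherence[m], 1.0, rtol=1e-9)

    def test_scalar_system_gain_two(self, map_600s):
        est = welch_cross_spectra(map_600s, 2.0 * map_600s)
        tf = transfer_function(est)
        m = (est.frequencies > 0.02) & (est.frequencies <= 0.3)
        np.testing.assert_allclose(tf.gain[m], 2.0, rtol=1e-9)
        np.testing.assert_allclose(tf.phase[m], 0.0, atol=1e-9)

    def test_one_sample_delay_phase_is_minus_2pi_f_dt(self, map_600s):
        # MCAv delayed by one 10 Hz sample lags: phase(f) = -2 pi f * 0.1.
        y = np.empty_like(map_600s)
        y[1:], y[0] = map_600s[:-1], map_600s[0]
        est = welch_cross_spectra(map_600s, y)
        tf = transfer_function(est)
        m = (est.frequencies >= 0.05) & (est.frequencies <= 0.3)
        np.testing.assert_allclose(
            tf.phase[m], -2 * np.pi * est.frequencies[m] * 0.1, atol=0.01
        )
        i = np.argmin(np.abs(est.frequencies - 0.1))
        assert tf.phase[i] == pytest.approx(-0.0628, abs=0.005)

    def test_lead_gives_positive_phase(self, map_600s):
        y = np.empty_like(map_600s)
        y[:-1], y[-1] = map_600s[1:], map_600s[-1]  # time-advance: MCAv leads
        est = welch_cross_spectra(map_600s, y)
        tf = transfer_function(est)
        m = (est.frequencies >= 0.05) & (est.frequencies <= 0.3)
        assert np.all(tf.phase[m] > 0)

    def test_single_segment_coherence_undefined_with_warning(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=1200), rng.normal(size=1200)
        est = welch_cross_spectra(x, y)
        with pytest.warns(UserWarning, match="coherence"):
            tf = transfer_function(est)
        assert np.all(np.isnan(tf.coherence))


def synthetic_estimate(coherence_value, n_bins=601, fs=10.0):
    """A flat estimate with exactly the requested squared coherence."""
    f = np.linspace(0, fs / 2, n_bins)
    ones = np.ones(n_bins)
    return SpectralEstimate(
        frequencies=f,
        s_map=ones,
        s_mcav=ones,
        s_cross=np.sqrt(coherence_value) * ones.astype(complex),
        n_segments=9,
        mean_map=88.0,
        mean_mcav=72.0,
    )


class TestBandAverage:
    def test_default_bands_cover_the_printed_ranges(self):
        est = synthetic_estimate(0.9)
        out = band_average(transfer_function(est), est)
        names = [(s.band.name, s.band.f_lo, s.band.f_hi) for s in out]
        assert names == [("VLF", 0.02, 0.07), ("LF", 0.07, 0.20), ("HF", 0.20, 0.30)]

    def test_band_averages_match_direct_bin_means(self, map_600s, flat_template):
        from cerebtfa import simulate_mcav

        y = simulate_mcav(map_600s, flat_template, output_noise_sd=1.0, seed=4)
        est = welch_cross_spectra(map_600s, y)
        tf = transfer_function(est)
        for s in band_average(tf, est):
            m = s.band.mask(est.frequencies)
            assert s.gain == pytest.approx(np.mean(tf.gain[m]), rel=1e-12)
            assert s.phase == pytest.approx(np.mean(tf.phase[m]), rel=1e-12)
            assert s.coherence == pytest.approx(np.mean(tf.coherence[m]), rel=1e-12)
            df = est.frequencies[1] - est.frequencies[0]
            assert s.map_power == pytest.approx(np.sum(est.s_map[m]) * df)

    def test_normalised_gain_is_gain_rescaled_by_channel_means(self):
        est = synthetic_estimate(0.9)
        out = band_average(transfer_function(est), est)
        for s in out:
            assert s.normalised_gain == pytest.approx(s.gain * 88.0 / 72.0)

    def test_coherence_028_invalid_040_valid(self):
        # The exclusion rule is a >= comparison: 0.28 fails, exactly 0.40 passes.
        for coh, expect in ((0.28, False), (0.40, True), (0.50, True)):
            est = synthetic_estimate(coh)
            lf = band_average(transfer_function(est), est)[1]
            assert lf.coherence == pytest.approx(coh)
            assert lf.valid is expect

    def test_band_powers_additive_below_total(self, map_600s):
        est = welch_cross_spectra(map_600s, map_600s)
        out = band_average(transfer_function(est), est)
        total = np.sum(est.s_map) * est.df
        assert sum(s.map_power for s in out) <= total + 1e-12

    def test_shared_band_edges_never_double_count(self):
        est = synthetic_estimate(0.9, n_bins=501)
        out = band_average(transfer_function(est), est)
        masks = [s.band.mask(est.frequencies) for s in out]
        overlap = masks[0] & masks[1] | masks[1] & masks[2]
        assert not overlap.any()

    def test_empty_band_names_resolution(self, map_600s):
        est = welch_cross_spectra(map_600s, map_600s)
        tf = transfer_function(est)
        with pytest.raises(BandResolutionError, match="resolution"):
            band_average(tf, est, bands=(BandDefinition("tiny", 0.0011, 0.0012),))

    def test_band_spectra_method_available(self, map_600s, flat_template):
        from cerebtfa import simulate_mcav

        y = simulate_mcav(map_600s, flat_template, sampling_rate=10.0)
        est = welch_cross_spectra(map_600s, y)
        tf = transfer_function(est)
        lf = band_average(tf, est, method="band_spectra")[1]
        assert lf.gain == pytest.approx(1.26, rel=0.02)
        assert lf.phase == pytest.approx(0.80, abs=0.05)


def summary(gain=1.26, ngain=1.49, phase=0.58, coherence=0.87, valid=True):
    return BandSummary(
        band=BandDefinition("LF", 0.07, 0.20),
        gain=gain,
        normalised_gain=ngain,
        phase=phase,
        coherence=coherence,
        map_power=4.6,
        mcav_power=9.2,
        valid=valid,
    )


class TestInterpretDirection:
    def test_phase_increase_is_enhanced_with_gain_unchanged(self):
        v = interpret_direction(summary(phase=0.58), summary(phase=0.82))
        assert v.phase == "enhanced"
        assert v.gain == "unchanged"
        assert v.normalised_gain == "unchanged"
        assert not v.withheld

    def test_identical_summaries_unchanged_on_all_metrics(self):
        v = interpret_direction(summary(), summary())
        assert (v.gain, v.normalised_gain, v.phase) == ("unchanged",) * 3

    def test_gain_decrease_is_enhanced_increase_diminished(self):
        v = interpret_direction(summary(gain=1.3), summary(gain=1.1))
        assert v.gain == "enhanced"
        v = interpret_direction(summary(gain=1.1), summary(gain=1.3))
        assert v.gain == "diminished"

    def test_phase_decrease_is_diminished(self):
        v = interpret_direction(summary(phase=0.82), summary(phase=0.58))
        assert v.phase == "diminished"

    def test_invalid_after_summary_withholds_verdict(self):
        after = summary(coherence=0.28, valid=False)
        v = interpret_direction(summary(), after)
        assert v.withheld
        assert "0.28" in v.reason
        assert v.phase is None
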