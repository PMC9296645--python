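"""Epoch PSD, artifact rejection, state averaging and normalization."""

import numpy as np
import pytest

import slowwave as sw
from slowwave.scoring import Hypnogram
from slowwave.spectral import (
    DELTA_ANALYSIS_BAND,
    N_FFT,
    STIMULATION_BAND,
    TOTAL_BAND,
    band_bins,
    freq_grid,
)

FS = 500.0


def sine_epoch(freq_hz, fs=FS, epoch_len_s=5.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(fs * epoch_len_s)) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t + phase)


class TestEpochPsd:
    def test_bin_spacing_is_printed_resolution(self):
        """5-s epochs at 500 Hz, zero-padded to 4096: bins every 0.12207 Hz."""
        grid = freq_grid(FS)
        df = grid[1] - grid[0]
        assert df == 500 / 4096
        assert round(df, 5) == 0.12207

    def test_zero_epoch_gives_zero_spectrum(self):
        assert np.all(sw.epoch_psd(np.zeros(2500), FS) == 0)

    def test_sine_peak_bin(self):
        """A 1.22-Hz sine peaks at bin 10 (10 * 0.12207 = 1.2207 Hz)."""
        spec = sw.epoch_psd(sine_epoch(1.22), FS)
        assert np.argmax(spec) == 10

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            sw.epoch_psd(np.zeros(5000), FS)  # longer than the FFT
        with pytest.raises(ValueError):
            sw.epoch_psd(np.array([]), FS)

    def test_parseval_energy_consistency(self):
        """Total spectrum power equals windowed-signal energy (Parseval)."""
        x = sine_epoch(2.0)
        psd = sw.epoch_psd(x, FS)
        from scipy.signal.windows import hann

        energy = np.sum((x * hann(x.size, sym=False)) ** 2)
        full = psd[0] + 2 * np.sum(psd[1:-1]) + psd[-1]
        assert full == pytest.approx(N_FFT * energy, rel=1e-6)

    def test_matches_naive_direct_dft(self):
        """FFT path agrees with an explicitly summed DFT to 1e-9."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2500)
        psd = sw.epoch_psd(x, FS)
        from scipy.signal.windows import hann

        xw = np.zeros(N_FFT)
        xw[:2500] = x * hann(2500, sym=False)
        k = np.arange(N_FFT // 2 + 1)
        naive = np.abs(np.exp(-2j * np.pi * np.outer(k, np.arange(N_FFT)) / N_FFT) @ xw) ** 2
        assert np.max(np.abs(psd - naive)) <= 1e-9 * naive.max()


class TestArtifactMask:
    def test_identical_metrics_nothing_excluded(self):
        assert not sw.artifact_mask(np.ones(50)).any()

    def test_outlier_excluded(self):
        """A 100x RMS outlier among 1000 unit epochs is the only exclusion."""
        m = np.ones(1001)
        m[500] = 100.0
        # brute-force oracle for the rule
        sem = np.std(m, ddof=1) / np.sqrt(m.size)
        expected = np.abs(m - m.mean()) > 10 * sem
        mask = sw.artifact_mask(m)
        np.testing.assert_array_equal(mask, expected)
        assert mask[500] and mask.sum() == 1

    def test_infinite_multiplier_excludes_nothing(self):
        rng = np.random.default_rng(1)
        assert not sw.artifact_mask(rng.standard_normal(200), np.inf).any()

    def test_single_epoch_no_exclusions(self):
        assert not sw.artifact_mask(np.array([3.0])).any()


class TestStatePsd:
    def _recording(self, eeg):
        return sw.Recording(eeg=eeg, emg=np.zeros_like(eeg), fs=FS)

    def test_identical_states_each_total_100(self):
        """Three states with identical spectra all normalize to 100%."""
        epoch = sine_epoch(2.0)
        eeg = np.tile(epoch, 9)
        hyp = Hypnogram(states=np.array(["WAKE", "NREM", "REM"] * 3, dtype=object))
        psd = sw.state_psd(self._recording(eeg), hyp, artifact_multiplier=np.inf)
        for state in ("WAKE", "NREM", "REM"):
            assert psd.band_power(TOTAL_BAND, state) == pytest.approx(100.0, abs=1e-6)

    def test_two_to_one_to_zero_totals(self):
        """Raw state totals 2:1:0 normalize to 200%, 100%, 0%."""
        eeg = np.concatenate(
            [np.tile(sine_epoch(2.0, amplitude=np.sqrt(2)), 3),
             np.tile(sine_epoch(2.0, amplitude=1.0), 3),
             np.zeros(3 * 2500)]
        )
        hyp = Hypnogram(states=np.array(["WAKE"] * 3 + ["NREM"] * 3 + ["REM"] * 3, dtype=object))
        psd = sw.state_psd(self._recording(eeg), hyp, artifact_multiplier=np.inf)
        assert psd.band_power(TOTAL_BAND, "WAKE") == pytest.approx(200.0, abs=1e-6)
        assert psd.band_power(TOTAL_BAND, "NREM") == pytest.approx(100.0, abs=1e-6)
        assert psd.band_power(TOTAL_BAND, "REM") == pytest.approx(0.0, abs=1e-9)

    def test_absent_state_reported_absent(self):
        eeg = np.tile(sine_epoch(3.0), 4)
        hyp = Hypnogram(states=np.array(["WAKE", "NREM"] * 2, dtype=object))
        psd = sw.state_psd(self._recording(eeg), hyp, artifact_multiplier=np.inf)
        assert set(psd.states) == {"WAKE", "NREM"}
        with pytest.raises(KeyError):
            psd.spectrum("REM")

    def test_normalization_conservation_on_noise(self):
        """Equal-weight mean of per-state totals is 100% on arbitrary input."""
        rng = np.random.default_rng(3)
        n_epochs = 30
        eeg = rng.standard_normal(n_epochs * 2500) * 20
        states = rng.choice(["WAKE", "NREM", "REM"], size=n_epochs)
        hyp = Hypnogram(states=states.astype(object))
        psd = sw.state_psd(self._recording(eeg), hyp)
        totals = [psd.band_power(TOTAL_BAND, s) for s in psd.states]
        assert np.mean(totals) == pytest.approx(100.0, abs=1e-6)

    def test_evoked_train_harmonic_maxima(self):
        """A noiseless 0.6-Hz evoked train shows local maxima at the bins
        nearest 0.61, 1.22 and 1.83 Hz in the normalized NREM spectrum."""
        spec = sw.SyntheticSpec(
            total_hours=0.1,
            noise_seed=0,
            state_spectra=sw.StateSpectra(
                nrem_delta_amp=0.0, rem_theta_amp=0.0,
                wake_broadband_amp=0.0, background_scale=0.0,
            ),
        )
        hyp = Hypnogram(states=np.array(["NREM"] * spec.n_epochs, dtype=object))
        rec = sw.generate_recording(hyp, spec, sw.StimulusProtocol(0.6, 0.4))
        psd = sw.state_psd(rec, hyp)
        s, f = psd.spectrum("NREM"), psd.freqs
        for target in (0.6104, 1.2207, 1.8311):
            i = int(np.argmin(np.abs(f - target)))
            assert s[i] > s[i - 1] and s[i] > s[i + 1]


class TestBands:
    def test_stimulation_band_bins(self):
        """The printed 0.49-0.61 Hz edges resolve to bins 4 and 5."""
        np.testing.assert_array_equal(band_bins(STIMULATION_BAND, FS), [4, 5])

    def test_delta_analysis_band_bins(self):
        """The printed 0.49-4.52 Hz edges resolve to bins 4..37."""
        np.testing.assert_array_equal(band_bins(DELTA_ANALYSIS_BAND, FS), np.arange(4, 38))

    def test_flat_spectrum_band_power_counts_bins(self):
        idx = band_bins(DELTA_ANALYSIS_BAND, FS)
        grid = freq_grid(FS)
        flat = np.ones_like(grid)
        assert sw.band_power(flat, DELTA_ANALYSIS_BAND, freqs=grid) == idx.size

    def test_empty_band_rejected(self):
        narrow = sw.BandDefinition(0.131, 0.188, "empty")  # between bin centers
        with pytest.raises(ValueError):
            band_bins(narrow, FS)


class TestPercentChange:
    def test_examples(self):
        assert sw.percent_change(1.0, 1.0) == 0.0
        assert sw.percent_change(1.644, 1.0) == pytest.approx(64.4)
        assert sw.percent_change(0.919, 1.0) == pytest.approx(-8.1)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            sw.percent_change(1.0, 0.0)


class TestSpectrogram:
    def test_stationary_signal_equal_columns(self):
        eeg = np.tile(sine_epoch(2.0), 6)
        hyp = Hypnogram(states=np.array(["NREM"] * 6, dtype=object))
        rec = sw.Recording(eeg=eeg, emg=np.zeros_like(eeg), fs=FS)
        times, freqs, mat = sw.spectrogram(rec, hyp, "NREM")
        assert mat.shape[1] == 6
        for j in range(1, 6):
            np.testing.assert_allclose(mat[:, j], mat[:, 0], rtol=1e-9)

    def test_column_count_is_state_epoch_count(self):
        rng = np.random.default_rng(4)
        eeg = rng.standard_normal(10 * 2500)
        states = np.array(["WAKE", "NREM"] * 5, dtype=object)
        hyp = Hypnogram(states=states)
        rec = sw.Recording(eeg=eeg, emg=np.zeros_like(eeg), fs=FS)
        _, _, mat = sw.spectrogram(rec, hyp, "NREM")
        assert mat.shape[1] == 5

    def test_band_row_increases_after_stimulation_onset(self):
        """Stimulation-band power steps up once the evoked train switches on."""
        spec = sw.SyntheticSpec(total_hours=0.2, noise_seed=9)
        n_ep = spec.n_epochs
        hyp = Hypnogram(states=np.array(["NREM"] * n_ep, dtype=object))
        half_s = n_ep * 5.0 / 2
        proto = sw.StimulusProtocol(
            0.6, 0.4, onset_s=half_s, duration_s=half_s,
        )
        spec = sw.SyntheticSpec(
            total_hours=0.2, noise_seed=9,
            evoked_kernel=sw.EvokedKernel(peak_uv=120.0),
        )
        rec = sw.generate_recording(hyp, spec, proto)
        times, freqs, mat = sw.spectrogram(rec, hyp, "NREM")
        band = (np.round(freqs, 2) >= 0.49) & (np.round(freqs, 2) <= 0.61)
        band_t = mat[band].sum(axis=0)
        before = band_t[times < half_s].mean()
        after = band_t[times >= half_s].mean()
        assert after > 2 * before
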