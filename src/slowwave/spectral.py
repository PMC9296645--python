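"""State-conditioned power spectral density on the 0.12207-Hz grid.

Every 5-s epoch (2500 samples at 500 Hz) is Hanning-windowed, zero-padded to
4096 samples and transformed; the padded FFT length is the only power of two
whose bin spacing at 500 Hz, 500/4096 = 0.1220703125 Hz, matches the analysis
resolution of 0.12207 Hz. Epoch spectra are averaged per vigilance state,
after excluding artifact epochs whose RMS deviates from the recording mean by
more than a configurable multiple (default 10) of the SEM across epochs, and
then normalized: each state's mean spectrum is expressed as a percentage of
the reference value R = mean over states of the per-state total power in the
0.5-20 Hz band, so the equal-weight mean of per-state totals is 100% by
construction.

Frequency-band membership uses the bin-center rounding convention: a bin at
k*0.12207 Hz belongs to a band when its center, rounded to 2 decimals, falls
inside the closed interval. The printed band edges 0.49/0.61/4.52 are the
rounded centers of bins 4, 5 and 37, so the stimulation band is bins 4..5 and
the wide delta band bins 4..37.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft
from scipy.signal.windows import hann

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - type hints only
    from .scoring import Hypnogram

logger = logging.getLogger(__name__)

__all__ = [
    "N_FFT",
    "BandDefinition",
    "STIMULATION_BAND",
    "DELTA_ANALYSIS_BAND",
    "DELTA_SCORING_BAND",
    "THETA_BAND",
    "TOTAL_BAND",
    "StatePSD",
    "freq_grid",
    "band_bins",
    "epoch_psd",
    "artifact_mask",
    "epoch_rms",
    "state_psd",
    "band_power",
    "percent_change",
    "spectrogram",
]

#: FFT length after zero padding a 5-s, 500-Hz epoch.
N_FFT = 4096


@dataclass(frozen=True)
class BandDefinition:
    """Closed frequency interval of bin centers, e.g. the stimulation band."""

    lo_hz: float
    hi_hz: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.lo_hz < self.hi_hz):
            raise ValueError(f"need 0 < lo_hz < hi_hz, got [{self.lo_hz}, {self.hi_hz}]")


#: Band around the 0.6-Hz stimulation fundamental (bins 4..5 on the grid).
STIMULATION_BAND = BandDefinition(0.49, 0.61, "stimulation")
#: Wide delta band used for slow-wave-activity contrasts (bins 4..37).
DELTA_ANALYSIS_BAND = BandDefinition(0.49, 4.52, "delta_analysis")
#: Delta band used by the vigilance-state scoring criteria.
DELTA_SCORING_BAND = BandDefinition(0.5, 4.5, "delta_scoring")
#: Theta band (REM signature; also where low-frequency harmonics land).
THETA_BAND = BandDefinition(4.0, 9.0, "theta")
#: Total band defining the normalization reference.
TOTAL_BAND = BandDefinition(0.5, 20.0, "total")


def freq_grid(fs: float, n_fft: int = N_FFT) -> np.ndarray:
    """Bin-center frequencies k * fs/n_fft for the one-sided spectrum."""
    return np.fft.rfftfreq(n_fft, d=1.0 / fs)


def band_bins(band: BandDefinition, fs: float, n_fft: int = N_FFT) -> np.ndarray:
    """Indices of bins whose center, rounded to 2 decimals, lies in the band."""
    centers = np.round(freq_grid(fs, n_fft), 2)
    idx = np.nonzero((centers >= band.lo_hz) & (centers <= band.hi_hz))[0]
    if idx.size == 0:
        raise ValueError(f"band [{band.lo_hz}, {band.hi_hz}] Hz contains no bins")
    return idx


def epoch_psd(samples: np.ndarray, fs: float, n_fft: int = N_FFT) -> np.ndarray:
    """Raw power spectrum of one epoch: |rfft(hann * x, n_fft)|^2.

    The epoch is Hanning-windowed and zero-padded to ``n_fft`` samples; the
    one-sided squared modulus is returned without the 2x single-sided energy
    correction (all downstream use is relative, so the scale cancels in the
    normalization).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("epoch must be a non-empty 1-D array")
    if x.size > n_fft:
        raise ValueError(f"epoch of {x.size} samples exceeds FFT length {n_fft}")
    w = hann(x.size, sym=False)
    spec = rfft(x * w, n=n_fft)
    return np.abs(spec) ** 2


def epoch_rms(eeg: np.ndarray, fs: float, epoch_len_s: float = 5.0) -> np.ndarray:
    """Per-epoch RMS of the signal; the artifact-rejection metric."""
    spe = int(round(fs * epoch_len_s))
    n_epochs = len(eeg) // spe
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    x = np.asarray(eeg[: n_epochs * spe], dtype=float).reshape(n_epochs, spe)
    return np.sqrt(np.mean(x**2, axis=1))


def artifact_mask(epoch_metrics: np.ndarray, multiplier: float = 10.0) -> np.ndarray:
    """Flag epochs whose metric deviates from the mean by > multiplier * SEM.

    SEM is sd/sqrt(N) over all epochs of the recording, two-sided exceedance.
    Returns True where the epoch is to be EXCLUDED. With a single epoch (or a
    non-finite multiplier) nothing is excluded.
    """
    m = np.asarray(epoch_metrics, dtype=float)
    if m.ndim != 1:
        raise ValueError("epoch metrics must be 1-D")
    n = m.size
    if n <= 1 or not math.isfinite(multiplier):
        return np.zeros(n, dtype=bool)
    sem = np.std(m, ddof=1) / np.sqrt(n)
    return np.abs(m - m.mean()) > multiplier * sem


@dataclass
class StatePSD:
    """Per-state normalized power spectral density.

    ``power[state]`` is the mean spectrum of that state's artifact-free
    epochs, expressed as percentage of the reference value per bin; states
    with zero usable epochs are absent from the mapping (not zero).
    ``freqs`` is the reported grid: bins 4..163 (0.4883-19.897 Hz), i.e. the
    bins whose rounded centers span the paper-facing 0.49-20 Hz range.
    """

    freqs: np.ndarray
    power: dict[str, np.ndarray]
    n_epochs: dict[str, int]
    reference_value: float
    fs: float = 500.0
    n_fft: int = N_FFT
    bin_offset: int = field(default=4, repr=False)  # grid starts at bin 4

    @property
    def states(self) -> list[str]:
        return list(self.power)

    def spectrum(self, state: str) -> np.ndarray:
        if state not in self.power:
            raise KeyError(f"no epochs for state {state!r}; have {self.states}")
        return self.power[state]

    def band_power(self, band: BandDefinition, state: str) -> float:
        """Summed normalized power (% units) over the band's bins."""
        idx = band_bins(band, self.fs, self.n_fft) - self.bin_offset
        if np.any(idx < 0) or np.any(idx >= self.freqs.size):
            raise ValueError(f"band {band.name or band} outside the reported grid")
        return float(np.sum(self.spectrum(state)[idx]))

    def to_frame(self):
        """Tidy table ``state,freq_hz,power_pct,n_epochs``."""
        import pandas as pd

        rows = []
        for state in self.states:
            rows.append(
                pd.DataFrame(
                    {
                        "state": state,
                        "freq_hz": self.freqs,
                        "power_pct": self.power[state],
                        "n_epochs": self.n_epochs[state],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _reported_bins(fs: float, n_fft: int) -> np.ndarray:
    """Grid reported by StatePSD: stimulation-band start (bin 4) up to 20 Hz."""
    centers = np.round(freq_grid(fs, n_fft), 2)
    lo = band_bins(STIMULATION_BAND, fs, n_fft)[0]
    idx = np.nonzero(centers <= TOTAL_BAND.hi_hz)[0]
    return idx[idx >= lo]


def state_psd(
    recording,
    hypnogram: Hypnogram,
    window: tuple[float, float] | None = None,
    artifact_multiplier: float = 10.0,
    n_fft: int = N_FFT,
) -> StatePSD:
    """Per-state mean epoch PSD with cross-state normalization.

    Epochs are taken from the hypnogram grid; the artifact mask is computed
    from per-epoch EEG RMS over the WHOLE recording, then combined with the
    hypnogram's artifact flags, and the analysis restricted to ``window``
    (``(start_s, stop_s)``; default the full recording — 24-h and 2-h windows
    are the two used in practice). Each state's mean raw spectrum is
    expressed as a percentage of R = mean over present states of the state's
    summed 0.5-20 Hz power; R is recomputed per analysis window.
    """
    fs = recording.fs
    epoch_len = hypnogram.epoch_len_s
    spe = int(round(fs * epoch_len))
    n_epochs = min(len(recording.eeg) // spe, hypnogram.n_epochs)
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")

    rms = epoch_rms(recording.eeg[: n_epochs * spe], fs, epoch_len)
    excluded = artifact_mask(rms, artifact_multiplier)
    excluded |= np.asarray(hypnogram.artifact_flags[:n_epochs], dtype=bool)

    epoch_starts = hypnogram.start_time_s + np.arange(n_epochs) * epoch_len
    in_window = np.ones(n_epochs, dtype=bool)
    if window is not None:
        t0, t1 = window
        in_window = (epoch_starts >= t0) & (epoch_starts + epoch_len <= t1)

    total_idx = band_bins(TOTAL_BAND, fs, n_fft)
    rep_idx = _reported_bins(fs, n_fft)
    grid = freq_grid(fs, n_fft)

    raw: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    states = np.asarray(hypnogram.states[:n_epochs])
    eeg = np.asarray(recording.eeg[: n_epochs * spe], dtype=float).reshape(
        n_epochs, spe
    )
    for state in ("WAKE", "NREM", "REM"):
        sel = np.nonzero((states == state) & ~excluded & in_window)[0]
        if sel.size == 0:
            continue
        acc = np.zeros(n_fft // 2 + 1)
        for i in sel:
            acc += epoch_psd(eeg[i], fs, n_fft)
        raw[state] = acc / sel.size
        counts[state] = int(sel.size)

    if not raw:
        raise ValueError("no artifact-free epochs in the analysis window")

    reference = float(np.mean([spec[total_idx].sum() for spec in raw.values()]))
    if reference <= 0:
        raise ValueError("normalization reference is non-positive (all-zero input?)")

    power = {state: 100.0 * spec[rep_idx] / reference for state, spec in raw.items()}
    n_excluded = int(np.sum(excluded & in_window))
    logger.info(
        "state_psd: %d epochs in window, %d excluded as artifacts, per-state n=%s",
        int(in_window.sum()),
        n_excluded,
        counts,
    )
    return StatePSD(
        freqs=grid[rep_idx],
        power=power,
        n_epochs=counts,
        reference_value=reference,
        fs=fs,
        n_fft=n_fft,
        bin_offset=int(rep_idx[0]),
    )


def band_power(
    psd: StatePSD | np.ndarray,
    band: BandDefinition,
    state: str | None = None,
    freqs: np.ndarray | None = None,
) -> float:
    """Summed power over the band's bins (bin-center rounding membership).

    Accepts either a ``StatePSD`` (with ``state``) or a raw spectrum array
    (with its ``freqs`` grid).
    """
    if isinstance(psd, StatePSD):
        if state is None:
            raise ValueError("state required when summing a StatePSD band")
        return psd.band_power(band, state)
    spec = np.asarray(psd, dtype=float)
    if freqs is None:
        raise ValueError("freqs grid required for a raw spectrum")
    centers = np.round(np.asarray(freqs, dtype=float), 2)
    sel = (centers >= band.lo_hz) & (centers <= band.hi_hz)
    if not np.any(sel):
        raise ValueError(f"band [{band.lo_hz}, {band.hi_hz}] Hz contains no bins")
    return float(np.sum(spec[sel]))


def percent_change(stim_value: float, baseline_value: float) -> float:
    """100 * (stim - baseline) / baseline; baseline must be positive."""
    if baseline_value <= 0:
        raise ValueError(f"baseline must be > 0, got {baseline_value}")
    return 100.0 * (stim_value - baseline_value) / baseline_value


def spectrogram(
    recording,
    hypnogram: Hypnogram,
    state: str,
    n_fft: int = N_FFT,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw per-epoch spectra of one state on the epoch time axis.

    Returns ``(times_s, freqs_hz, matrix)`` where column j of the
    (n_freq x n_epoch) matrix is the raw epoch spectrum of the j-th
    artifact-flag-free epoch of the requested state, and ``times_s`` are the
    epoch start times. Epochs of other states leave gaps in the time axis.
    """
    fs = recording.fs
    epoch_len = hypnogram.epoch_len_s
    spe = int(round(fs * epoch_len))
    n_epochs = min(len(recording.eeg) // spe, hypnogram.n_epochs)
    states = np.asarray(hypnogram.states[:n_epochs])
    flags = np.asarray(hypnogram.artifact_flags[:n_epochs], dtype=bool)
    sel = np.nonzero((states == state) & ~flags)[0]
    rep_idx = _reported_bins(fs, n_fft)
    eeg = np.asarray(recording.eeg[: n_epochs * spe], dtype=float).reshape(
        n_epochs, spe
    )
    mat = np.empty((rep_idx.size, sel.size))
    for j, i in enumerate(sel):
        mat[:, j] = epoch_psd(eeg[i], fs, n_fft)[rep_idx]
    times = hypnogram.start_time_s + sel * epoch_len
    return times, freq_grid(fs, n_fft)[rep_idx], mat
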