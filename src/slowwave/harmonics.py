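"""Peak detection and fundamental/harmonic structure in power spectra.

A periodic but non-sinusoidal stimulus-locked response produces narrow
spectral lines at exact integer multiples of the repetition rate. This module
finds peaks in a spectrum, matches them to the harmonic comb n*f0 of a
stimulation protocol, and quantifies agreement with the closed-form Fourier
amplitudes of the rectangular pulse train (the analytic oracle) — the
sine-vs-square demonstration: a pure sine yields exactly one peak, a square
wave the fundamental plus harmonics with sinc-envelope amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .spectral import StatePSD
from .stimulus import HarmonicSpectrum

__all__ = [
    "PeakList",
    "detect_peaks",
    "harmonic_structure",
    "compare_to_oracle",
    "line_spectrum",
]

#: Grid spacing used for harmonic matching tolerances (Hz).
DEFAULT_DF = 500.0 / 4096


@dataclass
class PeakList:
    """Detected spectral peaks, sorted by frequency."""

    peaks: pd.DataFrame  # columns freq_hz, power, prominence
    rel_threshold: float

    def __post_init__(self) -> None:
        self.peaks = self.peaks.sort_values("freq_hz", ignore_index=True)
        if len(self.peaks) and not np.all(self.peaks["power"] > 0):
            raise ValueError("all peak powers must be positive")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def freqs(self) -> np.ndarray:
        return self.peaks["freq_hz"].to_numpy()

    @property
    def powers(self) -> np.ndarray:
        return self.peaks["power"].to_numpy()


def detect_peaks(
    spectrum: StatePSD | np.ndarray,
    freqs: np.ndarray | None = None,
    state: str | None = None,
    rel_threshold: float = 0.01,
) -> PeakList:
    """Local maxima at least ``rel_threshold`` of the global maximum.

    A peak is a sample strictly greater than both neighbours (ties at equal
    height in separate locations are all reported). Accepts a ``StatePSD``
    (with ``state``) or a raw spectrum with its frequency grid. An all-zero
    spectrum yields an empty list.
    """
    if not (0 < rel_threshold < 1):
        raise ValueError(f"rel_threshold must be in (0, 1), got {rel_threshold}")
    if isinstance(spectrum, StatePSD):
        if state is None:
            raise ValueError("state required when detecting peaks in a StatePSD")
        freqs = spectrum.freqs
        power = spectrum.spectrum(state)
    else:
        power = np.asarray(spectrum, dtype=float)
        if freqs is None:
            raise ValueError("freqs grid required for a raw spectrum")
    if power.size == 0:
        raise ValueError("empty spectrum")

    top = power.max()
    empty = pd.DataFrame(columns=["freq_hz", "power", "prominence"])
    if top <= 0:
        return PeakList(peaks=empty, rel_threshold=rel_threshold)

    idx, _ = find_peaks(power, height=rel_threshold * top)
    if idx.size == 0:
        return PeakList(peaks=empty, rel_threshold=rel_threshold)
    prominence = peak_prominences(power, idx)[0]
    return PeakList(
        peaks=pd.DataFrame(
            {
                "freq_hz": np.asarray(freqs)[idx],
                "power": power[idx],
                "prominence": prominence,
            }
        ),
        rel_threshold=rel_threshold,
    )


def harmonic_structure(
    peaks: PeakList,
    f0: float,
    tol_bins: int = 1,
    df: float = DEFAULT_DF,
    n_max: int | None = None,
) -> set[int]:
    """Harmonic indices n whose comb frequency n*f0 has a peak within tolerance.

    A harmonic is matched when some detected peak lies within
    ``tol_bins * df`` of ``n * f0``. ``n_max`` defaults to the highest
    multiple of f0 below the top detected peak frequency.
    """
    if f0 <= 0:
        raise ValueError(f"f0 must be > 0, got {f0}")
    if len(peaks) == 0:
        return set()
    if n_max is None:
        n_max = int(np.floor((peaks.freqs.max() + tol_bins * df) / f0))
    matched = set()
    for n in range(1, n_max + 1):
        if np.any(np.abs(peaks.freqs - n * f0) <= tol_bins * df + 1e-12):
            matched.add(n)
    return matched


def compare_to_oracle(
    peaks: PeakList,
    oracle: HarmonicSpectrum,
    tol_bins: int = 1,
    df: float = DEFAULT_DF,
) -> dict[int, float]:
    """Relative amplitude error per harmonic against the analytic oracle.

    Measured amplitudes are sqrt of peak power, with the unknown overall
    spectral scale calibrated on the fundamental (n = 1), so the error at
    n = 1 is zero by construction and higher harmonics test the envelope
    shape. A harmonic the oracle expects (A_n > 0) but no peak matches is
    reported as error 1.0 (absent). Oracle zeros are skipped.
    """
    f0 = oracle.fundamental_hz

    def matched_power(n: int) -> float | None:
        if len(peaks) == 0:
            return None
        dist = np.abs(peaks.freqs - n * f0)
        i = int(np.argmin(dist))
        if dist[i] <= tol_bins * df + 1e-12:
            return float(peaks.powers[i])
        return None

    p1 = matched_power(1)
    if p1 is None or oracle.amplitude(1) <= 0:
        raise ValueError("fundamental peak required to calibrate the amplitude scale")
    scale = oracle.amplitude(1) / np.sqrt(p1)

    errors: dict[int, float] = {}
    for n in range(1, oracle.n_harmonics + 1):
        a_n = oracle.amplitude(n)
        if a_n <= 0:
            continue
        p = matched_power(n)
        if p is None:
            errors[n] = 1.0
        else:
            errors[n] = abs(scale * np.sqrt(p) - a_n) / a_n
    return errors


def line_spectrum(signal: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Unwindowed full-length power spectrum for calibration signals.

    For a noiseless periodic signal spanning an integer number of periods the
    DFT concentrates each Fourier component in a single bin, so
    ``sqrt(power) * 2 / N`` recovers component amplitudes exactly; used to
    measure pulse-train harmonics against the closed-form oracle without
    window scalloping.
    """
    x = np.asarray(signal, dtype=float)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return freqs, spec
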