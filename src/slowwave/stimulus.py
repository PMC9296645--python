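"""Periodic pulse-train stimulation protocols and their exact Fourier description.

A stimulation protocol is a rectangular pulse train: pulses of height
``amplitude`` and width ``pulse_width_s`` repeating at ``frequency_hz``.
The train's Fourier series is known in closed form, which makes it the
analytic oracle for the harmonic structure that a periodic, non-sinusoidal
stimulus imprints on an EEG power spectrum: narrow lines at every integer
multiple ``n*f`` of the repetition rate, with amplitudes following a sinc
envelope set by the duty cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusProtocol", "HarmonicSpectrum", "pulse_train", "fourier_oracle"]


@dataclass(frozen=True)
class StimulusProtocol:
    """A periodic rectangular pulse train.

    Parameters
    ----------
    frequency_hz : float
        Fundamental repetition rate of the pulses (Hz).
    pulse_width_s : float
        Duration of each pulse (s). Must satisfy
        ``0 < pulse_width_s <= 1/frequency_hz``.
    amplitude : float
        Pulse height, arbitrary units, > 0.
    onset_s : float
        Start time of the train within the recording (s), >= 0.
    duration_s : float
        Total stimulation time (s), > 0. ``math.inf`` means "until the end
        of the recording".
    label : str
        Free-text description, e.g. ``"620nm visual"`` or
        ``"629nm optogenetic"``.
    """

    frequency_hz: float
    pulse_width_s: float
    amplitude: float = 1.0
    onset_s: float = 0.0
    duration_s: float = math.inf
    label: str = ""

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError(f"frequency_hz must be > 0, got {self.frequency_hz}")
        if not (0 < self.pulse_width_s <= 1.0 / self.frequency_hz):
            raise ValueError(
                f"pulse_width_s must lie in (0, 1/frequency_hz] = "
                f"(0, {1.0 / self.frequency_hz:g}], got {self.pulse_width_s}"
            )
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")

    @property
    def duty_cycle(self) -> float:
        """Fraction of each period the pulse is on: d = f * width, in (0, 1]."""
        return self.frequency_hz * self.pulse_width_s

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency_hz


@dataclass(frozen=True)
class HarmonicSpectrum:
    """Closed-form Fourier amplitudes of a rectangular pulse train.

    ``harmonic_amplitudes[n-1]`` is the amplitude A_n of the cosine component
    at frequency ``n * fundamental_hz``; ``dc`` is the mean level. A_n
    vanishes exactly where ``n * duty`` is an integer (zeros of the sinc
    envelope).
    """

    fundamental_hz: float
    dc: float
    harmonic_amplitudes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        amps = np.asarray(self.harmonic_amplitudes, dtype=float)
        object.__setattr__(self, "harmonic_amplitudes", amps)
        if np.any(amps < 0):
            raise ValueError("harmonic amplitudes must be non-negative")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonic_amplitudes)

    def frequency(self, n: int) -> float:
        """Frequency (Hz) of harmonic index n (1-based)."""
        return n * self.fundamental_hz

    def amplitude(self, n: int) -> float:
        """Amplitude A_n of harmonic index n (1-based)."""
        return float(self.harmonic_amplitudes[n - 1])


def pulse_train(
    protocol: StimulusProtocol, fs: float, total_duration_s: float
) -> np.ndarray:
    """Sample a rectangular pulse train on the grid t_i = i / fs.

    Sample i maps to time ``i/fs`` (0-based). Within each period the pulse
    occupies the left-closed/right-open window
    ``[onset + k/f, onset + k/f + width)``; a sample landing exactly at the
    pulse offset is low. Returns an array of ``round(fs * total_duration_s)``
    samples equal to ``amplitude`` inside pulses and 0 elsewhere.
    """
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    if fs <= 2 * protocol.frequency_hz:
        raise ValueError(
            f"fs = {fs} must exceed twice the pulse rate {protocol.frequency_hz}"
        )
    if total_duration_s < protocol.onset_s:
        raise ValueError("total_duration_s must cover the protocol onset")

    n = int(round(fs * total_duration_s))
    t = np.arange(n) / fs
    rel = t - protocol.onset_s
    # position within the current period; floor() picks the period index k.
    # The 1e-9-period slack absorbs float rounding so a sample landing exactly
    # on a period start is assigned to the new pulse, and one landing exactly
    # on a pulse offset stays low (left-closed/right-open windows).
    k = np.floor(rel * protocol.frequency_hz + 1e-9)
    phase = rel - k * protocol.period_s
    teps = 1e-9 * protocol.period_s
    active = (
        (rel >= 0)
        & (rel < protocol.duration_s)
        & (phase < protocol.pulse_width_s - teps)
    )
    out = np.zeros(n)
    out[active] = protocol.amplitude
    return out


def fourier_oracle(protocol: StimulusProtocol, n_harmonics: int) -> HarmonicSpectrum:
    """Exact Fourier-series amplitudes of the protocol's pulse train.

    For a rectangular train of height A and duty cycle d the mean level is
    ``A*d`` and the amplitude of the n-th harmonic is

        A_n = (2 A / (n pi)) * |sin(n pi d)|,

    the standard sinc-envelope series. Used as the analytic oracle against
    which DFT measurements of pulse-train spectra are validated.
    """
    if n_harmonics < 1:
        raise ValueError(f"n_harmonics must be >= 1, got {n_harmonics}")
    d = protocol.duty_cycle
    a = protocol.amplitude
    n = np.arange(1, n_harmonics + 1)
    amps = (2.0 * a / (n * np.pi)) * np.abs(np.sin(n * np.pi * d))
    # snap sinc-envelope zeros (n*d integer) to exactly zero
    exact_zero = np.isclose((n * d) % 1.0, 0.0, atol=1e-12) | np.isclose(
        (n * d) % 1.0, 1.0, atol=1e-12
    )
    amps[exact_zero] = 0.0
    return HarmonicSpectrum(
        fundamental_hz=protocol.frequency_hz, dc=a * d, harmonic_amplitudes=amps
    )
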