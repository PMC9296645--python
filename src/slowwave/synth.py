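"""Synthetic EEG/EMG recordings with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at the recording conditions of a telemetered mouse: 500-Hz sampling,
5-s scoring epochs, a 12h:12h light/dark cycle. It produces

* a Markov-chain hypnogram whose per-epoch transition matrices differ between
  light (sleep-biased) and dark (wake-biased) periods;
* EEG = 1/f background noise + state-gated narrowband oscillators (NREM:
  delta-centered, REM: theta-centered, WAKE: extra broadband) switched at
  epoch boundaries through a 0.1-s cosine cross-fade, plus, when a
  stimulation protocol is given, a stimulus-locked evoked component: a damped
  oscillatory kernel convolved with the protocol's rectangular pulse train;
* EMG = white noise with per-state RMS (wake tone well above sleep atonia).

Identical spec + seed gives bit-identical output. The calibration fixtures
(pure sine, rectangular square wave) used to demonstrate harmonic generation
by non-sinusoidal periodic signals are also produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, fftconvolve, sosfilt

from .io import Recording
from .scoring import NREM, REM, STATES, WAKE, Hypnogram
from .stimulus import StimulusProtocol, pulse_train

__all__ = [
    "StateSpectra",
    "EmgLevels",
    "EvokedKernel",
    "SyntheticSpec",
    "generate_hypnogram",
    "generate_recording",
    "calibration_signal",
    "DEFAULT_LIGHT_TRANSITIONS",
    "DEFAULT_DARK_TRANSITIONS",
]

# Per-5-s-epoch transition probabilities, state order (WAKE, NREM, REM).
# Light period is sleep-biased (mice are nocturnal): short wake bouts, high
# NREM pressure; dark period is wake-biased. Implied mean bout lengths are a
# few tens of seconds to minutes, the scale seen in rodent sleep.
DEFAULT_LIGHT_TRANSITIONS = np.array(
    [
        [0.92, 0.08, 0.00],
        [0.04, 0.93, 0.03],
        [0.07, 0.05, 0.88],
    ]
)
DEFAULT_DARK_TRANSITIONS = np.array(
    [
        [0.985, 0.015, 0.000],
        [0.060, 0.925, 0.015],
        [0.080, 0.050, 0.870],
    ]
)


@dataclass(frozen=True)
class StateSpectra:
    """Oscillator parameters giving each state its spectral signature.

    Amplitudes are RMS levels in µV of the narrowband (±0.5 Hz) component;
    the 1/f background is shared by all states.
    """

    nrem_delta_hz: float = 1.5
    nrem_delta_amp: float = 40.0
    rem_theta_hz: float = 7.0
    rem_theta_amp: float = 30.0
    wake_broadband_amp: float = 10.0
    background_exponent: float = 1.0
    background_scale: float = 15.0


@dataclass(frozen=True)
class EmgLevels:
    """Per-state EMG RMS (µV). Separability assumption: wake > NREM >= REM."""

    wake: float = 30.0
    nrem: float = 8.0
    rem: float = 5.0

    def __post_init__(self) -> None:
        if not (self.wake > self.nrem >= self.rem):
            raise ValueError(
                f"need emg wake > nrem >= rem, got {self.wake}, {self.nrem}, {self.rem}"
            )

    def of(self, state: str) -> float:
        return {WAKE: self.wake, NREM: self.nrem, REM: self.rem}[state]


@dataclass(frozen=True)
class EvokedKernel:
    """Per-pulse evoked potential: a damped oscillation (generic VEP shape).

    ``peak_uv`` is the peak amplitude of the response to a single
    unit-height pulse of ``reference_width_s`` (0.4 s, the long-pulse
    protocol); shorter pulses drive proportionally weaker responses because
    the kernel is convolved with the rectangular drive, not an impulse train.
    """

    peak_uv: float = 20.0
    decay_s: float = 0.15
    ring_hz: float = 5.0
    reference_width_s: float = 0.4

    def waveform(self, fs: float) -> np.ndarray:
        """Unit-scale kernel samples out to 6 decay constants."""
        t = np.arange(int(round(6 * self.decay_s * fs))) / fs
        return np.exp(-t / self.decay_s) * np.sin(2 * np.pi * self.ring_hz * t)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic recording (the study conditions)."""

    fs: float = 500.0
    epoch_len_s: float = 5.0
    total_hours: float = 24.0
    light_onset_zt: float = 0.0
    start_zt_h: float = 0.0
    light_transitions: np.ndarray = field(
        default_factory=lambda: DEFAULT_LIGHT_TRANSITIONS.copy()
    )
    dark_transitions: np.ndarray = field(
        default_factory=lambda: DEFAULT_DARK_TRANSITIONS.copy()
    )
    state_spectra: StateSpectra = field(default_factory=StateSpectra)
    emg_rms: EmgLevels = field(default_factory=EmgLevels)
    evoked_kernel: EvokedKernel = field(default_factory=EvokedKernel)
    noise_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("light_transitions", "dark_transitions"):
            m = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, m)
            if m.shape != (3, 3) or np.any(m < 0):
                raise ValueError(f"{name} must be a non-negative 3x3 matrix")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"{name} rows must sum to 1")
        spe = self.fs * self.epoch_len_s
        if abs(spe - round(spe)) > 1e-9:
            raise ValueError("fs * epoch_len_s must be an integer")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.fs * self.epoch_len_s))

    @property
    def n_epochs(self) -> int:
        return int(round(self.total_hours * 3600 / self.epoch_len_s))


def generate_hypnogram(spec: SyntheticSpec) -> Hypnogram:
    """Markov-chain state sequence at epoch resolution, seeded and reproducible.

    The transition matrix in force at each epoch is chosen by the epoch's
    Zeitgeber time (light: sleep-biased rows, dark: wake-biased rows). The
    chain starts in WAKE.
    """
    if spec.total_hours <= 0:
        raise ValueError(f"total_hours must be > 0, got {spec.total_hours}")
    rng = np.random.default_rng([int(spec.noise_seed), 1])
    n = spec.n_epochs
    states = np.empty(n, dtype=object)
    current = 0  # WAKE
    u = rng.random(n)
    for i in range(n):
        zt = (spec.start_zt_h + i * spec.epoch_len_s / 3600.0) % 24.0
        is_light = spec.light_onset_zt <= zt < spec.light_onset_zt + 12.0
        m = spec.light_transitions if is_light else spec.dark_transitions
        current = int(np.searchsorted(np.cumsum(m[current]), u[i], side="right"))
        current = min(current, 2)
        states[i] = STATES[current]
    return Hypnogram(
        states=states,
        epoch_len_s=spec.epoch_len_s,
        start_time_s=spec.start_zt_h * 3600.0,
    )


def _smooth_gates(states: np.ndarray, spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Per-sample 0/1 state gates with a 0.1-s cosine cross-fade.

    Hard epoch-boundary switches would inject broadband clicks that the
    artifact stage then flags; the raised-cosine ramp removes them while
    keeping the gates summing to ~1 everywhere.
    """
    spe = spec.samples_per_epoch
    ramp_len = int(round(0.1 * spec.fs))
    w = np.hanning(2 * ramp_len + 1)
    w = w / w.sum()
    gates = {}
    for state in STATES:
        g = np.repeat((states == state).astype(float), spe)
        gates[state] = np.convolve(g, w, mode="same")
    return gates


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of white noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    return x / np.sqrt(np.mean(x**2))


def _narrowband(
    rng: np.random.Generator, n: int, fs: float, center_hz: float, half_bw_hz: float = 0.5
) -> np.ndarray:
    """Unit-RMS narrowband noise: white noise bandpassed around the center."""
    lo = max(center_hz - half_bw_hz, 0.05)
    hi = center_hz + half_bw_hz
    sos = butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x**2))


def evoked_response(
    protocol: StimulusProtocol,
    kernel: EvokedKernel,
    fs: float,
    total_duration_s: float,
) -> np.ndarray:
    """Stimulus-locked EEG component: kernel convolved with the pulse train.

    The rectangular drive (not an impulse train) carries the pulse width, so
    longer pulses recruit proportionally larger responses and the resulting
    comb spectrum is dominated by the fundamental, as observed for 0.6-Hz
    photic stimulation. Scaled so a single unit-height pulse of the kernel's
    reference width evokes a response peaking at ``peak_uv``.
    """
    k = kernel.waveform(fs)
    ref = np.zeros(int(round(kernel.reference_width_s * fs)) + len(k))
    ref[: int(round(kernel.reference_width_s * fs))] = 1.0
    ref_peak = np.max(np.abs(fftconvolve(ref, k)[: len(ref)] / fs))
    gain = kernel.peak_uv / ref_peak

    drive = pulse_train(protocol, fs, total_duration_s)
    n = len(drive)
    return gain * fftconvolve(drive, k)[:n] / fs


def generate_recording(
    hypnogram: Hypnogram,
    spec: SyntheticSpec,
    protocol: StimulusProtocol | None = None,
) -> Recording:
    """Synthesize the EEG/EMG sample streams for a ground-truth hypnogram."""
    if hypnogram.epoch_len_s != spec.epoch_len_s:
        raise ValueError("hypnogram epoch grid does not match the spec")
    n_epochs = hypnogram.n_epochs
    if n_epochs != spec.n_epochs:
        raise ValueError(
            f"hypnogram has {n_epochs} epochs but spec implies {spec.n_epochs}"
        )
    n = n_epochs * spec.samples_per_epoch
    rng = np.random.default_rng([int(spec.noise_seed), 2])
    ss = spec.state_spectra

    gates = _smooth_gates(hypnogram.states, spec)
    # fixed draw order keeps the noise identical with and without a protocol
    eeg = ss.background_scale * _pink_noise(rng, n, ss.background_exponent)
    eeg += (
        ss.nrem_delta_amp
        * gates[NREM]
        * _narrowband(rng, n, spec.fs, ss.nrem_delta_hz)
    )
    eeg += (
        ss.rem_theta_amp * gates[REM] * _narrowband(rng, n, spec.fs, ss.rem_theta_hz)
    )
    eeg += ss.wake_broadband_amp * gates[WAKE] * rng.standard_normal(n)

    emg_gate = sum(spec.emg_rms.of(s) * gates[s] for s in STATES)
    emg = emg_gate * rng.standard_normal(n)

    if protocol is not None:
        eeg = eeg + evoked_response(
            protocol, spec.evoked_kernel, spec.fs, n / spec.fs
        )

    return Recording(
        eeg=eeg,
        emg=emg,
        fs=spec.fs,
        start_time_s=hypnogram.start_time_s,
        protocol=protocol,
    )


def calibration_signal(
    kind: str,
    frequency_hz: float,
    pulse_width_s: float | None = None,
    fs: float = 500.0,
    duration_s: float = 60.0,
    amplitude: float = 1.0,
) -> Recording:
    """Noiseless calibration fixtures: pure sine or rectangular square wave.

    These reproduce the bench demonstration that a sinusoidal periodic signal
    yields a single spectral peak while a rectangular one yields the
    fundamental plus integer harmonics. The EMG channel is all-zero.
    """
    if kind == "sine":
        t = np.arange(int(round(fs * duration_s))) / fs
        eeg = amplitude * np.sin(2 * np.pi * frequency_hz * t)
    elif kind == "square":
        if pulse_width_s is None:
            raise ValueError("square calibration signals need pulse_width_s")
        protocol = StimulusProtocol(
            frequency_hz=frequency_hz,
            pulse_width_s=pulse_width_s,
            amplitude=amplitude,
            label="calibration square",
        )
        eeg = pulse_train(protocol, fs, duration_s)
    else:
        raise ValueError(f"unsupported calibration kind {kind!r}")
    return Recording(eeg=eeg, emg=np.zeros_like(eeg), fs=fs, subject_id=f"cal-{kind}")
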