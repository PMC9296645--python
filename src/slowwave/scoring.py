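"""Vigilance-state scoring in 5-s epochs and sleep-architecture statistics.

Each epoch is classified as WAKE, NREM or REM by a decision tree mirroring
the standard rodent criteria: sustained motor tone in the EMG defines wake;
among low-EMG epochs, theta-dominant spectra (theta/delta ratio above a
threshold) define REM, everything else NREM (delta-dominant, high-amplitude
EEG). The EMG threshold is calibrated per recording by two-class 1-D
clustering of the per-epoch EMG RMS distribution, which is strongly bimodal
when wake and sleep are both present; the theta/delta ratio threshold
defaults to 2.0.

Sleep architecture is summarized as per-block state amounts (3-h or 12-h
blocks, tagged light/dark) and as bouts: maximal runs of identical state
labels, broken by artifact epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WAKE",
    "NREM",
    "REM",
    "STATES",
    "Hypnogram",
    "ScoringThresholds",
    "BoutStats",
    "compute_epoch_features",
    "score_epoch",
    "score_features",
    "score_recording",
    "calibrate_thresholds",
    "majority_smooth",
    "state_amounts",
    "bout_analysis",
]

WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
STATES = (WAKE, NREM, REM)


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state labels with artifact flags.

    ``start_time_s`` anchors epoch 0 on the Zeitgeber clock (seconds since
    lights-on), so 3-h blocks can be tagged light/dark downstream.
    """

    states: np.ndarray
    artifact_flags: np.ndarray | None = None
    epoch_len_s: float = 5.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(len(self.states), dtype=bool)
        self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if len(self.states) != len(self.artifact_flags):
            raise ValueError("states and artifact_flags must have equal length")
        if self.epoch_len_s <= 0:
            raise ValueError(f"epoch_len_s must be > 0, got {self.epoch_len_s}")
        bad = set(self.states) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.states)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s


@dataclass(frozen=True)
class ScoringThresholds:
    """Calibrated decision-tree thresholds.

    ``emg_rms``: epoch EMG RMS above which the epoch is WAKE.
    ``theta_delta_ratio``: theta/delta power ratio above which a low-EMG
    epoch is REM (default 2.0).
    """

    emg_rms: float
    theta_delta_ratio: float = 2.0


def compute_epoch_features(recording, epoch_len_s: float = 5.0) -> pd.DataFrame:
    """Per-epoch scoring features: band powers, EEG amplitude, EMG tone.

    One row per complete epoch (a trailing partial epoch is dropped) with
    columns ``delta_power`` (0.5-4.5 Hz), ``theta_power`` (4-9 Hz),
    ``total_power`` (0.5-20 Hz), ``eeg_amplitude`` (epoch RMS of EEG) and
    ``emg_rms``. Band powers are integrals of the epoch PSD over the scoring
    bands.
    """
    from .spectral import (
        DELTA_SCORING_BAND,
        N_FFT,
        THETA_BAND,
        TOTAL_BAND,
        band_bins,
        epoch_psd,
    )

    fs = recording.fs
    spe = int(round(fs * epoch_len_s))
    n_epochs = len(recording.eeg) // spe
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")

    delta_idx = band_bins(DELTA_SCORING_BAND, fs, N_FFT)
    theta_idx = band_bins(THETA_BAND, fs, N_FFT)
    total_idx = band_bins(TOTAL_BAND, fs, N_FFT)

    eeg = np.asarray(recording.eeg[: n_epochs * spe], dtype=float).reshape(
        n_epochs, spe
    )
    emg = np.asarray(recording.emg[: n_epochs * spe], dtype=float).reshape(
        n_epochs, spe
    )
    rows = np.empty((n_epochs, 5))
    for i in range(n_epochs):
        spec = epoch_psd(eeg[i], fs, N_FFT)
        rows[i] = (
            spec[delta_idx].sum(),
            spec[theta_idx].sum(),
            spec[total_idx].sum(),
            np.sqrt(np.mean(eeg[i] ** 2)),
            np.sqrt(np.mean(emg[i] ** 2)),
        )
    return pd.DataFrame(
        rows,
        columns=["delta_power", "theta_power", "total_power", "eeg_amplitude", "emg_rms"],
    )


def score_epoch(features, thresholds: ScoringThresholds) -> str:
    """Classify one epoch's features as WAKE, NREM or REM.

    Decision tree in criteria-precedence order: EMG tone above threshold ->
    WAKE; else theta/delta ratio above threshold -> REM; else NREM. An epoch
    with zero delta and zero theta power is scored NREM by convention (the
    degenerate case is logged).
    """
    if features["emg_rms"] > thresholds.emg_rms:
        return WAKE
    delta = features["delta_power"]
    theta = features["theta_power"]
    if delta == 0:
        if theta == 0:
            logger.warning("degenerate epoch with zero delta and theta power; scored NREM")
            return NREM
        return REM
    if theta / delta > thresholds.theta_delta_ratio:
        return REM
    return NREM


def score_features(
    features: pd.DataFrame,
    thresholds: ScoringThresholds,
    epoch_len_s: float = 5.0,
    start_time_s: float = 0.0,
    smooth: bool = False,
) -> Hypnogram:
    """Score every epoch in a feature table; optionally majority-smooth."""
    emg = features["emg_rms"].to_numpy()
    delta = features["delta_power"].to_numpy()
    theta = features["theta_power"].to_numpy()
    states = np.where(
        emg > thresholds.emg_rms,
        WAKE,
        np.where(
            (delta > 0) & (theta / np.maximum(delta, np.finfo(float).tiny) > thresholds.theta_delta_ratio)
            | ((delta == 0) & (theta > 0)),
            REM,
            NREM,
        ),
    ).astype(object)
    n_degenerate = int(np.sum((delta == 0) & (theta == 0) & (emg <= thresholds.emg_rms)))
    if n_degenerate:
        logger.warning("%d degenerate zero-power epochs scored NREM", n_degenerate)
    if smooth:
        states = majority_smooth(states)
    return Hypnogram(
        states=states, epoch_len_s=epoch_len_s, start_time_s=start_time_s
    )


def score_recording(
    recording,
    thresholds: ScoringThresholds | None = None,
    epoch_len_s: float = 5.0,
    smooth: bool = False,
) -> Hypnogram:
    """Feature extraction, (optional) calibration and epoch scoring in one go."""
    features = compute_epoch_features(recording, epoch_len_s)
    if thresholds is None:
        thresholds = calibrate_thresholds(features)
    return score_features(
        features,
        thresholds,
        epoch_len_s=epoch_len_s,
        start_time_s=getattr(recording, "start_time_s", 0.0),
        smooth=smooth,
    )


def majority_smooth(states: np.ndarray) -> np.ndarray:
    """Relabel isolated single-epoch states flanked by two identical labels.

    A minimal transition smoother (OFF by default in the pipeline): epoch i
    is replaced when its two neighbours agree with each other but not with
    it. Single pass, ends untouched.
    """
    out = np.asarray(states, dtype=object).copy()
    for i in range(1, len(out) - 1):
        if out[i - 1] == out[i + 1] != out[i]:
            out[i] = out[i - 1]
    return out


def calibrate_thresholds(
    features: pd.DataFrame,
    theta_delta_ratio: float = 2.0,
) -> ScoringThresholds:
    """Derive the EMG threshold from the epoch EMG RMS distribution.

    Two-class 1-D k-means on ``emg_rms``; the threshold is the midpoint
    between the two cluster centers. If the distribution does not look
    bimodal (cluster separation below twice the summed within-cluster
    spreads, or a near-empty cluster), falls back to the 75th percentile and
    logs a warning.
    """
    if len(features) < 100:
        raise ValueError(f"calibration needs >= 100 epochs, got {len(features)}")
    emg = features["emg_rms"].to_numpy(dtype=float)

    from sklearn.cluster import KMeans

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-cluster degeneracy handled below
        km = KMeans(n_clusters=2, n_init=10, random_state=0)
        labels = km.fit_predict(emg.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())
    lo_mask = labels == int(np.argmin(km.cluster_centers_.ravel()))
    min_frac = min(lo_mask.mean(), 1 - lo_mask.mean())
    if min_frac > 0:
        spread = np.std(emg[lo_mask]) + np.std(emg[~lo_mask])
    else:
        spread = np.inf
    separation = centers[1] - centers[0]

    if separation <= 2.0 * spread or min_frac < 0.01:
        logger.warning(
            "EMG RMS distribution looks unimodal (separation %.3g vs spread %.3g); "
            "falling back to 75th-percentile threshold",
            separation,
            spread,
        )
        return ScoringThresholds(
            emg_rms=float(np.percentile(emg, 75)),
            theta_delta_ratio=theta_delta_ratio,
        )
    return ScoringThresholds(
        emg_rms=float(centers.mean()), theta_delta_ratio=theta_delta_ratio
    )


def state_amounts(
    hypnogram: Hypnogram,
    block_hours: float = 3.0,
    light_onset_zt: float = 0.0,
) -> pd.DataFrame:
    """Time and percent per state in consecutive 3-h (or 12-h) blocks.

    Artifact epochs are excluded from both numerator and denominator; a
    trailing partial block is dropped. Each block is tagged light/dark by
    the Zeitgeber time of its start (``hypnogram.start_time_s`` is seconds
    since ZT0 = lights-on; lights are on for 12 h from ``light_onset_zt``).
    Returns a tidy frame ``block,block_start_s,is_light,state,seconds,percent``.
    """
    epochs_per_block = int(round(block_hours * 3600 / hypnogram.epoch_len_s))
    n_blocks = hypnogram.n_epochs // epochs_per_block
    rows = []
    for b in range(n_blocks):
        sl = slice(b * epochs_per_block, (b + 1) * epochs_per_block)
        states = hypnogram.states[sl]
        flags = hypnogram.artifact_flags[sl]
        valid = ~flags
        denom = valid.sum() * hypnogram.epoch_len_s
        start_s = hypnogram.start_time_s + b * epochs_per_block * hypnogram.epoch_len_s
        zt = (start_s / 3600.0) % 24.0
        is_light = light_onset_zt <= zt < light_onset_zt + 12.0
        for state in STATES:
            sec = float(np.sum((states == state) & valid) * hypnogram.epoch_len_s)
            rows.append(
                {
                    "block": b,
                    "block_start_s": start_s,
                    "is_light": is_light,
                    "state": state,
                    "seconds": sec,
                    "percent": 100.0 * sec / denom if denom > 0 else np.nan,
                }
            )
    columns = ["block", "block_start_s", "is_light", "state", "seconds", "percent"]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class BoutStats:
    """Per-state bout counts, mean durations and total time.

    A bout is a maximal run of identical consecutive state labels; artifact
    epochs break runs and belong to no state. The invariant
    ``bout_count * mean_bout_duration_s == total_time_s`` holds exactly, and
    state totals plus artifact time partition the recording.
    """

    bout_count: dict[str, int]
    mean_bout_duration_s: dict[str, float]
    total_time_s: dict[str, float]
    artifact_time_s: float
    epoch_len_s: float = 5.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": list(STATES),
                "bout_count": [self.bout_count[s] for s in STATES],
                "mean_bout_duration_s": [self.mean_bout_duration_s[s] for s in STATES],
                "total_time_s": [self.total_time_s[s] for s in STATES],
            }
        )


def bout_analysis(hypnogram: Hypnogram) -> BoutStats:
    """Count bouts (maximal same-state runs) and their durations per state."""
    if hypnogram.n_epochs == 0:
        raise ValueError("empty hypnogram")
    counts = {s: 0 for s in STATES}
    totals = {s: 0.0 for s in STATES}
    run_state: str | None = None
    run_len = 0

    def close_run() -> None:
        nonlocal run_state, run_len
        if run_state is not None and run_len > 0:
            counts[run_state] += 1
            totals[run_state] += run_len * hypnogram.epoch_len_s
        run_state, run_len = None, 0

    for state, is_artifact in zip(hypnogram.states, hypnogram.artifact_flags):
        if is_artifact:
            close_run()
            continue
        if state != run_state:
            close_run()
            run_state = state
        run_len += 1
    close_run()

    means = {
        s: (totals[s] / counts[s]) if counts[s] else 0.0 for s in STATES
    }
    artifact_time = float(hypnogram.artifact_flags.sum() * hypnogram.epoch_len_s)
    return BoutStats(
        bout_count=counts,
        mean_bout_duration_s=means,
        total_time_s=totals,
        artifact_time_s=artifact_time,
        epoch_len_s=hypnogram.epoch_len_s,
    )
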