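"""Configuration and the end-to-end analysis pipeline.

The pipeline mirrors the experimental design: per subject, a baseline day
and a stimulation day are recorded (here: synthesized), each recording is
scored into a hypnogram, state-conditioned PSDs and band powers are computed
per day, sleep architecture is tabulated, and baseline-vs-stimulation band
powers are contrasted with paired t-tests across subjects. Every stage reads
and writes the documented file formats inside one working directory, and
``run_pipeline`` is literally the composition of the stage functions the CLI
exposes, so stepwise and single-shot runs produce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as swio
from .harmonics import detect_peaks, harmonic_structure
from .scoring import (
    STATES,
    ScoringThresholds,
    bout_analysis,
    calibrate_thresholds,
    compute_epoch_features,
    score_features,
    state_amounts,
)
from .spectral import (
    DELTA_ANALYSIS_BAND,
    STIMULATION_BAND,
    THETA_BAND,
    BandDefinition,
    StatePSD,
    percent_change,
    state_psd,
)
from .stats import paired_t, summarize
from .stimulus import StimulusProtocol
from .synth import (
    EmgLevels,
    EvokedKernel,
    StateSpectra,
    SyntheticSpec,
    generate_hypnogram,
    generate_recording,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "stage_simulate",
    "stage_score",
    "stage_spectra",
    "stage_harmonics",
    "stage_stats",
    "read_state_psd_csv",
]

ANALYSIS_BANDS: dict[str, BandDefinition] = {
    "stimulation": STIMULATION_BAND,
    "delta_analysis": DELTA_ANALYSIS_BAND,
    "theta": THETA_BAND,
}


def _from_mapping(cls, data: dict, context: str):
    """Build a dataclass from a dict, rejecting unknown keys by name."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown keys in {context}: {sorted(unknown)}; allowed: {sorted(names)}"
        )
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration (loadable from a YAML file).

    ``psd_window_h`` restricts the spectral analysis to the first N hours
    (the 2-h analysis window); ``None`` analyses the full recording. The
    stimulation-day protocol is shared by simulation and analysis.
    """

    seed: int = 0
    n_subjects: int = 4
    total_hours: float = 2.0
    fs: float = 500.0
    epoch_len_s: float = 5.0
    light_onset_zt: float = 0.0
    start_zt_h: float = 0.0
    protocol: StimulusProtocol = field(
        default_factory=lambda: StimulusProtocol(
            frequency_hz=0.6, pulse_width_s=0.4, amplitude=1.0, label="620nm visual"
        )
    )
    state_spectra: StateSpectra = field(default_factory=StateSpectra)
    emg_rms: EmgLevels = field(default_factory=EmgLevels)
    evoked_kernel: EvokedKernel = field(default_factory=EvokedKernel)
    theta_delta_ratio: float = 2.0
    smooth: bool = False
    artifact_multiplier: float = 10.0
    psd_window_h: float | None = None
    block_hours: float = 3.0
    harmonics_state: str = "NREM"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        nested = {
            "protocol": StimulusProtocol,
            "state_spectra": StateSpectra,
            "emg_rms": EmgLevels,
            "evoked_kernel": EvokedKernel,
        }
        for key, sub_cls in nested.items():
            if key in data and isinstance(data[key], dict):
                data[key] = _from_mapping(sub_cls, data[key], key)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}; allowed: {sorted(names)}"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, float) and math.isinf(o):
                return "inf"
            raise TypeError(type(o))

        blob = json.dumps(self.to_dict(), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def synthetic_spec(self, noise_seed: int) -> SyntheticSpec:
        return SyntheticSpec(
            fs=self.fs,
            epoch_len_s=self.epoch_len_s,
            total_hours=self.total_hours,
            light_onset_zt=self.light_onset_zt,
            start_zt_h=self.start_zt_h,
            state_spectra=self.state_spectra,
            emg_rms=self.emg_rms,
            evoked_kernel=self.evoked_kernel,
            noise_seed=noise_seed,
        )

    def thresholds(self, emg_rms: float) -> ScoringThresholds:
        return ScoringThresholds(
            emg_rms=emg_rms, theta_delta_ratio=self.theta_delta_ratio
        )


DAYS = ("baseline", "stim")


def _subject_seed(config: PipelineConfig, subject: int, day_index: int) -> int:
    return (config.seed * 1_000_003 + subject * 101 + day_index) % (2**31)


def _edf_path(out_dir: Path, subject: int, day: str) -> Path:
    return out_dir / f"s{subject:02d}_{day}.edf"


def _hyp_path(out_dir: Path, subject: int, day: str) -> Path:
    return out_dir / f"s{subject:02d}_{day}_hypnogram.csv"


def _psd_path(out_dir: Path, subject: int, day: str) -> Path:
    return out_dir / f"s{subject:02d}_{day}_psd.csv"


def stage_simulate(config: PipelineConfig, out_dir: str | Path) -> list[Path]:
    """Synthesize baseline/stimulation recordings for every subject.

    Writes ``sNN_{baseline,stim}.edf`` plus ground-truth hypnograms
    ``sNN_{day}_truth.csv``. Only the stimulation day carries the protocol's
    evoked component; the architecture of each day is an independent draw.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for subject in range(config.n_subjects):
        for d, day in enumerate(DAYS):
            spec = config.synthetic_spec(_subject_seed(config, subject, d))
            hyp = generate_hypnogram(spec)
            protocol = config.protocol if day == "stim" else None
            rec = generate_recording(hyp, spec, protocol)
            rec.subject_id = f"s{subject:02d}"
            path = _edf_path(out_dir, subject, day)
            swio.write_edf(rec, path)
            truth = out_dir / f"s{subject:02d}_{day}_truth.csv"
            swio.write_hypnogram_csv(hyp, truth)
            written += [path, truth]
    logger.info("simulated %d subjects x %d days into %s", config.n_subjects, 2, out_dir)
    return written


def stage_score(config: PipelineConfig, out_dir: str | Path) -> list[Path]:
    """Score every recording; tabulate per-block amounts and bout statistics.

    Thresholds are calibrated per recording from its own EMG distribution.
    Writes ``sNN_{day}_hypnogram.csv`` plus the aggregated ``amounts.csv``
    and ``bouts.csv`` tables.
    """
    out_dir = Path(out_dir)
    amounts_rows, bouts_rows = [], []
    written: list[Path] = []
    for subject in range(config.n_subjects):
        for day in DAYS:
            rec = swio.read_edf(_edf_path(out_dir, subject, day))
            features = compute_epoch_features(rec, config.epoch_len_s)
            thr = calibrate_thresholds(features, config.theta_delta_ratio)
            hyp = score_features(
                features,
                thr,
                epoch_len_s=config.epoch_len_s,
                start_time_s=rec.start_time_s,
                smooth=config.smooth,
            )
            path = _hyp_path(out_dir, subject, day)
            swio.write_hypnogram_csv(hyp, path)
            written.append(path)

            amounts = state_amounts(hyp, config.block_hours, config.light_onset_zt)
            amounts.insert(0, "day", day)
            amounts.insert(0, "subject", subject)
            amounts_rows.append(amounts)

            bouts = bout_analysis(hyp).to_frame()
            bouts.insert(0, "day", day)
            bouts.insert(0, "subject", subject)
            bouts_rows.append(bouts)

    amounts_path = out_dir / "amounts.csv"
    bouts_path = out_dir / "bouts.csv"
    pd.concat(amounts_rows, ignore_index=True).to_csv(amounts_path, index=False)
    pd.concat(bouts_rows, ignore_index=True).to_csv(bouts_path, index=False)
    return written + [amounts_path, bouts_path]


def stage_spectra(config: PipelineConfig, out_dir: str | Path) -> list[Path]:
    """Per-recording state PSDs and the aggregated band-power table.

    Writes ``sNN_{day}_psd.csv`` in the tidy dialect
    ``state,freq_hz,power_pct,n_epochs`` and ``bandpower.csv`` with one row
    per subject/day/state/band.
    """
    out_dir = Path(out_dir)
    band_rows = []
    written: list[Path] = []
    window = None
    if config.psd_window_h is not None:
        window = (
            config.start_zt_h * 3600.0,
            config.start_zt_h * 3600.0 + config.psd_window_h * 3600.0,
        )
    for subject in range(config.n_subjects):
        for day in DAYS:
            rec = swio.read_edf(_edf_path(out_dir, subject, day))
            hyp = swio.read_hypnogram_csv(_hyp_path(out_dir, subject, day))
            psd = state_psd(
                rec,
                hyp,
                window=window,
                artifact_multiplier=config.artifact_multiplier,
            )
            path = _psd_path(out_dir, subject, day)
            psd.to_frame().to_csv(path, index=False)
            written.append(path)
            for state in psd.states:
                for band_name, band in ANALYSIS_BANDS.items():
                    band_rows.append(
                        {
                            "subject": subject,
                            "day": day,
                            "state": state,
                            "band": band_name,
                            "power_pct": psd.band_power(band, state),
                            "n_epochs": psd.n_epochs[state],
                        }
                    )
    band_path = out_dir / "bandpower.csv"
    pd.DataFrame(band_rows).to_csv(band_path, index=False)
    return written + [band_path]


def read_state_psd_csv(path: str | Path, fs: float = 500.0) -> StatePSD:
    """Rebuild a StatePSD from its tidy CSV export."""
    df = pd.read_csv(path)
    power, n_epochs = {}, {}
    freqs = None
    for state, grp in df.groupby("state", sort=False):
        freqs = grp["freq_hz"].to_numpy()
        power[str(state)] = grp["power_pct"].to_numpy()
        n_epochs[str(state)] = int(grp["n_epochs"].iloc[0])
    if freqs is None:
        raise ValueError(f"no spectra in {path}")
    n_fft = 4096
    df_hz = fs / n_fft
    return StatePSD(
        freqs=freqs,
        power=power,
        n_epochs=n_epochs,
        reference_value=float("nan"),
        fs=fs,
        n_fft=n_fft,
        bin_offset=int(round(freqs[0] / df_hz)),
    )


def stage_harmonics(config: PipelineConfig, out_dir: str | Path) -> list[Path]:
    """Peak/harmonic report from the subject-mean stimulation-day spectrum.

    Averages the normalized spectra of ``harmonics_state`` (default NREM)
    across subjects, detects peaks and matches them to the protocol's
    harmonic comb. Writes ``peaks.csv`` with
    ``freq_hz,power,prominence,harmonic_index`` (empty index = off-comb).
    """
    out_dir = Path(out_dir)
    state = config.harmonics_state
    spectra, freqs = [], None
    for subject in range(config.n_subjects):
        psd = read_state_psd_csv(_psd_path(out_dir, subject, "stim"), config.fs)
        if state in psd.power:
            spectra.append(psd.spectrum(state))
            freqs = psd.freqs
    if not spectra:
        raise ValueError(f"no subject has {state} epochs on the stimulation day")
    mean_spec = np.mean(spectra, axis=0)
    peaks = detect_peaks(mean_spec, freqs=freqs)
    f0 = config.protocol.frequency_hz
    df_hz = config.fs / 4096
    matched = harmonic_structure(peaks, f0, df=df_hz)
    table = peaks.peaks.copy()
    indices = []
    for f in table["freq_hz"]:
        n = int(round(f / f0))
        indices.append(n if n in matched and abs(f - n * f0) <= df_hz + 1e-12 else None)
    table["harmonic_index"] = pd.array(indices, dtype="Int64")
    path = out_dir / "peaks.csv"
    table.to_csv(path, index=False)
    return [path]


def stage_stats(config: PipelineConfig, out_dir: str | Path) -> list[Path]:
    """Paired baseline-vs-stimulation contrasts of band power across subjects.

    For each state x band: a two-tailed paired t-test on per-subject band
    powers, plus the mean ± SEM of per-subject percent changes (the
    reporting convention). Subjects missing the state on either day drop out
    pairwise. Writes ``stats.csv``.
    """
    out_dir = Path(out_dir)
    bp = pd.read_csv(out_dir / "bandpower.csv")
    rows = []
    for state in STATES:
        for band_name in ANALYSIS_BANDS:
            sel = bp[(bp["state"] == state) & (bp["band"] == band_name)]
            pivot = sel.pivot_table(
                index="subject", columns="day", values="power_pct", aggfunc="first"
            )
            for day in DAYS:
                if day not in pivot:
                    pivot[day] = np.nan
            x = pivot["baseline"].to_numpy(dtype=float)
            y = pivot["stim"].to_numpy(dtype=float)
            complete = ~(np.isnan(x) | np.isnan(y))
            changes = [
                percent_change(yi, xi) for xi, yi in zip(x[complete], y[complete])
            ]
            row = {
                "contrast": "stim_vs_baseline",
                "state": state,
                "band": band_name,
                "n": int(complete.sum()),
            }
            if complete.sum() >= 2:
                res = paired_t(x, y)
                mean_pct, sem_pct = summarize(changes)
                row |= {
                    "t": res.t_statistic,
                    "df": res.degrees_of_freedom,
                    "p": res.p_two_tailed,
                    "mean_diff_pct": mean_pct,
                    "sem_diff_pct": sem_pct,
                }
            else:
                logger.warning(
                    "stats: <2 complete pairs for %s/%s; reporting NaN", state, band_name
                )
                row |= {
                    "t": np.nan,
                    "df": np.nan,
                    "p": np.nan,
                    "mean_diff_pct": np.nan,
                    "sem_diff_pct": np.nan,
                }
            rows.append(row)
    path = out_dir / "stats.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Simulate, score, analyse and summarise in one deterministic run.

    Composes the five stages in order on a shared working directory and
    writes ``manifest.json`` recording the config hash, package versions and
    output files. Identical config + seed give byte-identical result tables.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for stage in (stage_simulate, stage_score, stage_spectra, stage_harmonics, stage_stats):
        try:
            files += stage(config, out_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage.__name__} failed: {exc}") from exc

    import scipy

    from . import __version__

    manifest = {
        "config_hash": config.config_hash(),
        "versions": {
            "slowwave": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "files": sorted(p.name for p in files),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return {"out_dir": out_dir, "files": files, "manifest": manifest_path}
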