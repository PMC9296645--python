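# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of the model documentation shipped with simulation
and statistics libraries: what is computed, under which assumptions, with
which defaults, and what the synthetic-data tests do and do not establish.

## Time and epoch conventions

Sample *i* of a recording at rate *fs* covers the interval
[i/fs, (i+1)/fs); epoch *e* of length 5 s covers samples
[e·5·fs, (e+1)·5·fs). All indices are 0-based. ZT0 is lights-on; the
light/dark cycle is fixed at 12 h : 12 h. Stimulation pulses occupy
left-closed/right-open windows [onset + k/f, onset + k/f + w): a sample
landing exactly at a pulse offset is low, which makes duty-cycle accounting
unambiguous. Pulse edges are ideal rectangles — the drive is electronic and
no rise time is modelled; the Fourier oracle assumes the same.

## Spectral estimation

Each 5-s, 2500-sample epoch is multiplied by a periodic Hanning window,
zero-padded to 4096 samples and transformed; the power spectrum is the
squared modulus of the one-sided FFT, with no 2× single-sided energy
correction (every downstream quantity is relative, so constant scale
factors cancel in the normalization; this is noted here and in the API
docs). 4096 is the only power-of-two FFT length whose bin spacing at
500 Hz, 500/4096 = 0.1220703125 Hz, equals the analysis resolution of
0.12207 Hz.

Band membership follows a bin-center rounding rule: a bin at k·Δf belongs
to a band when its center rounded to two decimals lies in the closed
interval. The conventional band edges 0.49 / 0.61 / 4.52 Hz are themselves
the rounded centers of bins 4, 5 and 37, so the stimulation band resolves
to bins 4–5 and the wide delta band to bins 4–37. Two delta bands coexist
deliberately: 0.5–4.5 Hz for scoring features and 0.49–4.52 Hz for
band-power contrasts; they serve different roles and are kept as distinct
definitions. The reported spectral grid runs from bin 4 (0.4883 Hz) to
just under 20 Hz so that the stimulation band is always covered, while the
normalization total band [0.5, 20] resolves to bins 5–163 under the same
rounding rule.

**Normalization.** For each analysis window, the reference value R is the
equal-weight mean over states (that have at least one usable epoch) of the
state's summed mean power over the total band; each bin of each state is
reported as 100·P/R. By construction the equal-weight mean of per-state
totals is 100%, which is asserted as a property test on arbitrary inputs.
R is recomputed per analysis window (e.g. a 2-h window uses a 2-h R); a
state with zero usable epochs is reported absent, never as zeros.

**Artifact rejection.** An epoch is excluded when its EEG RMS deviates from
the recording-wide mean by more than 10 × SEM, where SEM = sd/√N over all
epochs of the recording, two-sided. The metric (epoch RMS), the population
(all epochs of the recording) and the sidedness are declared
interpretations of a conventional but under-specified criterion; the
multiplier is configurable, and a non-finite multiplier disables exclusion.
With many epochs this rule is strict — 10·SEM shrinks as √N — but the
evoked component is stationary across epochs, so state-mean spectra are not
biased by the subset kept; the pipeline logs how many epochs each window
excludes so users can judge.

## Scoring

The decision tree follows criteria precedence: motor activity defines
wake, so EMG is tested first; REM requires atonia plus theta dominance
(theta/delta ratio > 2.0 by default, configurable); everything else is
NREM. An epoch with zero power in both bands is scored NREM by convention
and logged. The EMG threshold is the midpoint of the two cluster centers
from two-class 1-D k-means on the epoch EMG RMS distribution; when the
distribution does not look bimodal (cluster separation ≤ 2× the summed
within-cluster spreads, or a cluster under 1% of epochs) the calibrator
falls back to the 75th percentile and warns. Calibration requires at least
100 epochs. The original scoring this emulates was operator-assisted
commercial software with unpublished thresholds; the automatic calibration
is validated only against synthetic ground truth (≥ 90% label recovery on
the default generator, in practice ≈ 100%).

No transition smoothing is applied by default. A minimal majority smoother
(an isolated single-epoch state flanked by two agreeing neighbours is
relabelled) is available but OFF, since the emulated protocol describes no
minimum-bout filter.

Sleep-architecture tables drop a partial trailing block rather than pad
it, and artifact epochs are excluded from both numerator and denominator
of block percentages. Bouts are maximal runs of identical labels; artifact
epochs break runs and belong to no state, so per-state bout time plus
artifact time exactly partitions the recording (asserted property).

## Synthetic data

The generator defines the study conditions for all tests:

* **Architecture.** A per-epoch Markov chain over (Wake, NREM, REM) with
  separate light and dark transition matrices. Defaults give mean bout
  lengths of tens of seconds to a few minutes and stationary sleep
  fractions of ≈ 62% in the light period and ≈ 24% in the dark, the scale
  reported for laboratory mice. The chain starts in Wake at ZT0.
* **EEG.** Unit-RMS 1/f background (exponent 1.0, scale 15 µV RMS) plus
  state-gated components: NREM, narrowband noise centered at 1.5 Hz
  (±0.5 Hz, 40 µV RMS); REM, 7 Hz (±0.5 Hz, 30 µV); Wake, 10 µV broadband.
  Gates switch at epoch boundaries through a 0.1-s raised-cosine
  cross-fade — hard switches would inject broadband clicks that the
  artifact stage then flags.
* **EMG.** White noise with per-state RMS 30 / 8 / 5 µV (Wake/NREM/REM);
  the generator enforces wake > NREM ≥ REM, its separability assumption.
* **Evoked response.** A damped oscillation (5-Hz ring, 0.15-s decay — a
  generic visual-evoked-potential shape; no published waveform exists to
  copy) convolved with the protocol's **rectangular** pulse train. The
  rectangular drive was a deliberate choice over an impulse comb: it makes
  longer pulses recruit proportionally larger responses and concentrates
  comb power at the fundamental, both of which match the observed
  phenomenology (0.6-Hz peak dominant; 10-ms pulses markedly weaker than
  400-ms). The amplitude parameter is the peak response to a single
  unit-height 400-ms pulse, default 20 µV; it is a free parameter with no
  measured counterpart and is swept in tests (dose monotonicity) and set
  well above the noise floor (150 µV) where a dominant, unambiguous
  fundamental is the point of the check.
* **Determinism.** All noise comes from a seeded generator with a fixed
  draw order, so identical spec + seed give bit-identical recordings, and
  the same seed with and without a protocol differs only by the added
  evoked component.

What passing tests on this generator show: the pipeline's operations are
correct on signals with the assumed structure (separable states, stationary
within-state spectra, additive evoked response). What they do not show:
robustness to real-data pathologies — movement artifacts with complex
spectra, state transitions inside epochs, electrode drift, or
frequency-modulated theta. The artifact stage and scorer should be
re-validated against human scoring before use on animal recordings.

## Harmonic analysis

Peaks are strict local maxima at least 1% of the global maximum (the
figure-derived peaks this emulates were never quantified; 1% is the
package's choice, configurable). Harmonic n is matched when a peak lies
within ±1 bin of n·f — one bin of tolerance because the 0.6-Hz fundamental
falls between bin centers (nearest 0.6104 Hz). Oracle comparison converts
peak power to amplitude by square root and calibrates the unknown overall
scale on the fundamental, so errors at n ≥ 2 test the sinc-envelope shape;
an expected harmonic with no matching peak counts as error 1. Calibration
measurements use an unwindowed full-length DFT over an integer number of
periods, which concentrates each line in a single bin and avoids window
scalloping entirely; agreement with the closed form is within 5% for
n ≤ 5 (in practice ≤ 2%, limited by sampling quantization of the pulse
edges).

## Statistics

The paired t statistic is computed from its definition (d = y − x, sample
sd, p from the t distribution with n−1 df, two-tailed) and cross-checked
against an independent implementation in tests. Degenerate zero-spread
cases are flagged: t = ±inf with p = 0 for a non-zero mean difference,
t = 0 with p = 1 otherwise. Pairs with a missing member (e.g. a subject
with no REM epochs on one day) are dropped pairwise with a logged count,
which is why degrees of freedom vary between contrasts. No
multiple-testing correction is applied by default, matching the emulated
reporting style; a Benjamini–Hochberg helper is provided. Type-I error of
the test at α = 0.05, n = 11 is verified by simulation to be 0.05 ± 0.01
over 10,000 null experiments.

## File formats and pipeline

Signals are exchanged as classic 16-bit EDF with 1-s records and channels
labelled EEG and EMG; the package ships its own minimal reader/writer
(validated in tests against an independent EDF reader), and one line maps
proprietary telemetry exports to this interchange format: export both
channels at 500 Hz with µV physical units and those labels. Round trips
are exact to one quantization step of the stored physical range; the ZT
start time is stored at 1-s resolution, so recordings must start on a
whole second and span whole seconds. Hypnograms travel as
`epoch_index,start_s,state,artifact` CSV; PSDs as tidy
`state,freq_hz,power_pct,n_epochs`; peaks as
`freq_hz,power,prominence,harmonic_index`; statistics as
`contrast,state,band,n,t,df,p,mean_diff_pct,sem_diff_pct`.

The pipeline stages (simulate → score → spectra → harmonics → stats) each
read and write only these formats inside one working directory, and the
single-shot runner is literally their composition, so stepwise and
end-to-end runs produce identical files; a manifest records the config
hash and library versions. Configuration is one YAML mapping validated
strictly — unknown keys are rejected by name — and every stochastic stage
derives its randomness from the single config seed.

## Problem sizes

Default desk-scale conditions: 2-h recordings, 4 subjects, with 24-h runs
supported for architecture studies. The test suite uses 6-min to 2-h
recordings and the headline reproduction uses 20 min of NREM-labelled
data, sizes at which every check runs comfortably on a single CPU while
leaving the statistical properties under test unchanged.

## Known limitations

* The scorer has no manual re-scoring path and no inter-rater statistics;
  it is an automatic surrogate for operator-assisted scoring.
* The literal recording-wide 10×SEM artifact rule is aggressive for long
  clean recordings; tune the multiplier for real data.
* The evoked model is linear and state-independent, although real
  visual-evoked responses vary with vigilance state and time of day.
* Multi-taper spectral estimation, phase/coherence and cross-frequency
  coupling metrics are out of scope.
* Whether the theta-band increase seen under slow photic stimulation is
  "real" theta or harmonic leakage is a scientific interpretation the
  harmonic report can inform but not settle.
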