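# Methods

This note documents the models and numerical choices behind hfokit, what
the synthetic data does and does not emulate, and the package's known
limitations.

## Signal model and preprocessing

Recordings are channels × time matrices in microvolts with a sampling
rate ≥ 2000 Hz (rates below 1000 Hz are rejected because the fast-ripple
band would sit above Nyquist). Depth-electrode recordings are
re-referenced to an adjacent-contact bipolar montage (`A1-A2 = A1 − A2`);
shafts are inferred from the letter+number label convention or supplied
explicitly.

Slow-wave-sleep screening selects 30-s epochs whose delta-band (0.5–4 Hz)
Welch power exceeds 25% of the epoch's total power, concatenated up to
300 s. The wording "delta higher than 25%" is ambiguous between a
per-epoch fraction and a cross-epoch ranking; the per-epoch fraction is
the default because it matches standard slow-wave screening, and the
top-quartile reading is available as `mode="rank"`.

Band-pass filters are Hamming windowed-sinc FIRs applied
forward-backward (zero phase). The order is chosen for a ~10 Hz
transition width at fs = 2000 Hz (≈ 661 taps, scaling with fs), giving
≥ 40 dB stopband attenuation one transition width outside the cutoffs and
passband gain within ±5%. Segments shorter than three filter lengths are
rejected with the minimum duration in the error message.

## Baseline by maximum-distributed peak points

All local maxima of the rectified filtered signal are collected; a
Gaussian KDE locates the modal peak amplitude `a_mode` on a grid up to the
99th percentile. Peaks with amplitude ≤ c·`a_mode` are baseline peaks;
their mean and SD set the detection thresholds. The cutoff c defaults
to 3: for band-limited Gaussian noise (whose peak amplitudes are
Rayleigh-like) this keeps ~97% of noise peaks, so the baseline mean is
within a few percent of the burst-free value, while HFO peaks — which sit
at ≥ 3 SD, several multiples of the mode — remain excluded. c = 2 biased
the mean ~18% low by truncating the noise distribution itself. The
baseline stays within 10% even when 5% of the recording is occupied by
high-amplitude bursts, which is the property the modal estimate exists to
provide.

Baseline *segments* are maximal stretches ≥ 200 ms containing only
baseline peaks. They anchor the spectral baseline: the per-frequency mean
Morlet power sampled every 100 ms inside segments (capped at 100
columns). When no stretch reaches 200 ms, the amplitude statistics are
kept and only the spectral sampling falls back to the lowest-decile peak
times, with a warning — replacing the amplitude statistics too would
collapse the thresholds.

## Detection

A candidate event is a maximal run of ≥ n_low consecutive rectified peaks
above mean + k_low·SD containing a sub-run of ≥ n_high consecutive peaks
above mean + k_high·SD; its boundaries are the first and last peak of the
low run, and events closer than 10 ms are merged. Eight rectified peaks
correspond to about four oscillation cycles, the visual definition of an
HFO. Defaults are the stereo-EEG operating points (8, 3, 6, 10) for
ripples and (8, 3, 6, 9.5) for fast ripples; both are plain parameters.

`optimize_parameters` traverses a parameter grid exhaustively, evaluating
each point against visual marks by greedy largest-overlap one-to-one
matching (any positive overlap counts), and returns the highest Youden
index among points with specificity > sensitivity; ties break toward
higher specificity, then smaller n_low. Sensitivity is TP / visual marks
and specificity is 1 − FP / detections throughout.

## False-HFO classification

The Morlet family uses ≈ 6 cycles per wavelet (`mne` wavelets,
n_cycles = 6). The classifier needs only single PSD columns, so instead
of materializing frequency × time maps on the 1-Hz grid it computes inner
products of the signal with the wavelets centered at the requested times
(reflect-padded at edges); this equals the corresponding column of the
full transform and is tested against it.

The spectral grid runs 2–600 Hz in 1-Hz steps. The 2-Hz floor (rather
than 1 Hz) keeps the longest wavelet at 3 s so it fits the ±4 s window
around an event; it removes a single (f, Δf) comparison pair per f.
Offset sweeps are Δf = 1–200 Hz for ripples and 200–600 Hz for fast
ripples (a config switch widens FRs to 1–600 Hz); pairs with
f − Δf < 2 Hz are skipped. The accumulation runs f over the event's own
band. The baseline constraint compares each difference against the
baseline mean power at f (a scalar band-mean alternative is a config
switch). S accumulates the surviving differences; the verdict is false
iff S is exactly 0 — every contribution was zeroed by sign or baseline —
so the decision is deterministic and scale-equivariant (S scales linearly
with joint scaling of event and baseline power, and is invariant to
additive offsets of the PSD).

The PSD defaults to the single midpoint column; averaging columns across
the event (`psd_mode="mean"`) is available, as the event-period PSD is an
equally defensible reading.

## Synthetic data: what it emulates

* **Background**: per-channel 1/f^α Gaussian noise (default α = 1,
  SD 25 µV), plus an optional per-epoch delta-amplitude schedule for
  segment-selection tests.
* **True HFOs**: sinusoidal bursts with a Tukey (50% taper) envelope,
  amplitude expressed in units of the band-filtered background SD so the
  generator knob lines up with the detector's SD thresholds: a "12-SD,
  8-cycle" burst is exactly the kind of event the default parameters must
  find. A fully tapered (Hann) envelope would let a nominal 12-SD burst
  sustain that amplitude on almost no peak.
* **False-HFO generators**: spike-and-wave transients — a cusp with
  exponential flanks (time constant width/6, default width 30 ms)
  followed by an opposite-polarity slow wave (30% amplitude, σ = 80 ms,
  150 ms delay). The cusp's broadband tail rings in both band-pass
  filters (more strongly in the ripple band, reproducing the ripple-FR
  Gibbs asymmetry), while the raw power spectrum decreases monotonically
  with frequency — the mountain signature the classifier keys on. A
  Gaussian-derivative transient is *not* a valid false-HFO generator
  here: its power spectrum peaks near 1/(2πσ) ≈ 48 Hz, so its in-band
  power genuinely exceeds its low-frequency power and the offset
  criterion correctly reports an energy increase. Default spike amplitude
  in the performance scenarios is 2500 µV, a large interictal discharge
  at depth contacts, chosen so the ringing clears the 10-SD detection
  threshold and the classifier is actually exercised.
* **Cohorts**: per-patient channel-rate tables with resection flags
  arranged to measure a designed continuous-resection ratio exactly (up
  to the 1/n grid, default 12 channels). Default good-outcome ratios are
  1 with probability 0.55, else uniform on [0.37, 0.95] (median 1, lower
  quartile ≈ 0.67, min 0.37); poor-outcome ratios are 0 with probability
  0.3, else uniform on (0, 0.25] (median ≈ 0.09). Group labels follow the
  design, because outcome is not a deterministic function of the ratio —
  good-outcome cohorts genuinely include partial resections. Signals for
  cohort patients are generated only on request; the outcome statistics
  operate on rates.

What the generator does **not** emulate: spatially correlated activity
across channels, physiological (non-epileptic) HFOs, muscle/electrode
artifacts, non-stationary background, or realistic spike morphology
variability. Passing synthetic floors therefore demonstrates the
correctness of the chain's logic and its behavior under the stated signal
model, not clinical-grade performance on patient data.

## Outcome statistics

Per-channel true-HFO rates use events/min over the analyzed duration;
channels at or below 1/min are excluded (strict inequality). Ranking
ties break lexicographically by label for determinism; a "pessimistic"
mode orders kept channels first within a tie to lower-bound the ratio.
The EZ at threshold θ is the top ⌈θ·n⌉ ranked channels and a resection
covers it when ratio ≥ θ (boundary inclusive); θ defaults to 0.72.

Group comparison uses the two-sided Mann–Whitney U test (exact
distribution when both groups are small and tie-free, normal
approximation otherwise), quartile IQRs, and a percentile bootstrap
(10 000 resamples, seeded) for the 95% CI of each group median — the CI
construction is a package choice, as is reporting the good group's lower
CI bound as the threshold candidate. Patients with no qualifying channel
have an undefined ratio and are excluded with a warning.

## Problem sizes and determinism

The validation suites run single-threaded in minutes: the mixed detection
/classification scenario uses one 470-s channel at 2000 Hz with 100
bursts and 100 transients; oracle-equivalence checks use 100 random PSD
slices, 1000 random rankings, and exhaustive U-statistic enumeration for
group sizes ≤ 8; the cohort comparison uses 20 patients. All randomness
flows through seeded `numpy` generators; identical seeds give identical
outputs to the last bit on a given platform.

## Known limitations

* EDF is read through `mne`; the built-in writer emits minimal 16-bit
  EDF (1-s records, zero-padded tail) intended for fixtures and
  simulator output, not clinical archiving.
* The Morlet peak-frequency estimate is biased low by ~1–2% at high
  frequencies (L2-normalized wavelets with bandwidth ∝ f); irrelevant to
  the classifier, which compares power within a fixed grid.
* The detector assumes the baseline model and the filtered channel share
  provenance; feeding mismatched band/channel combinations is not
  guarded beyond the band check.
* Visual marking, sleep staging beyond the delta criterion, resection
  determination from imaging, and physiological-vs-pathological HFO
  separation are out of scope; their products (marks, flags, outcome
  classes) are inputs.
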