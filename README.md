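# hfokit

Automated analysis of high-frequency oscillations (HFOs) in intracranial
EEG, for epilepsy surgery research: detection of ripples (80–200 Hz) and
fast ripples (FRs, 200–500 Hz), removal of filtering-induced *false* HFOs,
and delineation of the epileptogenic zone (EZ) from the spatial
distribution of HFO rates.

## What it computes

**Detection.** Each channel is band-pass filtered (zero-phase FIR) and the
baseline is estimated from *maximum-distributed peak points*: the mode
`a_mode` of the rectified-peak amplitude distribution identifies the
amplitude level the channel rests at, so the baseline stays accurate even
on channels dense with HFOs. Peaks ≤ 3·`a_mode` define the baseline mean
μ and SD σ. An HFO is a run of ≥ `n_low` consecutive rectified peaks above
μ + k_low·σ containing ≥ `n_high` consecutive peaks above μ + k_high·σ.
The stereo-EEG defaults are (n_low, k_low, n_high, k_high) = (8, 3, 6, 10)
for ripples and (8, 3, 6, 9.5) for fast ripples; `optimize_parameters`
re-derives such operating points on marked data by exhaustive traversal of
the Youden index (sensitivity + specificity − 1) under the constraint
specificity > sensitivity.

**False-HFO removal.** Sharp epileptiform transients ring inside band-pass
filters (Gibbs effect) and masquerade as HFOs. On the Morlet
time-frequency map a genuine HFO is an isolated island; a filtered
transient is a mountain whose power falls monotonically with frequency.
For each event the PSD column at the event midpoint is swept with
frequency-offset power differences

    D(f, Δf) = Power(f) − Power(f − Δf),

f over the event's band in 1-Hz steps, Δf = 1–200 Hz (ripples) or
200–600 Hz (FRs). Differences that are negative or below the channel's
baseline mean power are zeroed; the rest accumulate into S = Σ D.
S = 0 ⇒ false HFO, S > 0 ⇒ true HFO.

**EZ delineation.** After false-HFO removal, channels with > 1 true
event/min are ranked by descending rate. The *continuous resection ratio
of high-order HFO channels* is

    ratio = #ChannelConRem / #ChannelHFO,

the number of channels resected consecutively from the top of the ranking
over the number of ranked channels. Good-outcome (Engel I) cohorts show
ratios near 1, poor-outcome cohorts near 0; the lower 95% CI bound of the
good group (≈ 0.72) gives the quantitative criterion: the EZ is the top
72% of the ranking, and a resection covering it predicts seizure freedom.

Because no patient recordings ship with the package, a synthetic module
generates multichannel iEEG with known ground truth — 1/f background,
windowed oscillatory bursts (true HFOs, amplitude in baseline-SD units),
cusp-shaped spike-and-wave transients (false-HFO generators) and outcome
cohorts — so every stage is testable end to end.

## Worked example

`examples/02_reject_false_hfos.py` seeds two genuine 120-Hz bursts and two
sharp transients into one minute of 1/f background, detects ripple events
and classifies them:

```
4 ripple events detected (2 bursts + 2 spikes seeded)
  10.007 s  seeded as burst -> true_hfo  (accumulated power S = 6.44e+08)
  19.953 s  seeded as spike -> false_hfo (accumulated power S = 0)
  30.007 s  seeded as burst -> true_hfo  (accumulated power S = 6.88e+08)
  39.930 s  seeded as spike -> false_hfo (accumulated power S = 0)
false-ripple fraction: 50.0%
```

All four insertions are detected (the transients ring above the 10-SD
threshold after filtering), and the accumulated offset power separates
them exactly: the bursts' spectral islands leave S > 0 while the
transients' monotone mountain spectra are zeroed out. The other examples
cover detection (`01`), channel ranking and EZ coverage (`03`), and the
outcome-group statistics with the threshold candidate (`04`).

A thin CLI wraps the same functions
(`hfokit simulate|detect|classify|rank|ez|run`).

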