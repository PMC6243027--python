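"""Synthetic intracranial EEG with known ground truth.

Emulates the signal classes the pipeline must separate: 1/f background
activity, Hann-windowed oscillatory bursts in the ripple and fast-ripple
bands (genuine HFOs), and sharp biphasic transients whose band-passed
ringing produces false HFOs.  Burst amplitudes are parameterized in units
of the band-filtered background SD so detector thresholds (3 / 10 / 9.5
SD) map directly onto generator knobs.  A cohort generator produces
per-patient channel rates, resection flags and Engel outcome labels with a
designed continuous-resection ratio, so the outcome statistics have a
known direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ez import ChannelRate, OutcomeRecord, rank_channels
from .recording import RIPPLE, FAST_RIPPLE, Recording, bandpass_filter

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "gen_background",
    "insert_burst",
    "insert_spike",
    "gen_recording",
    "gen_cohort",
    "PatientDesign",
]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic recording."""

    n_channels: int = 2
    duration: float = 60.0  # s
    fs: float = 2000.0
    alpha: float = 1.0  # 1/f^alpha background exponent
    sd_uv: float = 25.0  # broadband background SD
    seed: int = 0
    labels: list[str] | None = None
    bursts: list[tuple] = field(default_factory=list)  # (ch, t, fc, n_cycles, amp_sd)
    spikes: list[tuple] = field(default_factory=list)  # (ch, t, width_ms, amp_uv)
    delta: list[float] | None = None  # per-30s-epoch delta-band SD in uV
    epoch_length: float = 30.0

    def __post_init__(self):
        if self.labels is None:
            self.labels = [f"A{i + 1}" for i in range(self.n_channels)]


@dataclass
class GroundTruth:
    """Annotations of everything inserted into a synthetic recording."""

    events: list[dict] = field(default_factory=list)  # true oscillatory bursts
    transients: list[dict] = field(default_factory=list)  # sharp spikes

    def events_for(self, channel: str, band: str | None = None) -> list[dict]:
        return [
            e
            for e in self.events
            if e["channel"] == channel and (band is None or e["band"] == band)
        ]


def _band_of(fc: float) -> str:
    return "ripple" if fc < FAST_RIPPLE.f_low else "fast_ripple"


def gen_background(spec: SyntheticSpec) -> Recording:
    """Per-channel 1/f^alpha Gaussian background at the requested SD."""
    if spec.alpha < 0:
        raise ValueError("alpha must be non-negative")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    f = np.fft.rfftfreq(n, 1 / spec.fs)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-spec.alpha / 2)
    shaping[0] = 0.0
    samples = np.empty((spec.n_channels, n))
    for c in range(spec.n_channels):
        white = rng.standard_normal(n)
        x = np.fft.irfft(np.fft.rfft(white) * shaping, n=n)
        samples[c] = x * (spec.sd_uv / x.std())
    if spec.delta is not None:
        # slow-wave component with a per-epoch amplitude schedule
        delta_shape = ((f >= 0.5) & (f <= 4.0)).astype(float)
        spe = int(round(spec.epoch_length * spec.fs))
        env = np.ones(n)
        for i, sd in enumerate(spec.delta):
            env[i * spe : (i + 1) * spe] = sd
        for c in range(spec.n_channels):
            w = rng.standard_normal(n)
            d = np.fft.irfft(np.fft.rfft(w) * delta_shape, n=n)
            samples[c] += env * (d / d.std())
    return Recording(samples, spec.fs, list(spec.labels))


def band_sd(rec: Recording, channel: str, fc: float) -> float:
    """SD of the channel filtered into the band containing ``fc``."""
    band = RIPPLE if _band_of(fc) == "ripple" else FAST_RIPPLE
    return float(bandpass_filter(rec.channel(channel), rec.fs, band).std())


def insert_burst(
    rec: Recording,
    channel: str,
    t: float,
    fc: float,
    n_cycles: int,
    amp_sd: float,
    truth: GroundTruth | None = None,
    sd_ref: float | None = None,
) -> dict:
    """Add a windowed sinusoid; amplitude = ``amp_sd`` x band SD.

    The envelope is a Tukey (tapered-cosine, 50% taper) window so that the
    central cycles actually sustain the nominal amplitude — keeping the
    amp-in-SD-units knob aligned with the detector's SD thresholds — while
    the onset/offset stay smooth.  ``sd_ref`` may pass a pre-measured band
    SD to avoid re-filtering the background for every insertion.  Returns
    (and appends) the annotation.
    """
    if not fc < rec.fs / 2:
        raise ValueError("burst frequency above Nyquist")
    dur = n_cycles / fc
    n = int(round(dur * rec.fs))
    if n < 2:
        raise ValueError("burst too short at this sampling rate")
    i0 = int(round(t * rec.fs))
    if i0 < 0 or i0 + n > rec.samples.shape[1]:
        raise ValueError("burst does not fit in the recording")
    sd = sd_ref if sd_ref is not None else band_sd(rec, channel, fc)
    from scipy.signal import windows

    tt = np.arange(n) / rec.fs
    wave = amp_sd * sd * windows.tukey(n, 0.5) * np.sin(2 * np.pi * fc * tt)
    rec.samples[rec.labels.index(channel), i0 : i0 + n] += wave
    ann = {
        "channel": channel,
        "band": _band_of(fc),
        "start": t,
        "end": t + dur,
        "fc": fc,
        "n_cycles": n_cycles,
        "amp_sd": amp_sd,
        "kind": "burst",
    }
    if truth is not None:
        if any(
            e["channel"] == channel and e["start"] < ann["end"] and ann["start"] < e["end"]
            for e in truth.events
        ):
            warnings.warn("burst overlaps an existing annotation")
        truth.events.append(ann)
    return ann


def insert_spike(
    rec: Recording,
    channel: str,
    t: float,
    width_ms: float = 30.0,
    amp_uv: float = 800.0,
    wave_frac: float = 0.3,
    truth: GroundTruth | None = None,
) -> dict:
    """Add a sharp epileptiform transient (no sustained oscillation).

    The waveform is the classic spike-and-wave: a cusp with exponential
    flanks (time constant ``width_ms / 6``) followed by an opposite-polarity
    slow wave of ``wave_frac`` relative amplitude.  The cusp's broadband
    tail rings in the band-pass filters — more in the ripple than the
    fast-ripple band — producing detectable false HFOs, while the raw power
    spectrum stays monotone decreasing (the "mountain" signature).
    """
    tau = width_ms / 1000.0 / 6.0
    half = int(round(0.45 * rec.fs))
    i0 = int(round(t * rec.fs))
    if i0 - half < 0 or i0 + half >= rec.samples.shape[1]:
        raise ValueError("spike does not fit in the recording")
    tt = (np.arange(-half, half + 1)) / rec.fs
    g = amp_uv * np.exp(-np.abs(tt) / tau)
    g -= wave_frac * amp_uv * np.exp(-((tt - 0.15) ** 2) / (2 * 0.08**2))
    rec.samples[rec.labels.index(channel), i0 - half : i0 + half + 1] += g
    ann = {
        "channel": channel,
        "start": t - 0.1,  # extent of the sharp component's ringing
        "end": t + 0.1,
        "width_ms": width_ms,
        "amp_uv": amp_uv,
        "kind": "spike",
    }
    if truth is not None:
        truth.transients.append(ann)
    return ann


def gen_recording(spec: SyntheticSpec) -> tuple[Recording, GroundTruth]:
    """Background plus every burst and spike listed in the spec."""
    rec = gen_background(spec)
    truth = GroundTruth()
    sd_cache: dict[tuple[str, str], float] = {}
    for ch, t, fc, n_cycles, amp_sd in spec.bursts:
        key = (ch, _band_of(fc))
        if key not in sd_cache:
            sd_cache[key] = band_sd(rec, ch, fc)
        insert_burst(rec, ch, t, fc, n_cycles, amp_sd, truth, sd_ref=sd_cache[key])
    for ch, t, width_ms, amp_uv in spec.spikes:
        insert_spike(rec, ch, t, width_ms, amp_uv, truth=truth)
    return rec, truth


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class PatientDesign:
    """Designed resection ratio and channel count for one synthetic patient."""

    patient: str
    designed_ratio: float  # in [0, 1]
    n_channels: int = 12


def gen_cohort(
    designs: list[PatientDesign] | None = None,
    n_good: int = 10,
    n_poor: int = 10,
    seed: int = 0,
    band: str = "fast_ripple",
) -> tuple[list[OutcomeRecord], dict[str, list[ChannelRate]]]:
    """Synthetic patients with designed continuous-resection ratios.

    Default designs emulate the outcome-group distributions seen in
    fast-ripple cohorts: good-outcome (Engel I) patients have a complete
    resection of the top-ranked channels more often than not (ratio 1 with
    probability 0.55, else in [0.37, 0.95]; group median 1, lower quartile
    ~0.67), poor-outcome (Engel II-IV) patients rarely cover the top of the
    ranking (ratio 0 with probability 0.3, else in (0, 0.25]; group median
    ~0.1).  The distributions overlap below 0.72, as real cohorts do; the
    group membership is part of the design, so the statistics have a known
    direction.  Rates are descending, all above 1/min, with resection flags
    arranged so that ``rank_channels`` measures exactly the designed ratio
    (up to the 1/n_channels grid).  Returns the outcome records (with
    measured ratios) and each patient's channel-rate table.
    """
    rng = np.random.default_rng(seed)
    groups = None
    if designs is None:
        good_r = np.where(
            rng.random(n_good) < 0.55, 1.0, rng.uniform(0.37, 0.95, size=n_good)
        )
        poor_r = np.where(
            rng.random(n_poor) < 0.3, 0.0, rng.uniform(0.02, 0.25, size=n_poor)
        )
        designs = [
            PatientDesign(f"P{i + 1:02d}", float(r)) for i, r in enumerate(good_r)
        ] + [
            PatientDesign(f"P{i + n_good + 1:02d}", float(r))
            for i, r in enumerate(poor_r)
        ]
        groups = ["good"] * n_good + ["poor"] * n_poor
    records: list[OutcomeRecord] = []
    tables: dict[str, list[ChannelRate]] = {}
    for j, d in enumerate(designs):
        if d.n_channels < 2:
            raise ValueError("each patient needs at least 2 channels")
        n = d.n_channels
        k = int(round(d.designed_ratio * n))  # continuously removed from the top
        rates = np.sort(rng.uniform(1.1, 30.0, size=n))[::-1]
        removed = np.zeros(n, dtype=bool)
        removed[:k] = True
        if k < n:
            removed[k] = False  # the first kept channel
            removed[k + 1 :] = rng.random(n - k - 1) < 0.3
        chans = [
            ChannelRate(f"{d.patient}-C{i + 1}", band, float(rates[i]), bool(removed[i]))
            for i in range(n)
        ]
        measured = rank_channels(chans).ratio
        # explicit designs fall back to the threshold rule for the label
        good = groups[j] == "good" if groups is not None else measured >= 0.72
        engel = 1 if good else int(rng.integers(2, 5))
        records.append(OutcomeRecord(d.patient, engel, {band: measured}))
        tables[d.patient] = chans
    return records, tables
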