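"""False-HFO rejection from Morlet spectra.

Band-pass filtering turns sharp epileptiform transients into ringing that
mimics an HFO (Gibbs effect).  On a Morlet time-frequency map a genuine
oscillation is an isolated island of power; a filtered transient is a
"mountain" whose power falls monotonically with frequency.  The classifier
takes the power-spectral-density column at the event's midpoint and
accumulates frequency-offset power differences

    D(f, df) = Power(f) - Power(f - df)

over the event's band (f) and an offset sweep (df), zeroing every
difference that is negative or below the channel's baseline mean power at
f.  A genuine oscillation leaves a positive accumulated power S; a pure
filtering artifact leaves S = 0 and is discarded as a false HFO.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import BaselineModel, HFOEvent
from .recording import BandDefinition, BANDS

__all__ = [
    "SpectralMap",
    "PSDSlice",
    "OffsetParams",
    "default_freqs",
    "morlet_spectrum",
    "psd_at_times",
    "psd_slice",
    "offset_power_difference",
    "classify_event",
    "remove_false",
]

N_CYCLES = 6.0  # Morlet width; ~omega0 = 6 cycles per wavelet

#: Default analysis grid: 1-Hz steps, 2-600 Hz.  The 2-Hz floor keeps the
#: longest wavelet (6 cycles) at 3 s so it fits the +-4 s event window.
F_MIN, F_MAX = 2.0, 600.0


def default_freqs(f_min: float = F_MIN, f_max: float = F_MAX) -> np.ndarray:
    return np.arange(f_min, f_max + 0.5, 1.0)


@dataclass
class SpectralMap:
    power: np.ndarray  # frequency x time, >= 0
    freqs: np.ndarray  # 1-Hz grid
    times: np.ndarray  # s


@dataclass
class PSDSlice:
    power: np.ndarray  # per-frequency power at one time point
    freqs: np.ndarray


@dataclass(frozen=True)
class OffsetParams:
    """Sweep ranges for the frequency-offset power difference.

    ``df_range`` maps band name to the inclusive offset sweep in Hz
    (ripples 1-200, fast ripples 200-600); ``f_floor`` is the lowest
    admissible ``f - df``.  ``wide_df`` switches fast ripples to the full
    1-600 Hz offset sweep.
    """

    df_range: dict = field(
        default_factory=lambda: {"ripple": (1, 200), "fast_ripple": (200, 600)}
    )
    f_floor: float = F_MIN
    wide_df: bool = False

    def df_for(self, band_name: str) -> tuple[int, int]:
        if self.wide_df:
            return (1, 600)
        return self.df_range[band_name]


# ---------------------------------------------------------------------------
# Morlet transforms


def morlet_spectrum(
    raw: np.ndarray, fs: float, freqs: np.ndarray | None = None
) -> SpectralMap:
    """Morlet wavelet power map of a raw (unfiltered) channel."""
    import mne

    if freqs is None:
        freqs = default_freqs(f_max=min(F_MAX, fs / 2 - 1))
    freqs = np.asarray(freqs, dtype=float)
    if fs < 2 * freqs.max():
        raise ValueError(f"fs={fs:g} too low for frequencies up to {freqs.max():g} Hz")
    raw = np.asarray(raw, dtype=float)
    power = mne.time_frequency.tfr_array_morlet(
        raw[None, None, :], sfreq=fs, freqs=freqs, n_cycles=N_CYCLES,
        output="power", verbose="error",
    )[0, 0]
    times = np.arange(raw.size) / fs
    return SpectralMap(power, freqs, times)


def psd_at_times(
    raw: np.ndarray, fs: float, freqs: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Morlet power columns at selected time points (frequency x time).

    Computes, per frequency, the inner product of the signal with the mne
    Morlet wavelet centered at each requested time — the same quantity as
    the corresponding column of the full transform, without materializing
    the whole map.  Signal edges are reflect-padded.
    """
    import mne

    raw = np.asarray(raw, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if fs < 2 * freqs.max():
        raise ValueError(f"fs={fs:g} too low for frequencies up to {freqs.max():g} Hz")
    wavelets = mne.time_frequency.morlet(fs, freqs, n_cycles=N_CYCLES)
    centers = np.round(times * fs).astype(int)
    if centers.min() < 0 or centers.max() >= raw.size:
        raise ValueError("requested time outside the signal")
    max_half = max(len(w) // 2 for w in wavelets)
    pad = min(max_half, raw.size - 1)
    padded = np.pad(raw, pad, mode="reflect")
    power = np.empty((len(freqs), len(times)))
    for k, w in enumerate(wavelets):
        half = len(w) // 2
        offsets = np.arange(len(w)) - half
        if half > pad:  # wavelet outlives even the padded signal
            w = w[half - pad : half + pad + 1]
            offsets = np.arange(len(w)) - pad
        idx = (centers + pad)[:, None] + offsets[None, :]
        segs = padded[idx]
        coef = segs @ np.conj(w[::-1])
        power[k] = np.abs(coef) ** 2
    return power


def psd_slice(smap: SpectralMap, event: HFOEvent) -> PSDSlice:
    """PSD column at the event midpoint (nearest sample, ties to earlier)."""
    mid = event.midpoint
    if not (smap.times[0] <= mid <= smap.times[-1]):
        raise ValueError("event midpoint outside the spectral map")
    j = int(np.searchsorted(smap.times, mid))
    if j == 0:
        i = 0
    elif j >= len(smap.times):
        i = len(smap.times) - 1
    else:
        d_left = mid - smap.times[j - 1]
        d_right = smap.times[j] - mid
        i = j - 1 if d_left <= d_right + 1e-9 else j  # ties go to the earlier sample
    return PSDSlice(smap.power[:, i].copy(), smap.freqs)


# ---------------------------------------------------------------------------
# Frequency-offset power difference


def offset_power_difference(
    sl: PSDSlice,
    base: BaselineModel,
    params: OffsetParams,
    band: BandDefinition,
) -> float:
    """Accumulated frequency-offset power difference S over the event band.

    For each integer f in [band.f_low, band.f_high] and df in the band's
    sweep with f - df >= f_floor:  D = P(f) - P(f - df); D is zeroed where
    negative or below the baseline mean power at f; S is the sum of what
    remains.  S = 0 is the false-HFO signature.
    """
    if base.mean_power is None:
        raise ValueError("baseline model lacks mean_power; estimate with raw signal")
    freqs = np.asarray(sl.freqs)
    if base.freqs is None or len(base.freqs) != len(freqs) or not np.allclose(
        base.freqs, freqs
    ):
        raise ValueError("slice and baseline frequency grids differ")
    df_lo, df_hi = params.df_for(band.name)
    f_vals = freqs[(freqs >= band.f_low) & (freqs <= band.f_high)]
    df_vals = np.arange(df_lo, df_hi + 1)
    # map frequency value -> grid index (1-Hz grid)
    f0 = freqs[0]
    fi = np.round(f_vals - f0).astype(int)
    tgt = f_vals[:, None] - df_vals[None, :]  # f - df
    valid = tgt >= params.f_floor
    if not valid.any():
        raise ValueError(
            f"no valid (f, df) pair for band {band.name} with offsets "
            f"{df_lo}-{df_hi} Hz and f_floor={params.f_floor:g} Hz"
        )
    ti = np.round(tgt - f0).astype(int)
    ti[~valid] = 0
    D = sl.power[fi][:, None] - sl.power[ti]
    D[~valid] = 0.0
    D[D < 0] = 0.0
    D[D < base.mean_power[fi][:, None]] = 0.0
    return float(D.sum())


def classify_event(
    event: HFOEvent,
    raw: np.ndarray,
    fs: float,
    base: BaselineModel,
    params: OffsetParams | None = None,
    freqs: np.ndarray | None = None,
    psd_mode: str = "midpoint",
) -> str:
    """Label one detected event true or false by its accumulated power.

    ``psd_mode="midpoint"`` uses the single PSD column at the event middle;
    ``"mean"`` averages columns over the event duration.
    """
    if params is None:
        params = OffsetParams()
    if freqs is None:
        freqs = base.freqs if base.freqs is not None else default_freqs()
    band = BANDS[event.band]
    if psd_mode == "midpoint":
        times = np.array([min(event.midpoint, (len(raw) - 1) / fs)])
    elif psd_mode == "mean":
        times = np.linspace(event.start, min(event.end, (len(raw) - 1) / fs), 5)
    else:
        raise ValueError(f"unknown psd_mode {psd_mode!r}")
    power = psd_at_times(raw, fs, freqs, times).mean(axis=1)
    s = offset_power_difference(PSDSlice(power, freqs), base, params, band)
    event.accumulated_power = s
    event.verdict = "false_hfo" if s == 0.0 else "true_hfo"
    return event.verdict


def remove_false(
    events: list[HFOEvent],
    raw_by_channel: dict[str, np.ndarray],
    fs: float,
    bases: dict[str, BaselineModel],
    params: OffsetParams | None = None,
    freqs: np.ndarray | None = None,
) -> tuple[list[HFOEvent], list[HFOEvent], dict[str, float]]:
    """Partition events into true/false; report the false percentage per band.

    ``bases`` maps ``(channel)`` or ``(channel, band)`` keys to baseline
    models; the raw (unfiltered) signal of each event's channel is required.
    """
    true_ev: list[HFOEvent] = []
    false_ev: list[HFOEvent] = []
    for ev in events:
        if ev.channel not in raw_by_channel:
            raise KeyError(f"no raw signal for channel {ev.channel!r}")
        base = bases.get((ev.channel, ev.band), bases.get(ev.channel))
        if base is None:
            raise KeyError(f"no baseline model for channel {ev.channel!r}")
        v = classify_event(ev, raw_by_channel[ev.channel], fs, base, params, freqs)
        (false_ev if v == "false_hfo" else true_ev).append(ev)
    fractions: dict[str, float] = {}
    for band in {e.band for e in events}:
        n_all = sum(1 for e in events if e.band == band)
        n_false = sum(1 for e in false_ev if e.band == band)
        fractions[band] = 100.0 * n_false / n_all if n_all else np.nan
    return true_ev, false_ev, fractions


def false_fraction(n_false: int, n_detected: int) -> float:
    """Percentage of detections classified false."""
    if n_detected <= 0:
        return float("nan")
    return 100.0 * n_false / n_detected
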