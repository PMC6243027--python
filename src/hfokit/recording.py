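"""Recordings, montage, slow-wave segment selection and band-pass filtering.

A :class:`Recording` holds a channels-x-time matrix in microvolts together
with its sampling rate and channel labels.  Intracranial EEG enters either
as EDF (read through :mod:`mne`) or as a delimited text matrix with a JSON
sidecar.  Depth-electrode recordings are re-referenced to a bipolar montage
of adjacent contacts before analysis; 30-s epochs dominated by delta-band
power are selected to approximate slow-wave sleep; and each analysis band
(ripples 80-200 Hz, fast ripples 200-500 Hz) is isolated with a zero-phase
FIR filter.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "RIPPLE",
    "FAST_RIPPLE",
    "Recording",
    "SegmentSelection",
    "read_recording",
    "write_recording",
    "to_bipolar",
    "select_segments",
    "bandpass",
    "bandpass_filter",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named analysis band with corner frequencies in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self):
        if not self.f_low < self.f_high:
            raise ValueError("f_low must be below f_high")

    def contains(self, f: float) -> bool:
        return self.f_low <= f <= self.f_high


RIPPLE = BandDefinition("ripple", 80.0, 200.0)
FAST_RIPPLE = BandDefinition("fast_ripple", 200.0, 500.0)

BANDS = {b.name: b for b in (RIPPLE, FAST_RIPPLE)}


@dataclass
class Recording:
    """Multichannel iEEG: ``samples`` in microvolts, channels x time."""

    samples: np.ndarray
    fs: float
    labels: list[str]
    montage: str = "monopolar"
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("labels must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def copy(self) -> "Recording":
        return replace(self, samples=self.samples.copy(), labels=list(self.labels))


@dataclass
class SegmentSelection:
    """Epochs passing the delta-dominance criterion, in seconds."""

    epochs: list[tuple[float, float]]
    epoch_length: float
    delta_fraction: np.ndarray
    threshold: float
    target_duration: float

    @property
    def total_duration(self) -> float:
        return sum(e - s for s, e in self.epochs)


# ---------------------------------------------------------------------------
# I/O

_MIN_FS = 1000.0  # below this the fast-ripple band cannot be analyzed


def read_recording(path, format: str | None = None) -> Recording:
    """Read an EDF file or a text matrix (+ JSON sidecar) into microvolts.

    ``format`` is ``"edf"`` or ``"matrix"``; inferred from the suffix when
    omitted.  Rejects sampling rates below 1000 Hz.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        fs = float(raw.info["sfreq"])
        samples = raw.get_data() * 1e6  # mne returns volts
        labels = list(raw.ch_names)
    elif format == "matrix":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"matrix format requires sidecar {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        samples = np.loadtxt(path, delimiter="\t", ndmin=2).T  # file is time x ch
        fs = float(meta["fs"])
        labels = list(meta["labels"])
        scale = {"uV": 1.0, "mV": 1e3, "V": 1e6}.get(meta.get("unit", "uV"))
        if scale is None:
            raise ValueError(f"unresolvable unit {meta.get('unit')!r}")
        samples = samples * scale
    else:
        raise ValueError(f"unknown format {format!r}")
    if fs < _MIN_FS:
        raise ValueError(
            f"sampling rate {fs:g} Hz < {_MIN_FS:g} Hz: fast-ripple band unanalyzable"
        )
    return Recording(samples, fs, labels, montage=meta.get("montage", "monopolar") if format == "matrix" else "monopolar")


def write_recording(rec: Recording, path, format: str | None = None) -> None:
    """Write to EDF or a tab-delimited matrix (time x channels) + sidecar."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        from ._edf import write_edf

        write_edf(path, rec.samples, rec.fs, rec.labels)
    elif format == "matrix":
        np.savetxt(path, rec.samples.T, delimiter="\t", fmt="%.6f")
        meta = {"fs": rec.fs, "labels": rec.labels, "unit": "uV", "montage": rec.montage}
        path.with_suffix(".json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Bipolar montage

_LABEL_RE = re.compile(r"^([A-Za-z']+)(\d+)$")


def infer_shafts(labels: list[str]) -> dict[str, list[str]]:
    """Group contact labels like A1, A2, B1... into per-shaft ordered lists."""
    shafts: dict[str, list[tuple[int, str]]] = {}
    for lb in labels:
        m = _LABEL_RE.match(lb)
        if not m:
            raise ValueError(f"cannot parse contact label {lb!r}; pass shaft_map")
        shafts.setdefault(m.group(1), []).append((int(m.group(2)), lb))
    return {k: [lb for _, lb in sorted(v)] for k, v in sorted(shafts.items())}


def to_bipolar(rec: Recording, shaft_map: dict[str, list[str]] | None = None) -> Recording:
    """Re-reference to adjacent-contact differences within each shaft.

    Output channel ``A1-A2`` is ``A1 - A2``.  Shafts with a single contact
    are skipped with a warning; labels absent from the recording raise.
    """
    if rec.montage != "monopolar":
        raise ValueError("recording is already bipolar")
    if shaft_map is None:
        shaft_map = infer_shafts(rec.labels)
    rows, labels = [], []
    for shaft, contacts in shaft_map.items():
        for lb in contacts:
            if lb not in rec.labels:
                raise KeyError(f"shaft {shaft}: unknown contact label {lb!r}")
        if len(contacts) < 2:
            warnings.warn(f"shaft {shaft!r} has a single contact; skipped")
            continue
        for a, b in zip(contacts[:-1], contacts[1:]):
            rows.append(rec.channel(a) - rec.channel(b))
            labels.append(f"{a}-{b}")
    return Recording(np.array(rows), rec.fs, labels, montage="bipolar", t0=rec.t0)


# ---------------------------------------------------------------------------
# Delta-dominance segment selection

DELTA_BAND = (0.5, 4.0)


def select_segments(
    rec: Recording,
    epoch_length: float = 30.0,
    threshold: float = 0.25,
    target_duration: float = 300.0,
    mode: str = "fraction",
) -> SegmentSelection:
    """Pick 30-s epochs whose delta-band power share exceeds ``threshold``.

    Per epoch the Welch power in 0.5-4 Hz is divided by the total power
    (averaged over channels); epochs above the threshold are taken in time
    order up to ``target_duration`` seconds.  ``mode="rank"`` instead keeps
    the top quartile of epochs by delta fraction.
    """
    n_ep = int(rec.duration // epoch_length)
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")
    spe = int(round(epoch_length * rec.fs))
    nper = min(spe, int(4 * rec.fs))
    fracs = np.empty(n_ep)
    for i in range(n_ep):
        seg = rec.samples[:, i * spe : (i + 1) * spe]
        f, pxx = sps.welch(seg, fs=rec.fs, nperseg=nper, axis=1)
        keep = f >= DELTA_BAND[0]
        delta = f[keep] <= DELTA_BAND[1]
        tot = pxx[:, keep].sum(axis=1)
        num = pxx[:, keep][:, delta].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fracs[i] = np.nanmean(np.where(tot > 0, num / tot, 0.0))
    if mode == "fraction":
        qualifying = np.flatnonzero(fracs > threshold)
    elif mode == "rank":
        qualifying = np.flatnonzero(fracs >= np.quantile(fracs, 0.75))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    epochs: list[tuple[float, float]] = []
    total = 0.0
    for i in qualifying:
        if total >= target_duration:
            break
        epochs.append((i * epoch_length, (i + 1) * epoch_length))
        total += epoch_length
    if not epochs:
        warnings.warn("no epoch passed the delta-dominance criterion")
    return SegmentSelection(epochs, epoch_length, fracs, threshold, target_duration)


# ---------------------------------------------------------------------------
# Zero-phase FIR band-pass

_TRANSITION_HZ = 10.0  # at fs = 2000; scales with fs


def _design_fir(fs: float, band: BandDefinition) -> np.ndarray:
    # Hamming windowed-sinc; transition width ~3.3/N of fs
    width = _TRANSITION_HZ * fs / 2000.0
    numtaps = int(np.ceil(3.3 * fs / width)) | 1
    return sps.firwin(
        numtaps, [band.f_low, band.f_high], pass_zero=False, fs=fs, window="hamming"
    )


def bandpass_filter(x: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Forward-backward (zero-phase) FIR band-pass of a 1-D or 2-D signal."""
    if fs <= 2 * band.f_high:
        raise ValueError(f"fs={fs:g} too low for band up to {band.f_high:g} Hz")
    taps = _design_fir(fs, band)
    n = np.atleast_2d(x).shape[1]
    min_len = 3 * len(taps)
    if n < min_len:
        raise ValueError(
            f"segment of {n} samples too short to filter; need >= {min_len} "
            f"samples ({min_len / fs:.2f} s at fs={fs:g})"
        )
    return sps.filtfilt(taps, [1.0], x, axis=-1)


def bandpass(rec: Recording, band: BandDefinition) -> Recording:
    """Band-pass every channel of a recording; returns a new Recording."""
    out = rec.copy()
    out.samples = bandpass_filter(rec.samples, rec.fs, band)
    return out
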