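"""HFO detection by consecutive-peak amplitude thresholds.

The detector works on the band-passed signal of one channel.  The baseline
is estimated from the *maximum-distributed* peak amplitudes: the mode of
the rectified-peak amplitude distribution marks the amplitude level most of
the channel spends at, which stays put even when the channel is dense with
HFOs (unlike whole-segment RMS baselines).  Peaks up to twice the modal
amplitude are treated as baseline peaks; their mean and SD set the two
detection thresholds.

An event requires ``n_low`` consecutive rectified peaks above
``mean + k_low * SD`` containing at least ``n_high`` consecutive peaks above
``mean + k_high * SD``.  The defaults are the stereo-EEG optimized values:
8 peaks at 3 SD with 6 peaks at 10 SD for ripples, and 8 at 3 SD with 6 at
9.5 SD for fast ripples.  Eight rectified peaks correspond to roughly four
oscillation cycles, matching the visual definition of an HFO.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spst

from .recording import RIPPLE, FAST_RIPPLE, BandDefinition

__all__ = [
    "BaselineModel",
    "DetectionParams",
    "HFOEvent",
    "EvaluationResult",
    "Pairing",
    "find_peaks",
    "estimate_baseline",
    "detect_hfos",
    "match_events",
    "evaluate",
    "optimize_parameters",
    "DEFAULT_PARAMS",
]


@dataclass
class BaselineModel:
    """Baseline peak-amplitude statistics and baseline spectral power."""

    channel: str
    band: BandDefinition
    mean_amp: float  # uV, mean baseline rectified-peak amplitude
    sd_amp: float  # uV
    segments: list[tuple[float, float]]  # >= 200 ms stretches without HF activity
    mean_power: np.ndarray | None = None  # baseline Morlet power per frequency
    freqs: np.ndarray | None = None  # 1-Hz grid matching mean_power


@dataclass(frozen=True)
class DetectionParams:
    """Consecutive-peak thresholds for one band."""

    n_low: int
    k_low: float
    n_high: int
    k_high: float
    merge_gap: float = 0.010  # s
    band: BandDefinition = RIPPLE

    def __post_init__(self):
        if self.n_high > self.n_low:
            raise ValueError("n_high must not exceed n_low")
        if self.k_low >= self.k_high:
            raise ValueError("k_low must be below k_high")


DEFAULT_PARAMS = {
    "ripple": DetectionParams(8, 3.0, 6, 10.0, band=RIPPLE),
    "fast_ripple": DetectionParams(8, 3.0, 6, 9.5, band=FAST_RIPPLE),
}


@dataclass
class HFOEvent:
    channel: str
    band: str
    start: float
    end: float
    peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_amps: np.ndarray = field(default_factory=lambda: np.empty(0))
    verdict: str = "unclassified"  # true_hfo | false_hfo | unclassified
    accumulated_power: float = np.nan

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlap(self, other: "HFOEvent") -> float:
        return max(0.0, min(self.end, other.end) - max(self.start, other.start))


# ---------------------------------------------------------------------------


def find_peaks(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima of the rectified signal.

    Returns (times in s, amplitudes in uV).  Plateaus contribute their
    center sample; a constant signal has no peaks.
    """
    r = np.abs(np.asarray(x, dtype=float))
    idx, props = sps.find_peaks(r, plateau_size=1)
    if len(idx) and "left_edges" in props:
        idx = (props["left_edges"] + props["right_edges"]) // 2
    return idx / fs, r[idx]


def estimate_baseline(
    filtered: np.ndarray,
    fs: float,
    band: BandDefinition,
    channel: str = "",
    raw: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    mode_cutoff: float = 3.0,
    min_segment: float = 0.2,
) -> BaselineModel:
    """Estimate the baseline from maximum-distributed peak points.

    The modal rectified-peak amplitude ``a_mode`` is located with a Gaussian
    KDE; peaks with amplitude <= ``mode_cutoff * a_mode`` are baseline
    peaks, whose mean/SD set detection thresholds.  Maximal stretches of at
    least ``min_segment`` seconds containing only baseline peaks become
    baseline segments; when ``raw`` is supplied, the mean Morlet power per
    frequency over those segments is stored for the false-HFO constraint.
    """
    if len(filtered) < 10 * fs:
        raise ValueError("need at least 10 s of filtered signal")
    times, amps = find_peaks(filtered, fs)
    if len(amps) < 50:
        raise ValueError(f"only {len(amps)} peaks; too few to model a baseline")

    grid = np.linspace(0, np.percentile(amps, 99), 512)
    kde = spst.gaussian_kde(amps)
    a_mode = grid[np.argmax(kde(grid))]
    cutoff = mode_cutoff * a_mode
    base_mask = amps <= cutoff
    if base_mask.sum() < 10:  # degenerate mode estimate
        base_mask = amps <= np.quantile(amps, 0.5)
    mean_amp = float(amps[base_mask].mean())
    sd_amp = float(amps[base_mask].std(ddof=1))

    duration = len(filtered) / fs
    offend = times[~base_mask]
    bounds = np.concatenate([[0.0], offend, [duration]])
    segments = [
        (float(a), float(b))
        for a, b in zip(bounds[:-1], bounds[1:])
        if b - a >= min_segment
    ]
    low_decile_times = None
    if not segments:
        # thresholds keep the modal-peak statistics; only the spectral
        # baseline sampling falls back to the quietest peaks
        warnings.warn(
            "no baseline segment >= 200 ms; sampling baseline power at "
            "lowest-decile peaks"
        )
        low_decile_times = times[amps <= np.quantile(amps, 0.1)]

    mean_power = None
    if raw is not None:
        from .spectral import default_freqs, psd_at_times

        if freqs is None:
            freqs = default_freqs()
        if low_decile_times is not None:
            sample_times = low_decile_times
            if len(sample_times) > 100:
                sample_times = sample_times[
                    np.linspace(0, len(sample_times) - 1, 100).astype(int)
                ]
        else:
            sample_times = _baseline_sample_times(segments, duration, fs)
        power = psd_at_times(raw, fs, freqs, sample_times)
        mean_power = power.mean(axis=1)
    return BaselineModel(channel, band, mean_amp, sd_amp, segments, mean_power, freqs)


def _baseline_sample_times(
    segments: list[tuple[float, float]],
    duration: float,
    fs: float,
    spacing: float = 0.1,
    max_samples: int = 100,
) -> np.ndarray:
    if segments:
        pts = np.concatenate(
            [np.arange(a + spacing / 2, b, spacing) for a, b in segments]
        )
    else:
        pts = np.arange(spacing, duration - spacing, spacing)
    if len(pts) > max_samples:
        pts = pts[np.linspace(0, len(pts) - 1, max_samples).astype(int)]
    return pts


def detect_hfos(
    filtered: np.ndarray,
    fs: float,
    base: BaselineModel,
    params: DetectionParams,
    channel: str | None = None,
) -> list[HFOEvent]:
    """Detect events as runs of consecutive supra-threshold rectified peaks.

    A candidate is a maximal run of >= ``n_low`` consecutive peaks above the
    low threshold containing >= ``n_high`` consecutive peaks above the high
    threshold; its boundaries are the first and last peak of the low run.
    Events separated by less than ``merge_gap`` are merged.
    """
    channel = channel if channel is not None else base.channel
    times, amps = find_peaks(filtered, fs)
    thr_low = base.mean_amp + params.k_low * base.sd_amp
    thr_high = base.mean_amp + params.k_high * base.sd_amp
    above_low = amps > thr_low
    events: list[HFOEvent] = []
    for run_start, run_len in _runs(above_low):
        if run_len < params.n_low:
            continue
        hi = amps[run_start : run_start + run_len] > thr_high
        if max((l for _, l in _runs(hi)), default=0) < params.n_high:
            continue
        sl = slice(run_start, run_start + run_len)
        events.append(
            HFOEvent(
                channel=channel,
                band=params.band.name,
                start=float(times[sl][0]),
                end=float(times[sl][-1]),
                peak_times=times[sl].copy(),
                peak_amps=amps[sl].copy(),
            )
        )
    return _merge_events(events, params.merge_gap)


def _runs(mask: np.ndarray):
    """Yield (start_index, length) of maximal runs of True."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    for a, b in zip(edges[::2], edges[1::2]):
        yield int(a), int(b - a)


def _merge_events(events: list[HFOEvent], gap: float) -> list[HFOEvent]:
    events = sorted(events, key=lambda e: e.start)
    merged: list[HFOEvent] = []
    for ev in events:
        if merged and ev.start - merged[-1].end < gap:
            prev = merged[-1]
            prev.end = max(prev.end, ev.end)
            prev.peak_times = np.concatenate([prev.peak_times, ev.peak_times])
            prev.peak_amps = np.concatenate([prev.peak_amps, ev.peak_amps])
        else:
            merged.append(ev)
    return merged


# ---------------------------------------------------------------------------
# Evaluation against visual marks


@dataclass
class Pairing:
    matches: list[tuple[int, int]]  # (detected index, visual index)
    unmatched_detected: list[int]
    unmatched_visual: list[int]

    @property
    def tp(self) -> int:
        return len(self.matches)

    @property
    def fp(self) -> int:
        return len(self.unmatched_detected)

    @property
    def fn(self) -> int:
        return len(self.unmatched_visual)


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    youden: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvaluationResult":
        """sensitivity = TP / visual marks; specificity = 1 - FP / detections."""
        n_visual = tp + fn
        n_det = tp + fp
        if n_visual == 0:
            warnings.warn("no visual marks: sensitivity undefined")
            sens = np.nan
        else:
            sens = tp / n_visual
        spec = 1.0 - fp / n_det if n_det > 0 else np.nan
        return cls(tp, fp, fn, sens, spec, sens + spec - 1.0)


def match_events(
    detected: list[HFOEvent], visual: list[HFOEvent]
) -> Pairing:
    """Greedy one-to-one matching by temporal overlap, largest overlap first."""
    pairs = [
        (detected[i].overlap(visual[j]), i, j)
        for i in range(len(detected))
        for j in range(len(visual))
        if detected[i].overlap(visual[j]) > 0
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_d: set[int] = set()
    used_v: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i in used_d or j in used_v:
            continue
        matches.append((i, j))
        used_d.add(i)
        used_v.add(j)
    return Pairing(
        matches,
        [i for i in range(len(detected)) if i not in used_d],
        [j for j in range(len(visual)) if j not in used_v],
    )


def evaluate(pairing: Pairing) -> EvaluationResult:
    return EvaluationResult.from_counts(pairing.tp, pairing.fp, pairing.fn)


# ---------------------------------------------------------------------------
# Parameter optimization (traversal of the Youden index)

DEFAULT_GRID = {
    "n_low": range(4, 13),
    "n_high": range(2, 9),
    "k_low": (2.0, 2.5, 3.0, 3.5, 4.0),
    "k_high": tuple(np.arange(6.0, 12.5, 0.5)),
}


def optimize_parameters(
    filtered: np.ndarray,
    fs: float,
    base: BaselineModel,
    visual: list[HFOEvent],
    grid: dict | None = None,
    band: BandDefinition | None = None,
) -> tuple[DetectionParams, EvaluationResult]:
    """Exhaustive grid traversal maximizing the Youden index.

    Among parameter sets with specificity strictly above sensitivity the
    highest Youden index wins; ties break toward higher specificity, then
    smaller ``n_low``.  If no set satisfies the constraint, the
    unconstrained argmax is returned with a warning.
    """
    if grid is None:
        grid = DEFAULT_GRID
    band = band if band is not None else base.band
    best = None  # (youden, spec, -n_low, params, result)
    best_any = None
    for n_low, n_high, k_low, k_high in itertools.product(
        grid["n_low"], grid["n_high"], grid["k_low"], grid["k_high"]
    ):
        if n_high > n_low or k_low >= k_high:
            continue
        p = DetectionParams(n_low, k_low, n_high, k_high, band=band)
        det = detect_hfos(filtered, fs, base, p)
        res = evaluate(match_events(det, visual))
        if np.isnan(res.youden):
            continue
        key = (res.youden, res.specificity, -n_low, -k_high)
        if best_any is None or key > best_any[0]:
            best_any = (key, p, res)
        if res.specificity > res.sensitivity and (best is None or key > best[0]):
            best = (key, p, res)
    if best is None:
        if best_any is None:
            raise ValueError("no parameter set could be evaluated")
        warnings.warn("no parameter set with specificity > sensitivity; "
                      "returning unconstrained Youden argmax")
        best = best_any
    return best[1], best[2]
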