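"""Epileptogenic-zone delineation from HFO channel rankings.

Channels are ranked in descending order of their true-HFO rate (events per
minute, after false-HFO removal; only channels above 1/min participate).
The *continuous resection ratio of high-order HFO channels* is the number
of channels resected consecutively from the top of that ranking, divided
by the number of ranked channels:

    ratio = #ChannelConRem_HFOs / #Channel_HFOs

Resections whose ratio reaches at least 0.72 — the lower 95% CI bound of
the good-outcome group's fast-ripple ratio — predict seizure freedom, so
the EZ is delineated as the top 72% of the ranking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spst

from .detection import HFOEvent

__all__ = [
    "ChannelRate",
    "RankingResult",
    "OutcomeRecord",
    "EZResult",
    "OutcomeComparison",
    "channel_rates",
    "rank_channels",
    "delineate_ez",
    "compare_outcomes",
    "RATIO_THRESHOLD",
]

RATIO_THRESHOLD = 0.72
MIN_RATE = 1.0  # events/min; strictly greater required


@dataclass(frozen=True)
class ChannelRate:
    channel: str
    band: str
    rate: float  # true events per minute
    removed: bool


@dataclass
class RankingResult:
    ordered: list[ChannelRate]  # descending by rate
    n_channels: int
    n_continuous_removed: int
    first_kept_index: int
    ratio: float
    valid: bool = True


@dataclass
class EZResult:
    channels: list[str]  # top ceil(threshold * n) of the ranking
    threshold: float
    covered: bool  # does the actual resection reach the threshold?
    ratio: float


@dataclass(frozen=True)
class OutcomeRecord:
    patient: str
    engel_class: int  # 1..4
    ratios: dict  # band -> continuous resection ratio (nan if undefined)

    @property
    def group(self) -> str:
        return "good" if self.engel_class == 1 else "poor"


@dataclass
class GroupStats:
    n: int
    median: float
    iqr: tuple[float, float]
    ci95: tuple[float, float] | None


@dataclass
class OutcomeComparison:
    good: GroupStats
    poor: GroupStats
    p_value: float
    threshold_candidate: float | None  # lower CI bound of the good group


# ---------------------------------------------------------------------------


def channel_rates(
    true_events: list[HFOEvent],
    duration_min: float,
    resection_flags: dict[str, bool],
    band: str | None = None,
) -> list[ChannelRate]:
    """Per-channel true-HFO rates; channels at or below 1/min are dropped."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    events = [e for e in true_events if band is None or e.band == band]
    missing = sorted({e.channel for e in events} - set(resection_flags))
    if missing:
        raise KeyError(f"channels without resection flag: {missing}")
    counts: dict[tuple[str, str], int] = {}
    for e in events:
        counts[(e.channel, e.band)] = counts.get((e.channel, e.band), 0) + 1
    rates = [
        ChannelRate(ch, bd, n / duration_min, bool(resection_flags[ch]))
        for (ch, bd), n in counts.items()
    ]
    return [r for r in rates if r.rate > MIN_RATE]


def rank_channels(
    rates: list[ChannelRate], tie_mode: str = "lexicographic"
) -> RankingResult:
    """Descending-rate ranking and the continuous resection ratio.

    Equal rates are ordered lexicographically by label; ``tie_mode=
    "pessimistic"`` instead puts non-removed channels first within a tie,
    lower-bounding the ratio.
    """
    if not rates:
        warnings.warn("no channels above 1 event/min; ratio undefined")
        return RankingResult([], 0, 0, 0, float("nan"), valid=False)
    if tie_mode == "lexicographic":
        key = lambda r: (-r.rate, r.channel)
    elif tie_mode == "pessimistic":
        key = lambda r: (-r.rate, r.removed, r.channel)
    else:
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    ordered = sorted(rates, key=key)
    first_kept = next(
        (i for i, r in enumerate(ordered) if not r.removed), len(ordered)
    )
    n = len(ordered)
    return RankingResult(ordered, n, first_kept, first_kept, first_kept / n)


def delineate_ez(ranking: RankingResult, threshold: float = RATIO_THRESHOLD) -> EZResult:
    """EZ = top ``ceil(threshold * n)`` channels; coverage = ratio >= threshold."""
    if not ranking.valid:
        return EZResult([], threshold, False, float("nan"))
    k = math.ceil(threshold * ranking.n_channels - 1e-9)
    channels = [r.channel for r in ranking.ordered[:k]]
    return EZResult(channels, threshold, ranking.ratio >= threshold, ranking.ratio)


# ---------------------------------------------------------------------------
# Outcome-group statistics


def _group_stats(
    vals: np.ndarray, rng: np.random.Generator, n_boot: int
) -> GroupStats:
    med = float(np.median(vals))
    q1, q3 = np.percentile(vals, [25, 75])
    if len(vals) < 2:
        warnings.warn("group of size < 2: CI suppressed")
        ci = None
    else:
        boots = np.median(
            vals[rng.integers(0, len(vals), size=(n_boot, len(vals)))], axis=1
        )
        ci = tuple(float(x) for x in np.percentile(boots, [2.5, 97.5]))
    return GroupStats(len(vals), med, (float(q1), float(q3)), ci)


def compare_outcomes(
    records: list[OutcomeRecord],
    band: str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> OutcomeComparison:
    """Good-vs-poor comparison of the continuous resection ratio.

    Reports per-group median, quartile IQR, percentile-bootstrap 95% CI of
    the median, and the two-sided Mann-Whitney U p-value (exact when both
    groups are small and tie-free).  Patients with an undefined ratio are
    excluded.  The lower CI bound of the good group is the data-driven
    candidate for the resection threshold.
    """
    good = np.array(
        [r.ratios[band] for r in records if r.group == "good"], dtype=float
    )
    poor = np.array(
        [r.ratios[band] for r in records if r.group == "poor"], dtype=float
    )
    n_nan = np.isnan(good).sum() + np.isnan(poor).sum()
    if n_nan:
        warnings.warn(f"excluding {n_nan} patient(s) with undefined ratio")
    good, poor = good[~np.isnan(good)], poor[~np.isnan(poor)]
    if len(good) == 0 or len(poor) == 0:
        raise ValueError("both outcome groups must be non-empty")
    no_ties = len(np.unique(np.concatenate([good, poor]))) == len(good) + len(poor)
    method = "exact" if (no_ties and max(len(good), len(poor)) <= 25) else "auto"
    p = float(
        spst.mannwhitneyu(good, poor, alternative="two-sided", method=method).pvalue
    )
    rng = np.random.default_rng(seed)
    gs = _group_stats(good, rng, n_boot)
    ps = _group_stats(poor, rng, n_boot)
    cand = gs.ci95[0] if gs.ci95 is not None else None
    return OutcomeComparison(gs, ps, p, cand)
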