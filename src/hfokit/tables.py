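"""Delimited-table I/O for events, annotations, resection flags and outcomes."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detection import HFOEvent

__all__ = [
    "events_to_frame",
    "frame_to_events",
    "write_events",
    "read_events",
    "read_resection_flags",
    "read_outcomes",
]

_EVENT_COLS = [
    "channel",
    "band",
    "start_s",
    "end_s",
    "n_peaks",
    "max_amp_uv",
    "verdict",
    "accumulated_power",
]


def events_to_frame(events: list[HFOEvent]) -> pd.DataFrame:
    rows = [
        {
            "channel": e.channel,
            "band": e.band,
            "start_s": e.start,
            "end_s": e.end,
            "n_peaks": len(e.peak_times),
            "max_amp_uv": float(e.peak_amps.max()) if len(e.peak_amps) else np.nan,
            "verdict": e.verdict,
            "accumulated_power": e.accumulated_power,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLS)


def frame_to_events(df: pd.DataFrame) -> list[HFOEvent]:
    return [
        HFOEvent(
            channel=str(r.channel),
            band=str(r.band),
            start=float(r.start_s),
            end=float(r.end_s),
            verdict=str(getattr(r, "verdict", "unclassified")),
            accumulated_power=float(getattr(r, "accumulated_power", np.nan)),
        )
        for r in df.itertuples(index=False)
    ]


def write_events(events: list[HFOEvent], path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events(path) -> list[HFOEvent]:
    return frame_to_events(pd.read_csv(path, sep="\t"))


def read_resection_flags(path) -> dict[str, bool]:
    """Two-column table (channel, removed) -> {channel: bool}."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.channel): bool(r.removed) for r in df.itertuples(index=False)
    }


def read_outcomes(path) -> pd.DataFrame:
    """Table with columns (patient, engel_class)."""
    return pd.read_csv(path, sep="\t")
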