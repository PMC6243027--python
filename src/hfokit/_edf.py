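"""Minimal EDF writer.

Writes plain EDF (16-bit) with one-second data records, enough to persist
synthetic recordings and round-trip them through standard EDF readers.
Physical units are written per channel; digital range is the full int16 span.
"""

from __future__ import annotations

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    samples: np.ndarray,
    fs: float,
    labels: list[str],
    physical_dimension: str = "uV",
) -> None:
    """Write ``samples`` (channels x time, in ``physical_dimension``) as EDF.

    ``fs`` must be a whole number of samples per second; the last partial
    second is zero-padded.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be 2-D (channels x time)")
    n_ch, n_t = samples.shape
    if len(labels) != n_ch:
        raise ValueError("labels length must match channel count")
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(n_t / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_t] = samples

    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax[flat] = pmin[flat] + 1.0

    header = b"".join(
        [
            _field("0", 8),
            _field("X", 80),
            _field("X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (n_ch + 1)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(lb, 16) for lb in labels),
            b"".join(_field("", 80) for _ in labels),
            b"".join(_field(physical_dimension, 8) for _ in labels),
            b"".join(_field(f"{v:.6g}"[:8], 8) for v in pmin),
            b"".join(_field(f"{v:.6g}"[:8], 8) for v in pmax),
            b"".join(_field(str(_DIG_MIN), 8) for _ in labels),
            b"".join(_field(str(_DIG_MAX), 8) for _ in labels),
            b"".join(_field("", 80) for _ in labels),
            b"".join(_field(str(spr), 8) for _ in labels),
            b"".join(_field("", 32) for _ in labels),
        ]
    )

    # re-read the exact 8-char physical bounds so writer and file agree
    pmin_q = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_q = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    scale = (_DIG_MAX - _DIG_MIN) / (pmax_q - pmin_q)
    digital = np.rint((padded - pmin_q[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
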