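"""Minimal 16-bit EDF writer.

Only what the synthetic-cohort export needs: one data record per second,
identical sample rate on every signal, physical dimension microvolts. The
per-channel physical range is widened 5% beyond the observed extrema so the
16-bit quantization step stays well below 0.1% of the signal RMS.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data_io import Recording

__all__ = ["write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numeric fields rather than corrupt the fixed-width header
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _fit8(value: float) -> float:
    """Round so the decimal form fits the 8-char EDF header field exactly."""
    for prec in range(7, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8:
            return float(s)
    raise ValueError(f"cannot encode {value!r} in 8 characters")


def _phys_range(x: np.ndarray) -> tuple[float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    span = hi - lo
    if span <= 0:
        center = lo
        lo, hi = center - 1.0, center + 1.0
    else:
        lo -= 0.05 * span
        hi += 0.05 * span
    # quantization below must use the exact header values, so round first
    lo, hi = _fit8(lo), _fit8(hi)
    if hi <= lo:
        hi = _fit8(lo + 1.0)
    return lo, hi


def write_edf(rec: Recording, path: str | Path, label_style: str = "physionet") -> Path:
    """Write a :class:`Recording` as a plain EDF file.

    ``label_style='physionet'`` mimics the source dataset's label convention
    ("Fc5." — capitalized, trailing dot); ``'plain'`` writes canonical labels.
    Requires an integer sample rate (one data record per second); a trailing
    partial second is zero-padded in the last record, so callers should write
    whole-second recordings for bit-faithful round trips.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rate = rec.sample_rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF export requires an integer sample rate")
    rate = int(round(rate))
    n_sig = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / rate))

    if label_style == "physionet":
        labels = [ch.capitalize() + "." for ch in rec.channel_names]
    else:
        labels = list(rec.channel_names)

    phys = [_phys_range(row) for row in rec.signal]

    header = b"".join(
        [
            _field(0, 8),  # version
            _field(f"X X X {rec.subject_id}", 80),
            _field(f"Startdate 01-JAN-2000 X X X {rec.session.value}", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(256 * (1 + n_sig), 8),
            _field("", 44),
            _field(n_records, 8),
            _field(1, 8),  # record duration, seconds
            _field(n_sig, 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_field(lab, 16) for lab in labels),
            b"".join(_field("", 80) for _ in range(n_sig)),  # transducer
            b"".join(_field("uV", 8) for _ in range(n_sig)),
            b"".join(_field(f"{lo:.7g}", 8) for lo, _ in phys),
            b"".join(_field(f"{hi:.7g}", 8) for _, hi in phys),
            b"".join(_field(_DIG_MIN, 8) for _ in range(n_sig)),
            b"".join(_field(_DIG_MAX, 8) for _ in range(n_sig)),
            b"".join(_field("", 80) for _ in range(n_sig)),  # prefiltering
            b"".join(_field(rate, 8) for _ in range(n_sig)),
            b"".join(_field("", 32) for _ in range(n_sig)),
        ]
    )

    padded = np.zeros((n_sig, n_records * rate))
    padded[:, : rec.n_samples] = rec.signal
    digital = np.empty_like(padded, dtype=np.int16)
    for i, (lo, hi) in enumerate(phys):
        gain = (hi - lo) / (_DIG_MAX - _DIG_MIN)
        digital[i] = np.clip(
            np.round((padded[i] - lo) / gain + _DIG_MIN), _DIG_MIN, _DIG_MAX
        ).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        # records are interleaved: all of signal 0's second, then signal 1's, ...
        for r in range(n_records):
            block = digital[:, r * rate : (r + 1) * rate]
            fh.write(block.astype("<i2").tobytes())
    return path
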