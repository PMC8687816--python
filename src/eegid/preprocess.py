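"""Per-subject Z-score standardization of raw EEG.

No filtering, artifact rejection or re-referencing is applied: the raw
multichannel signal is rescaled as ``(x - mu) / sigma`` where ``mu`` and
``sigma`` are the mean and population standard deviation pooled over *all*
values (every channel, every time-point, every provided session) of one
subject. Standardization mainly conditions the optimization (EEG amplitudes
are small); it carries no subject-discriminative information by itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data_io import Recording

__all__ = ["SubjectStats", "compute_stats", "standardize", "inverse_standardize"]


@dataclass(frozen=True)
class SubjectStats:
    """Pooled mean/std of one subject's signal values.

    ``sigma`` is the population (divide-by-N) standard deviation; ``n`` is the
    number of pooled values.
    """

    subject_id: str
    mu: float
    sigma: float
    n: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self))
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SubjectStats":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls(**json.loads(text))


def compute_stats(recs: list[Recording] | Recording) -> SubjectStats:
    """Pool every sample value of one subject into a mean and population std.

    All recordings must belong to the same subject; pass both sessions to get
    the pooled statistics used by the union protocol, one session otherwise.
    """
    if isinstance(recs, Recording):
        recs = [recs]
    if not recs:
        raise ValueError("compute_stats requires at least one recording")
    subjects = {r.subject_id for r in recs}
    if len(subjects) > 1:
        raise ValueError(
            f"statistics are per subject; got recordings from {sorted(subjects)}"
        )
    values = np.concatenate([np.asarray(r.signal, dtype=np.float64).ravel() for r in recs])
    if values.size == 0:
        raise ValueError("no sample values to pool")
    return SubjectStats(
        subject_id=recs[0].subject_id,
        mu=float(values.mean()),
        sigma=float(values.std(ddof=0)),
        n=int(values.size),
    )


def standardize(rec: Recording, stats: SubjectStats) -> Recording:
    """Apply ``(x - mu) / sigma``; shape, channels and sample rate unchanged."""
    if not stats.sigma > 0:
        raise ValueError(
            f"subject {stats.subject_id}: sigma={stats.sigma} — constant "
            "(degenerate) recording cannot be standardized"
        )
    out = (np.asarray(rec.signal, dtype=np.float64) - stats.mu) / stats.sigma
    return Recording(
        subject_id=rec.subject_id,
        session=rec.session,
        channel_names=list(rec.channel_names),
        sample_rate=rec.sample_rate,
        signal=out,
    )


def inverse_standardize(rec: Recording, stats: SubjectStats) -> Recording:
    """Undo :func:`standardize` given the same stats."""
    out = np.asarray(rec.signal, dtype=np.float64) * stats.sigma + stats.mu
    return Recording(
        subject_id=rec.subject_id,
        session=rec.session,
        channel_names=list(rec.channel_names),
        sample_rate=rec.sample_rate,
        signal=out,
    )
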