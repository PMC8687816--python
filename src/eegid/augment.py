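"""Sliding-window segmentation of recordings into fixed-size labeled samples.

A window of ``length_s`` seconds slides over each recording (or each
train/test span of it) with hop ``stride_s``; every position yields one
classifier input of shape P x C (time-points down the rows, channels across
the columns). ``stride_s == length_s`` recovers plain fixed windows; a
stride of half the length gives 50%-overlapping windows, the augmentation
setting that drives the identification accuracy. Windows start at offset 0
of each span and the trailing remainder is discarded, so a span of T samples
yields exactly ``floor((T - L) / S) + 1`` windows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import Recording, Session

__all__ = [
    "WindowSpec",
    "Segment",
    "SegmentedDataset",
    "n_windows",
    "segment_recording",
    "build_dataset",
    "training_set_scale",
]


@dataclass(frozen=True)
class WindowSpec:
    """Window duration and hop, in seconds."""

    length_s: float
    stride_s: float

    def __post_init__(self) -> None:
        if not self.length_s > 0:
            raise ValueError("window length must be positive")
        if not 0 < self.stride_s <= self.length_s:
            raise ValueError("stride must satisfy 0 < stride <= length")

    @property
    def sliding_ratio(self) -> float:
        """stride / length; 1 means fixed windows, 0.5 means 50% overlap."""
        return self.stride_s / self.length_s

    def in_samples(self, sample_rate: float) -> tuple[int, int]:
        """(window, stride) in samples; both must be whole at this rate."""
        out = []
        for name, seconds in (("length", self.length_s), ("stride", self.stride_s)):
            exact = seconds * sample_rate
            if abs(exact - round(exact)) > 1e-9:
                raise ValueError(
                    f"window {name} {seconds}s is not a whole number of samples "
                    f"at {sample_rate} Hz"
                )
            out.append(int(round(exact)))
        return out[0], out[1]


@dataclass
class Segment:
    """One fixed-size classifier input with its provenance.

    ``data`` is P x C (time-major); ``label`` is the dense class index, -1
    until a dataset assigns it; ``start_sample`` locates the window in the
    source recording.
    """

    data: np.ndarray
    label: int
    subject_id: str
    session: Session
    start_sample: int


@dataclass
class SegmentedDataset:
    """Ordered segments plus the subject -> dense class index map."""

    segments: list[Segment]
    label_map: dict[str, int]

    def __post_init__(self) -> None:
        n = len(self.label_map)
        if sorted(self.label_map.values()) != list(range(n)):
            raise ValueError("label_map indices must be dense 0..O-1")
        for seg in self.segments:
            if not 0 <= seg.label < n:
                raise ValueError(f"segment label {seg.label} outside 0..{n - 1}")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_classes(self) -> int:
        return len(self.label_map)

    def arrays(self, dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
        """Stack into network input (N, 1, P, C) and label vector (N,)."""
        x = np.stack([seg.data for seg in self.segments]).astype(dtype)[:, None]
        y = np.array([seg.label for seg in self.segments], dtype=np.int64)
        return x, y

    def save(self, path: str | Path) -> None:
        """Cache as ``<path>.npz`` (data) + ``<path>.json`` (provenance)."""
        path = Path(path)
        x = np.stack([seg.data for seg in self.segments])
        np.savez(path.with_suffix(".npz"), data=x)
        meta = {
            "label_map": self.label_map,
            "segments": [
                {
                    "label": seg.label,
                    "subject_id": seg.subject_id,
                    "session": seg.session.value,
                    "start_sample": seg.start_sample,
                }
                for seg in self.segments
            ],
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentedDataset":
        path = Path(path)
        x = np.load(path.with_suffix(".npz"))["data"]
        meta = json.loads(path.with_suffix(".json").read_text())
        segments = [
            Segment(
                data=x[i],
                label=m["label"],
                subject_id=m["subject_id"],
                session=Session(m["session"]),
                start_sample=m["start_sample"],
            )
            for i, m in enumerate(meta["segments"])
        ]
        return cls(segments=segments, label_map=meta["label_map"])


def n_windows(n_samples, window: int, stride: int):
    """floor((T - L) / S) + 1, or 0 when the span is shorter than the window.

    Accepts a scalar span or an array of spans.
    """
    n = np.asarray(n_samples)
    counts = np.where(n < window, 0, (n - window) // stride + 1)
    if n.ndim == 0:
        return int(counts)
    return counts


def segment_recording(
    rec: Recording,
    spec: WindowSpec,
    start: int = 0,
    stop: int | None = None,
    label: int = -1,
) -> list[Segment]:
    """Cut one recording (or the half-open sample span [start, stop)) into
    windows.

    Returns the segments in temporal order; a span shorter than one window
    yields an empty list with a warning. Each segment's data is the transpose
    of the channels x time slice, i.e. P x C.
    """
    stop = rec.n_samples if stop is None else stop
    if not 0 <= start <= stop <= rec.n_samples:
        raise ValueError(f"invalid span [{start}, {stop}) for {rec.n_samples} samples")
    window, stride = spec.in_samples(rec.sample_rate)
    span = stop - start
    count = n_windows(span, window, stride)
    if count == 0:
        warnings.warn(
            f"span of {span} samples is shorter than the {window}-sample window; "
            "no segments produced",
            stacklevel=2,
        )
        return []
    return [
        Segment(
            data=rec.signal[:, start + k * stride : start + k * stride + window].T.copy(),
            label=label,
            subject_id=rec.subject_id,
            session=rec.session,
            start_sample=start + k * stride,
        )
        for k in range(count)
    ]


def build_dataset(
    recs: list[Recording],
    spec: WindowSpec,
    ranges: list[list[tuple[int, int]]] | None = None,
    label_map: dict[str, int] | None = None,
) -> SegmentedDataset:
    """Segment each recording's spans independently into one labeled dataset.

    ``ranges[i]`` lists half-open sample intervals of ``recs[i]`` to segment
    (default: the whole recording). Windows never straddle an interval
    boundary. Dense class labels are assigned by lexicographically sorted
    subject_id unless an existing ``label_map`` is supplied.
    """
    if ranges is None:
        ranges = [[(0, r.n_samples)] for r in recs]
    if len(ranges) != len(recs):
        raise ValueError("ranges must be parallel to recs")
    for rec, spans in zip(recs, ranges):
        ordered = sorted(spans)
        for (a0, b0), (a1, b1) in zip(ordered, ordered[1:]):
            if a1 < b0:
                raise ValueError(
                    f"overlapping spans [{a0},{b0}) and [{a1},{b1}) for "
                    f"recording {rec.subject_id}/{rec.session.value}"
                )
    if label_map is None:
        subjects = sorted({r.subject_id for r in recs})
        label_map = {s: i for i, s in enumerate(subjects)}
    segments: list[Segment] = []
    for rec, spans in zip(recs, ranges):
        if rec.subject_id not in label_map:
            raise KeyError(f"subject {rec.subject_id} not in label_map")
        label = label_map[rec.subject_id]
        for a, b in spans:
            segments.extend(segment_recording(rec, spec, start=a, stop=b, label=label))
    return SegmentedDataset(segments=segments, label_map=dict(label_map))


def training_set_scale(
    n_subjects: int,
    duration_s: float,
    sample_rate: float,
    spec: WindowSpec,
    n_recordings_per_subject: int = 1,
) -> int:
    """Total training segments for a cohort of identical-length spans.

    Mirrors the augmentation-grid bookkeeping: e.g. 109 subjects, first 48 s
    at 160 Hz, 0.5 s windows with 0.25 s stride -> 20819 training samples.
    """
    t = duration_s * sample_rate
    if abs(t - round(t)) > 1e-9:
        raise ValueError("duration is not a whole number of samples at this rate")
    window, stride = spec.in_samples(sample_rate)
    return n_subjects * n_recordings_per_subject * n_windows(int(round(t)), window, stride)
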