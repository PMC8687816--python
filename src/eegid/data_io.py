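"""Reading multichannel EEG recordings and selecting electrode montages.

Recordings arrive as EDF files (one file per subject per resting-state
session, e.g. the PhysioNet motor movement/imagery layout ``S001/S001R01.edf``).
Channel labels in those files carry trailing dots ("Fc5.") which are stripped
and uppercased to canonical 10-10 names so they can be matched against the
named montages: the 14-channel consumer-headset layout (``EPOC14``), a
32-channel cap (``FLEX32``) and the full 64-channel set (``FULL64``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Session",
    "Recording",
    "Montage",
    "MONTAGES",
    "CHANNELS_64",
    "normalize_label",
    "read_edf",
    "select_channels",
]


class Session(str, Enum):
    """Resting-state session type: eyes-open or eyes-closed."""

    EO = "EO"
    EC = "EC"


_NON_ALNUM = re.compile(r"[^A-Za-z0-9]")


def normalize_label(label: str) -> str:
    """Canonicalize an electrode label: drop non-alphanumerics, uppercase.

    ``"Fc5."`` -> ``"FC5"``; an optional ``EEG `` prefix (used by some EDF
    exporters in the 16-char label field) is removed first.
    """
    label = re.sub(r"^(EEG|eeg)[ _]", "", label.strip())
    return _NON_ALNUM.sub("", label).upper()


@dataclass
class Recording:
    """One subject-session multichannel signal.

    ``signal`` is channels x time-points; units are whatever the source file
    declared (microvolts for the EDF files written by this package).
    """

    subject_id: str
    session: Session
    channel_names: list[str]
    sample_rate: float
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x time matrix")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.signal.shape[1] < 1:
            raise ValueError("recording must contain at least one time-point")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique after normalization")
        if not isinstance(self.session, Session):
            self.session = Session(self.session)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass(frozen=True)
class Montage:
    """A named, ordered subset of scalp electrodes."""

    name: str
    channels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.channels)


def _load_montages() -> dict[str, Montage]:
    text = resources.files("eegid").joinpath("data/montages.json").read_text()
    raw = json.loads(text)
    return {name: Montage(name, tuple(chs)) for name, chs in raw.items()}


MONTAGES: dict[str, Montage] = _load_montages()
CHANNELS_64: tuple[str, ...] = MONTAGES["FULL64"].channels

_PHYSIONET_NAME = re.compile(r"^(S\d{3})R(\d{2})$", re.IGNORECASE)
# Runs 1 and 2 of the PhysioNet layout are the eyes-open / eyes-closed baselines.
_RUN_SESSION = {1: Session.EO, 2: Session.EC}


def _infer_identity(path: Path) -> tuple[str, Session | None]:
    m = _PHYSIONET_NAME.match(path.stem)
    if m:
        run = int(m.group(2))
        return m.group(1).upper(), _RUN_SESSION.get(run)
    return path.stem, None


def read_edf(
    path: str | Path,
    subject_id: str | None = None,
    session: Session | str | None = None,
) -> Recording:
    """Read one EDF file into a :class:`Recording`.

    Channel labels are normalized via :func:`normalize_label`; the sample rate
    comes from the EDF header. ``subject_id`` and ``session`` default to what
    the PhysioNet-style file name implies (``S001R01`` -> subject ``S001``,
    eyes-open); pass them explicitly for other layouts (session falls back to
    eyes-open when it cannot be inferred).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # corrupt header, truncated records, ...
        raise IOError(f"could not read EDF file {path}: {exc}") from exc
    if len(raw.ch_names) == 0:
        raise ValueError(f"EDF file {path} contains no signals")

    inferred_subject, inferred_session = _infer_identity(path)
    if session is None:
        session = inferred_session if inferred_session is not None else Session.EO
    return Recording(
        subject_id=subject_id if subject_id is not None else inferred_subject,
        session=Session(session),
        channel_names=[normalize_label(ch) for ch in raw.ch_names],
        sample_rate=float(raw.info["sfreq"]),
        signal=raw.get_data(units="uV"),
    )


def select_channels(rec: Recording, montage: Montage | str) -> Recording:
    """Restrict a recording to a montage's channels, in montage order.

    The montage's declared order (not the file's) fixes the row order, so the
    network's input-channel assignment is deterministic across files. Retained
    samples are copied bit-exactly.
    """
    if isinstance(montage, str):
        montage = MONTAGES[montage]
    index = {name: i for i, name in enumerate(rec.channel_names)}
    missing = [ch for ch in montage.channels if ch not in index]
    if missing:
        raise KeyError(
            f"recording {rec.subject_id}/{rec.session.value} is missing montage "
            f"{montage.name} channels: {', '.join(missing)}"
        )
    rows = [index[ch] for ch in montage.channels]
    return Recording(
        subject_id=rec.subject_id,
        session=rec.session,
        channel_names=list(montage.channels),
        sample_rate=rec.sample_rate,
        signal=rec.signal[rows].copy(),
    )
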