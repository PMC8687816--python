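"""Synthetic resting-state cohorts with recoverable identity structure.

Each synthetic subject is defined by latent oscillatory sources — one
sinusoid per source with a subject-specific center frequency (drawn from the
4-30 Hz band covering the theta/alpha/beta rhythms that dominate resting
EEG), amplitude and phase, plus per-source broadband noise — linearly mixed
into the observed channels by a subject-specific mixing matrix with
zero-mean Gaussian entries, and finally corrupted by additive white sensor
noise scaled relative to the mixed signal's RMS. Identity therefore lives in
*both* the spectral content of the sources and the mixing weights, which is
exactly the generative structure a learnable channel-unmixing stage can
exploit.

These cohorts emulate fixed-rate multichannel recordings with stable
per-subject structure; they make no claim of physiological realism (no 1/f
background, no artifacts, no inter-session drift).

All randomness derives from a single master seed through per-(subject,
session) seed sequences, so any recording is reproducible independently of
generation order; a subject's sources and mixing matrix are shared across
sessions (they *are* the identity), while phases and noise are redrawn per
session.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import CHANNELS_64, MONTAGES, Recording, Session
from .edf import write_edf

__all__ = ["SyntheticSpec", "generate_recording", "generate_cohort", "export_cohort_edf"]

_SESSION_CODE = {Session.EO: 1, Session.EC: 2}


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort parameters.

    Defaults describe the desk-scale study cohort: 8 subjects, one minute of
    14-channel signal at 160 Hz, 6 latent sources in the 4-30 Hz band, sensor
    noise at a quarter of the signal RMS.
    """

    n_subjects: int = 8
    n_sources: int = 6
    n_channels: int = 14
    duration_s: float = 60.0
    sample_rate: float = 160.0
    freq_range: tuple[float, float] = (4.0, 30.0)
    amp_range: tuple[float, float] = (0.5, 1.5)
    source_noise_sd: float = 0.1
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_sources < 1 or self.n_subjects < 1:
            raise ValueError("n_subjects, n_sources, n_channels must be >= 1")
        if self.freq_range[1] >= self.sample_rate / 2:
            raise ValueError(
                f"max source frequency {self.freq_range[1]} Hz reaches the "
                f"Nyquist limit {self.sample_rate / 2} Hz"
            )
        if self.noise_sd < 0 or self.source_noise_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if self.n_channels > len(CHANNELS_64):
            raise ValueError(f"at most {len(CHANNELS_64)} channels available")


def _channel_names(n: int) -> list[str]:
    if n == 14:
        return list(MONTAGES["EPOC14"].channels)
    if n == 32:
        return list(MONTAGES["FLEX32"].channels)
    return list(CHANNELS_64[:n])


def _identity_params(spec: SyntheticSpec, subject_index: int):
    """Mixing matrix, frequencies and amplitudes — fixed per subject."""
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, subject_index])
    )
    freqs = rng.uniform(*spec.freq_range, size=spec.n_sources)
    amps = rng.uniform(*spec.amp_range, size=spec.n_sources)
    mixing = rng.normal(0.0, 1.0, size=(spec.n_channels, spec.n_sources))
    return mixing, freqs, amps


def generate_recording(
    spec: SyntheticSpec,
    subject_index: int,
    session: Session | str = Session.EO,
    mixing: np.ndarray | None = None,
) -> Recording:
    """One subject-session recording: channels = mixing @ sources + noise.

    Deterministic in (seed, subject_index, session). Pass ``mixing`` to
    override the subject's generated mixing matrix (e.g. all-ones rank-1
    mixing for degenerate-case tests).
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(f"subject_index {subject_index} outside cohort of {spec.n_subjects}")
    session = Session(session)
    gen_mixing, freqs, amps = _identity_params(spec, subject_index)
    if mixing is None:
        mixing = gen_mixing
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, subject_index, _SESSION_CODE[session]])
    )
    n = int(round(spec.duration_s * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    phases = rng.uniform(0, 2 * np.pi, size=spec.n_sources)
    sources = amps[:, None] * np.sin(
        2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
    )
    if spec.source_noise_sd > 0:
        sources = sources + rng.normal(
            0.0, spec.source_noise_sd, size=sources.shape
        )
    signal = np.asarray(mixing) @ sources
    if spec.noise_sd > 0:
        rms = float(np.sqrt(np.mean(signal**2)))
        signal = signal + rng.normal(0.0, spec.noise_sd * rms, size=signal.shape)
    return Recording(
        subject_id=f"S{subject_index + 1:03d}",
        session=session,
        channel_names=_channel_names(spec.n_channels),
        sample_rate=spec.sample_rate,
        signal=signal,
    )


def generate_cohort(
    spec: SyntheticSpec,
    sessions: tuple[Session | str, ...] = (Session.EO,),
) -> list[Recording]:
    """All subjects' recordings for the requested sessions."""
    return [
        generate_recording(spec, i, session)
        for i in range(spec.n_subjects)
        for session in sessions
    ]


def export_cohort_edf(
    recs: list[Recording], out_dir: str | Path
) -> list[Path]:
    """Write a cohort as EDF files in the PhysioNet-style per-subject layout
    (``S001/S001R01.edf`` for eyes-open, ``R02`` for eyes-closed)."""
    out_dir = Path(out_dir)
    run = {Session.EO: 1, Session.EC: 2}
    paths = []
    for rec in recs:
        name = f"{rec.subject_id}R{run[rec.session]:02d}.edf"
        paths.append(write_edf(rec, out_dir / rec.subject_id / name))
    return paths
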