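"""Reproducible experimental procedures.

Two protocols: (A) a temporal hold-out per recording — the first 48 s train,
the last 12 s test — used for the window/stride augmentation grid; (B) k-fold
cross-validation where fold i's test interval is the i-th contiguous 1/k span
of every recording, over the eyes-open session, the eyes-closed session, or
their union, and over the 14/32/64-channel montages.

Windows are always cut *after* the temporal split, inside each interval, so
no window straddles a train/test or fold boundary; with overlapping windows
that is the only construction that keeps test samples out of the training
material. A leakage check over the interval arithmetic is asserted on every
plan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .augment import SegmentedDataset, WindowSpec, build_dataset
from .data_io import Montage, Recording, select_channels
from .model import ModelConfig, build_model
from .preprocess import compute_stats, standardize
from .train_eval import EvalReport, TrainConfig, evaluate, train

__all__ = [
    "Interval",
    "SplitPlan",
    "make_holdout_split",
    "make_cv_splits",
    "aggregate_folds",
    "run_experiment",
    "ExperimentResult",
]


@dataclass(frozen=True)
class Interval:
    """A half-open sample interval of one recording with its role."""

    role: str  # "train" or "test"
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.stop:
            raise ValueError(f"invalid interval [{self.start}, {self.stop})")


@dataclass
class SplitPlan:
    """Per-recording train/test intervals; parallel to a recording list."""

    intervals: list[list[Interval]]

    def __post_init__(self) -> None:
        for ivs in self.intervals:
            ordered = sorted(ivs, key=lambda iv: iv.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start < a.stop:
                    raise ValueError(
                        f"overlapping intervals [{a.start},{a.stop}) and "
                        f"[{b.start},{b.stop})"
                    )

    def ranges(self, role: str) -> list[list[tuple[int, int]]]:
        return [
            [(iv.start, iv.stop) for iv in ivs if iv.role == role]
            for ivs in self.intervals
        ]

    def assert_no_leakage(self) -> None:
        """No sample index may carry both a train and a test role."""
        for ivs in self.intervals:
            train_idx = set()
            for iv in ivs:
                if iv.role == "train":
                    train_idx.update(range(iv.start, iv.stop))
            for iv in ivs:
                if iv.role == "test" and train_idx.intersection(
                    range(iv.start, iv.stop)
                ):
                    raise AssertionError(
                        "train/test intervals overlap within one recording"
                    )


def _whole_samples(seconds: float, rate: float, what: str) -> int:
    exact = seconds * rate
    if abs(exact - round(exact)) > 1e-9:
        raise ValueError(f"{what} of {seconds}s is not whole at {rate} Hz")
    return int(round(exact))


def make_holdout_split(
    recs: list[Recording], train_s: float = 48.0, test_s: float = 12.0
) -> SplitPlan:
    """First ``train_s`` seconds train, next ``test_s`` seconds test."""
    intervals = []
    for rec in recs:
        n_train = _whole_samples(train_s, rec.sample_rate, "training span")
        n_test = _whole_samples(test_s, rec.sample_rate, "testing span")
        if rec.n_samples < n_train + n_test:
            raise ValueError(
                f"recording {rec.subject_id}/{rec.session.value} has only "
                f"{rec.duration_s:.1f}s; needs {train_s + test_s:.1f}s"
            )
        intervals.append(
            [
                Interval("train", 0, n_train),
                Interval("test", n_train, n_train + n_test),
            ]
        )
    plan = SplitPlan(intervals)
    plan.assert_no_leakage()
    return plan


def make_cv_splits(recs: list[Recording], k: int = 5) -> list[SplitPlan]:
    """Contiguous-block k-fold plans: fold i tests the i-th 1/k of each recording.

    Every recording (of every session present) contributes to every fold, so
    under the union protocol each fold's test set spans both sessions of each
    subject. The recording length must divide into k equal spans.
    """
    if k < 2:
        raise ValueError("k-fold cross-validation requires k >= 2")
    fold_len = []
    for rec in recs:
        if rec.n_samples % k != 0:
            raise ValueError(
                f"recording {rec.subject_id}/{rec.session.value} has "
                f"{rec.n_samples} samples, not divisible into {k} folds; trim "
                f"{rec.n_samples % k} trailing samples first"
            )
        fold_len.append(rec.n_samples // k)
    plans = []
    for i in range(k):
        intervals = []
        for rec, f in zip(recs, fold_len):
            ivs = [Interval("test", i * f, (i + 1) * f)]
            if i > 0:
                ivs.insert(0, Interval("train", 0, i * f))
            if i < k - 1:
                ivs.append(Interval("train", (i + 1) * f, k * f))
            intervals.append(ivs)
        plan = SplitPlan(intervals)
        plan.assert_no_leakage()
        plans.append(plan)
    return plans


def aggregate_folds(values: list[float] | np.ndarray) -> tuple[float, float]:
    """Mean and population (ddof=0) standard deviation across folds.

    The population convention reproduces the printed mean +- std style of the
    published cross-validation tables from their per-fold values.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 1:
        warnings.warn("single fold: std reported as 0", stacklevel=2)
        return float(values[0]), 0.0
    return float(values.mean()), float(values.std(ddof=0))


@dataclass
class ExperimentResult:
    """Per-fold reports plus the mean +- std aggregate."""

    fold_reports: list[EvalReport]
    rank1_mean: float
    rank1_std: float
    eer_mean: float
    eer_std: float

    def summary_dict(self) -> dict:
        return {
            "rank1_mean": self.rank1_mean,
            "rank1_std": self.rank1_std,
            "eer_mean": self.eer_mean,
            "eer_std": self.eer_std,
            "folds": [r.summary_dict() for r in self.fold_reports],
        }


def _subject_stats(recs: list[Recording], scope_ranges=None):
    """Pooled stats per subject over all their recordings (union pools both
    sessions); ``scope_ranges`` restricts the pooled span (strict mode)."""
    by_subject: dict[str, list[Recording]] = {}
    for idx, rec in enumerate(recs):
        if scope_ranges is not None:
            parts = [rec.signal[:, a:b] for a, b in scope_ranges[idx]]
            rec = replace(rec, signal=np.concatenate(parts, axis=1))
        by_subject.setdefault(rec.subject_id, []).append(rec)
    return {s: compute_stats(rs) for s, rs in by_subject.items()}


def run_experiment(
    recs: list[Recording],
    plans: SplitPlan | list[SplitPlan],
    montage: Montage | str | None,
    window_spec: WindowSpec,
    train_cfg: TrainConfig,
    model_overrides: dict | None = None,
    strict_stats: bool = False,
    expected_rate: float | None = 160.0,
    off_rate_policy: str = "exclude",
) -> ExperimentResult:
    """Preprocess, window, train and evaluate over one or more split plans.

    Per fold: per-subject Z-score standardization (full recording by default;
    ``strict_stats=True`` pools only the fold's training spans), montage
    selection, windowing inside the split intervals, training from a fresh
    seeded initialization, and biometric evaluation. Fold metrics are
    aggregated as mean +- population std.

    Recordings whose header rate differs from ``expected_rate`` are excluded
    (default), resampled, or kept verbatim per ``off_rate_policy``.
    """
    recs, plans = _apply_rate_policy(
        recs, plans, expected_rate, off_rate_policy
    )
    if isinstance(plans, SplitPlan):
        plans = [plans]
    rates = {r.sample_rate for r in recs}
    if len(rates) != 1:
        raise ValueError(f"inconsistent sample rates across recordings: {rates}")
    rate = rates.pop()
    p, _ = window_spec.in_samples(rate)

    fold_reports: list[EvalReport] = []
    for fold_idx, plan in enumerate(plans):
        plan.assert_no_leakage()
        try:
            fold_reports.append(
                _run_fold(
                    recs, plan, montage, window_spec, p, train_cfg,
                    model_overrides, strict_stats, fold_idx,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"fold {fold_idx}: {exc}") from exc

    r1_mean, r1_std = aggregate_folds([r.rank1 for r in fold_reports])
    eer_mean, eer_std = aggregate_folds([r.eer for r in fold_reports])
    return ExperimentResult(fold_reports, r1_mean, r1_std, eer_mean, eer_std)


def _apply_rate_policy(recs, plans, expected_rate, policy):
    if expected_rate is None:
        return recs, plans
    flagged = [i for i, r in enumerate(recs) if r.sample_rate != expected_rate]
    if not flagged:
        return recs, plans
    if policy == "keep":
        warnings.warn(
            f"{len(flagged)} recordings deviate from {expected_rate} Hz; kept",
            stacklevel=3,
        )
        return recs, plans
    if policy == "exclude":
        warnings.warn(
            f"excluding {len(flagged)} recordings not at {expected_rate} Hz",
            stacklevel=3,
        )
        keep = [i for i in range(len(recs)) if i not in set(flagged)]
        recs = [recs[i] for i in keep]
        if isinstance(plans, SplitPlan):
            plans = SplitPlan([plans.intervals[i] for i in keep])
        else:
            plans = [SplitPlan([pl.intervals[i] for i in keep]) for pl in plans]
        return recs, plans
    if policy == "resample":
        from scipy.signal import resample_poly
        from fractions import Fraction

        out = []
        for r in recs:
            if r.sample_rate == expected_rate:
                out.append(r)
                continue
            frac = Fraction(expected_rate / r.sample_rate).limit_denominator(1000)
            sig = resample_poly(r.signal, frac.numerator, frac.denominator, axis=1)
            out.append(
                replace(r, signal=sig, sample_rate=expected_rate)
            )
        warnings.warn(
            f"resampled {len(flagged)} recordings to {expected_rate} Hz",
            stacklevel=3,
        )
        return out, plans
    raise ValueError(f"unknown off-rate policy {policy!r}")


def _run_fold(
    recs, plan, montage, window_spec, p, train_cfg, model_overrides,
    strict_stats, fold_idx,
):
    scope = plan.ranges("train") if strict_stats else None
    stats = _subject_stats(recs, scope_ranges=scope)
    prepared = [standardize(r, stats[r.subject_id]) for r in recs]
    if montage is not None:
        prepared = [select_channels(r, montage) for r in prepared]
    train_set = build_dataset(prepared, window_spec, plan.ranges("train"))
    test_set = build_dataset(
        prepared, window_spec, plan.ranges("test"), label_map=train_set.label_map
    )
    cfg_kwargs = {
        "n_channels": prepared[0].n_channels,
        "n_points": p,
        "n_classes": train_set.n_classes,
    }
    cfg_kwargs.update(model_overrides or {})
    network = build_model(
        ModelConfig(**cfg_kwargs),
        seed=int(np.random.SeedSequence([train_cfg.seed, 101, fold_idx]).generate_state(1)[0] % (2**31)),
    )
    train(network, train_set, replace(train_cfg, seed=train_cfg.seed + fold_idx))
    return evaluate(network, test_set)
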