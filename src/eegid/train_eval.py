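"""Training loop and biometric evaluation.

Training follows the published recipe: Adam at learning rate 3e-3, batch
size 64, seeded shuffling each epoch, no early stopping or schedule, and the
final-epoch weights are the enrolled model.

Evaluation covers both biometric scenarios. *Identification* (closed set):
Rank-1 accuracy, the percentage of test segments whose highest-scoring
identity is the true one. *Authentication*: every test segment claims every
enrolled identity in turn; the match score of a claim is the posterior
probability the classifier assigns to the claimed class. Claims of the true
identity are genuine trials, all others impostor trials, and sweeping an
acceptance threshold over the pooled scores yields FAR/FRR curves, the DET
curve, and the equal error rate at their crossing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .augment import SegmentedDataset
from .model import ICAConvNet

__all__ = [
    "TrainConfig",
    "TrainResult",
    "ScoreSet",
    "EvalReport",
    "train",
    "rank1",
    "score_claims",
    "compute_eer",
    "evaluate",
    "plot_det",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults: the published recipe)."""

    learning_rate: float = 3e-3
    batch_size: int = 64
    epochs: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainResult:
    """Final network plus the per-epoch trace of loss and accuracy."""

    network: ICAConvNet
    trace: list[dict]

    def trace_to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(self.trace[0].keys()))
            writer.writeheader()
            writer.writerows(self.trace)


@dataclass
class ScoreSet:
    """Genuine and impostor claim scores (posterior probabilities in [0, 1])."""

    genuine: np.ndarray
    impostor: np.ndarray

    def __post_init__(self) -> None:
        self.genuine = np.asarray(self.genuine, dtype=np.float64)
        self.impostor = np.asarray(self.impostor, dtype=np.float64)


@dataclass
class EvalReport:
    """Identification and authentication metrics for one evaluation run.

    All rates are percentages. ``thresholds``, ``far_curve`` and ``frr_curve``
    trace the full sweep; ``det_points`` pairs them as (FAR, FRR).
    """

    rank1: float
    eer: float
    eer_threshold: float
    thresholds: np.ndarray
    far_curve: np.ndarray
    frr_curve: np.ndarray
    n_test: int = 0
    n_genuine: int = 0
    n_impostor: int = 0

    @property
    def det_points(self) -> np.ndarray:
        return np.column_stack([self.far_curve, self.frr_curve])

    def summary_dict(self) -> dict:
        return {
            "rank1_percent": self.rank1,
            "eer_percent": self.eer,
            "eer_threshold": self.eer_threshold,
            "n_test": self.n_test,
            "n_genuine": self.n_genuine,
            "n_impostor": self.n_impostor,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=2))

    def curves_to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["threshold", "far_percent", "frr_percent"])
            writer.writerows(
                zip(self.thresholds, self.far_curve, self.frr_curve)
            )


def train(
    network: ICAConvNet,
    train_set: SegmentedDataset,
    cfg: TrainConfig,
    eval_set: SegmentedDataset | None = None,
    eval_every: int = 0,
) -> TrainResult:
    """Run exactly ``cfg.epochs`` passes over seeded-shuffled batches.

    The trace records each epoch's mean batch loss and training accuracy
    (computed from the train-mode forward outputs), plus test Rank-1 every
    ``eval_every`` epochs when an ``eval_set`` is given. Identical seeds and
    inputs give identical traces on one platform.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    x, y = train_set.arrays(dtype=network.dtype)
    o = train_set.n_classes
    if network.cfg.n_classes != o:
        raise ValueError(
            f"network has {network.cfg.n_classes} classes but the training set "
            f"enrolls {o} subjects"
        )
    present = np.unique(y)
    if len(present) != o:
        raise ValueError(
            f"training labels must cover all {o} classes; missing "
            f"{sorted(set(range(o)) - set(present.tolist()))}"
        )
    opt = nn.Adam(network.params(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    trace: list[dict] = []
    for epoch in range(cfg.epochs):
        perm = shuffle_rng.permutation(len(x))
        losses: list[float] = []
        correct = 0
        for i in range(0, len(x), cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            logp = network.forward(x[idx], train=True)
            losses.append(nn.nll_loss(logp, y[idx]))
            correct += int((logp.argmax(axis=1) == y[idx]).sum())
            network.zero_grad()
            network.backward(logp, y[idx])
            opt.step()
        row = {
            "epoch": epoch + 1,
            "loss": float(np.mean(losses)),
            "train_accuracy": 100.0 * correct / len(x),
        }
        if eval_set is not None and eval_every and (epoch + 1) % eval_every == 0:
            row["test_rank1"] = rank1(network, eval_set)
        trace.append(row)
    return TrainResult(network=network, trace=trace)


def _check_closed_set(network: ICAConvNet, test_set: SegmentedDataset) -> None:
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    if test_set.n_classes > network.cfg.n_classes:
        raise ValueError(
            "closed-set system: test set enrolls more subjects than the network"
        )


def rank1(network: ICAConvNet, test_set: SegmentedDataset) -> float:
    """Percent of test segments whose top-scoring class is the true class.

    Ties at the maximum break toward the lowest class index.
    """
    _check_closed_set(network, test_set)
    x, y = test_set.arrays(dtype=network.dtype)
    logp = network.predict_logp(x)
    return 100.0 * float((logp.argmax(axis=1) == y).mean())


def score_claims(network: ICAConvNet, test_set: SegmentedDataset) -> ScoreSet:
    """Score every (segment, claimed identity) pair.

    The claim score is the posterior probability of the claimed class, so each
    segment contributes one genuine score (its true identity) and O-1 impostor
    scores; per segment the O claim scores sum to 1.
    """
    _check_closed_set(network, test_set)
    x, y = test_set.arrays(dtype=network.dtype)
    probs = np.exp(network.predict_logp(x).astype(np.float64))
    idx = np.arange(len(y))
    genuine = probs[idx, y]
    mask = np.ones_like(probs, dtype=bool)
    mask[idx, y] = False
    return ScoreSet(genuine=genuine, impostor=probs[mask])


def compute_eer(scores: ScoreSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Sweep all distinct scores as acceptance thresholds.

    At threshold t, FAR(t) = % impostor scores >= t and FRR(t) = % genuine
    scores < t, so FAR is non-increasing and FRR non-decreasing in t. The EER
    is read off at the FAR = FRR crossing, linearly interpolating both curves
    between the bracketing pair of thresholds.

    Returns (thresholds, far_curve, frr_curve, eer, eer_threshold), rates in
    percent.
    """
    gen, imp = scores.genuine, scores.impostor
    if gen.size == 0 or imp.size == 0:
        raise ValueError("both genuine and impostor score lists must be nonempty")
    all_scores = np.concatenate([gen, imp])
    thresholds = np.unique(all_scores)
    # sentinel above every score: FAR 0, FRR 100 — guarantees a crossing
    thresholds = np.append(thresholds, thresholds[-1] + 1.0)
    imp_sorted = np.sort(imp)
    gen_sorted = np.sort(gen)
    far = 100.0 * (imp.size - np.searchsorted(imp_sorted, thresholds, side="left")) / imp.size
    frr = 100.0 * np.searchsorted(gen_sorted, thresholds, side="left") / gen.size
    diff = far - frr
    i = int(np.argmax(diff <= 0))  # first threshold where FAR <= FRR
    if diff[i] == 0 or i == 0:
        eer, eer_t = far[i], thresholds[i]
    else:
        d0, d1 = diff[i - 1], diff[i]
        t = d0 / (d0 - d1)
        eer = far[i - 1] + t * (far[i] - far[i - 1])
        eer_t = thresholds[i - 1] + t * (thresholds[i] - thresholds[i - 1])
    return thresholds, far, frr, float(eer), float(eer_t)


def evaluate(network: ICAConvNet, test_set: SegmentedDataset) -> EvalReport:
    """Full report: Rank-1 plus the FAR/FRR sweep, EER and DET points."""
    r1 = rank1(network, test_set)
    scores = score_claims(network, test_set)
    thresholds, far, frr, eer, eer_t = compute_eer(scores)
    return EvalReport(
        rank1=r1,
        eer=eer,
        eer_threshold=eer_t,
        thresholds=thresholds,
        far_curve=far,
        frr_curve=frr,
        n_test=len(test_set),
        n_genuine=scores.genuine.size,
        n_impostor=scores.impostor.size,
    )


def plot_det(
    reports: dict[str, EvalReport] | EvalReport, path: str | Path
) -> Path:
    """Render DET curves (FRR against FAR as the threshold varies)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(reports, EvalReport):
        reports = {"": reports}
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, rep in reports.items():
        ax.plot(rep.far_curve, rep.frr_curve, label=label or None)
        ax.plot([rep.eer], [rep.eer], "o", ms=4)
    ax.set_xlabel("FAR (%)")
    ax.set_ylabel("FRR (%)")
    ax.set_title("DET curve")
    if any(reports.keys()):
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
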