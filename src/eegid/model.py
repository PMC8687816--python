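"""The ICAConvNet: a channel-mixing CNN for closed-set EEG identification.

The network embodies the blind-source-separation view of scalp EEG: the
observed channels X are assumed to be a linear mixture A·S of latent cortical
sources S, so the first stage is a learnable separation matrix W applied to
every time-point's channel vector (Y = W·X), trained end-to-end with the
rest of the network rather than by a classical ICA contrast. Three
convolution blocks then extract temporal features of the unmixed sources,
and two fully connected layers with dropout emit log-normalized class scores
over the enrolled identities.

Stage by stage, for an input plane of P time-points x C channels:

    input (1, P, C)
    channel mix  C -> S sources           -> (1, P, S)
    conv 1->32, 5x3, stride (2,1), pad (2,1), ELU   -> (32, P/2, S)
    maxpool 2x1                                      -> (32, P/4, S)
    conv 32->32, 3x3, stride 1, pad 1, ELU           -> (32, P/4, S)
    maxpool 1x2                                      -> (32, P/4, S/2)
    conv 32->32, 3x3, stride 1, pad 1, ELU           -> (32, P/4, S/2)
    maxpool 2x1                                      -> (32, P/8, S/2)
    flatten -> fully connected -> 512 -> dropout 0.5 -> fully connected -> O
    log-softmax over the O identities

with S = 64 sources by default, so the flatten width is 32 · (P/8) · 32.
P must be divisible by 8 (three temporal halvings).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["ModelConfig", "ICAConvNet", "build_model", "forward", "loss"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the selected values of the published recipe: 64 latent
    sources, 32 feature maps per convolution block, a 512-unit hidden layer
    and dropout 0.5.
    """

    n_channels: int
    n_points: int
    n_classes: int
    n_sources: int = 64
    conv_width: int = 32
    fc_width: int = 512
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        if self.n_points % 8 != 0:
            raise ValueError(
                f"n_points={self.n_points} must be divisible by 8 "
                "(three temporal halvings)"
            )
        if self.n_sources % 2 != 0:
            raise ValueError("n_sources must be even (one width halving)")
        for name in ("n_channels", "n_points", "n_classes", "n_sources",
                     "conv_width", "fc_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")

    @property
    def flatten_width(self) -> int:
        return self.conv_width * (self.n_points // 8) * (self.n_sources // 2)


class ICAConvNet:
    """The assembled network; build with :func:`build_model`."""

    def __init__(self, cfg: ModelConfig, seed: int, dtype=np.float32):
        self.cfg = cfg
        self.seed = seed
        self.dtype = np.dtype(dtype).type
        init_rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 1]))
        w = cfg.conv_width
        self.stack = nn.Sequential([
            nn.ChannelMix(cfg.n_channels, cfg.n_sources, init_rng, self.dtype),
            nn.Conv2d(1, w, (5, 3), (2, 1), (2, 1), init_rng, self.dtype, "conv1"),
            nn.ELU(),
            nn.MaxPool2d((2, 1)),
            nn.Conv2d(w, w, (3, 3), (1, 1), (1, 1), init_rng, self.dtype, "conv2"),
            nn.ELU(),
            nn.MaxPool2d((1, 2)),
            nn.Conv2d(w, w, (3, 3), (1, 1), (1, 1), init_rng, self.dtype, "conv3"),
            nn.ELU(),
            nn.MaxPool2d((2, 1)),
            nn.Flatten(),
            nn.Linear(cfg.flatten_width, cfg.fc_width, init_rng, self.dtype, "fc1"),
            nn.Dropout(cfg.dropout_p, self.dropout_rng),
            nn.Linear(cfg.fc_width, cfg.n_classes, init_rng, self.dtype, "fc2"),
        ])

    # -- forward / backward -------------------------------------------------
    def _check_shape(self, batch: np.ndarray) -> None:
        expected = (1, self.cfg.n_points, self.cfg.n_channels)
        if batch.ndim != 4 or batch.shape[1:] != expected:
            raise ValueError(
                f"expected batch of shape (B, {expected[0]}, {expected[1]}, "
                f"{expected[2]}); got {batch.shape}"
            )

    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        """Log-normalized class scores, one row per segment.

        The public tensor convention is (B, 1, P, C); internally the layers
        run channels-last ((B, P, C, planes)) for speed. Evaluation mode (the
        default) disables dropout and is deterministic.
        """
        self._check_shape(batch)
        x = batch.astype(self.dtype, copy=False).transpose(0, 2, 3, 1)
        scores = self.stack.forward(x, train=train)
        return nn.log_softmax(scores)

    def intermediate_shapes(self, batch_size: int = 1) -> list[tuple[int, ...]]:
        """Per-layer output shapes in the conventional (B, maps, H, W) order.

        For the published configuration (P=80, C=64, S=64, O=109) this walks
        (B,1,80,64) -> (B,1,80,64) -> (B,32,40,64) -> ... -> (B,10240) ->
        (B,512) -> (B,109).
        """
        x = np.zeros(
            (batch_size, self.cfg.n_points, self.cfg.n_channels, 1), dtype=self.dtype
        )
        shapes: list[tuple[int, ...]] = [
            (batch_size, 1, self.cfg.n_points, self.cfg.n_channels)
        ]
        for layer in self.stack.layers:
            x = layer.forward(x)
            if x.ndim == 4:  # channels-last -> report channels-first
                b, h, w, f = x.shape
                shapes.append((b, f, h, w))
            else:
                shapes.append(x.shape)
        return shapes

    def backward(self, logp: np.ndarray, labels: np.ndarray) -> None:
        """Accumulate gradients of the mean cross-entropy into the params."""
        self.stack.backward(nn.nll_loss_grad(logp, labels))

    def zero_grad(self) -> None:
        self.stack.zero_grad()

    def params(self) -> list[nn.Param]:
        return self.stack.params()

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    def predict_logp(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode log-scores over an arbitrary number of segments."""
        return np.concatenate(
            [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        )

    # -- checkpointing ------------------------------------------------------
    def save(
        self,
        path: str | Path,
        label_map: dict[str, int] | None = None,
        stats: dict | None = None,
    ) -> Path:
        """One-file checkpoint: weights + config (+ label map, subject stats).

        Reloading restores bit-identical evaluation outputs.
        """
        path = Path(path)
        meta = {
            "format_version": 1,
            "config": asdict(self.cfg),
            "seed": self.seed,
            "dtype": np.dtype(self.dtype).name,
            "label_map": label_map,
            "stats": stats,
        }
        arrays = {p.name.replace(".", "_"): p.value for p in self.params()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> tuple["ICAConvNet", dict | None, dict | None]:
        with np.load(Path(path)) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            net = cls(
                ModelConfig(**meta["config"]),
                seed=meta["seed"],
                dtype=np.dtype(meta.get("dtype", "float32")),
            )
            for p in net.params():
                p.value[...] = archive[p.name.replace(".", "_")]
        return net, meta["label_map"], meta["stats"]


def build_model(cfg: ModelConfig, seed: int, dtype=np.float32) -> ICAConvNet:
    """Construct the network; identical seeds give identical initial weights."""
    return ICAConvNet(cfg, seed, dtype=dtype)


def forward(network: ICAConvNet, batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode log-scores (functional alias for network.forward)."""
    return network.forward(batch, train=False)


def loss(log_scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of log-normalized scores against integer labels."""
    return nn.nll_loss(log_scores, labels)
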