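"""Model optimization: binary cross-entropy, Adam, and the training loop.

Training follows the link-prediction recipe: the co-participation graph
and the reaction hypergraph are built from the *positive training
reactions only*, and every labeled sample (positive or substitution
negative) is scored against that fixed topology.  Adam updates all weight
matrices and the metabolite embedding table jointly under the binary
cross-entropy loss, with shuffled mini-batches each epoch.

Defaults: learning rate 5e-4, up to 100 epochs with early stopping when
the epoch-mean training loss plateaus (patience 10, min-delta 1e-4),
batch size 256 (full batch when fewer samples).
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor
from .gem_io import MetabolicNetwork, ValidationError, merge_universe
from .model import (
    Hyperparams,
    ModelState,
    VARIANTS,
    forward_scores,
    init_model,
    topology_fingerprint,
)
from .sampling import LabeledSample
from .topology import build_graph, build_hypergraph

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Adam",
    "bce_loss",
    "train_model",
    "set_global_seed",
]

_SCORE_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    epochs: int = 100
    batch_size: int = 256
    seed: int = 0
    variant: str = "full"
    early_stopping_patience: int = 10
    early_stopping_min_delta: float = 1e-4

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch size must be >= 1")
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class TrainHistory:
    losses: list[float] = field(default_factory=list)
    validation: Optional[list] = None

    @property
    def epochs_run(self) -> int:
        return len(self.losses)


class Adam:
    """Adam with beta = (0.9, 0.999), eps 1e-8 and a constant rate."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 5e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mean binary cross-entropy; scores at 0 or 1 are clamped at 1e-7."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if s.size == 0 or s.shape != y.shape:
        raise ValidationError("scores and labels must be equal-length and non-empty")
    s = np.clip(s, _SCORE_EPS, 1.0 - _SCORE_EPS)
    return float(-np.mean(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)))


def bce_loss_tensor(scores: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable BCE for a (batch, 1) score tensor."""
    y = labels.reshape(-1, 1).astype(np.float64)
    s = scores.clip(_SCORE_EPS, 1.0 - _SCORE_EPS)
    return -(Tensor(y) * s.log() + Tensor(1.0 - y) * (1.0 - s).log()).mean()


def set_global_seed(seed: int) -> dict:
    """Seed Python and NumPy global RNGs; returns a manifest entry.

    The pipeline itself threads explicit ``numpy.random.Generator``
    objects, so this is defense in depth for any library-internal
    randomness.
    """
    random.seed(seed)
    np.random.seed(seed % (2**32 - 1))
    return {"seed": int(seed)}


def train_model(
    network: MetabolicNetwork,
    samples: Sequence[LabeledSample],
    pool: Optional[MetabolicNetwork] = None,
    hp: Optional[Hyperparams] = None,
    cfg: Optional[TrainConfig] = None,
) -> tuple[ModelState, TrainHistory]:
    """Train GHCN-SE on labeled reaction samples.

    The node universe is the network's, extended by pool-only metabolites
    when a candidate pool is supplied (those nodes get embeddings but stay
    isolated in both topologies).
    """
    hp = hp or Hyperparams()
    cfg = cfg or TrainConfig()
    labels = np.array([s.label for s in samples])
    if len(set(labels.tolist())) < 2:
        raise ValidationError("training needs both positive and negative samples")
    universe = merge_universe(network, pool) if pool is not None else network
    positives = [s.reaction for s in samples if s.label == 1]
    graph = build_graph(positives, universe)
    hyper = build_hypergraph(positives, universe)

    state = init_model(universe.n, len(positives), hp, cfg.seed, variant=cfg.variant)
    index = universe.index_map()
    state.metabolite_index = index
    state.topology_fingerprint = topology_fingerprint(graph, hyper)

    member_lists = []
    for s in samples:
        try:
            member_lists.append([index[mid] for mid in sorted(s.reaction.members)])
        except KeyError as exc:
            raise ValidationError(
                f"sample {s.reaction.id!r} references unknown metabolite {exc.args[0]!r}"
            ) from None

    opt = Adam(state.trainable(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    best = np.inf
    stale = 0
    n_samples = len(samples)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n_samples)
        epoch_losses = []
        for start in range(0, n_samples, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch_members = [member_lists[i] for i in idx]
            scores = forward_scores(state, graph, hyper, batch_members, training=True)
            loss = bce_loss_tensor(scores, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        mean_loss = float(np.mean(epoch_losses))
        history.losses.append(mean_loss)
        if mean_loss < best - cfg.early_stopping_min_delta:
            best = mean_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stopping_patience:
                break
    return state, history
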