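"""The GHCN-SE scoring network.

Architecture
------------
Every metabolite node i carries a learnable embedding ``x0_i`` in R^N0,
initialized from a standard normal and updated during training.  Two
branches extract topological features over the co-participation graph and
the reaction hypergraph:

* **GCN branch** — a linear adaptation ``x1 = ReLU(W1 x0 + b1)`` followed
  by two rounds of row-normalized propagation
  ``x^(k+1)_i = ReLU(W2^(k) X^(k) A1[:, i] + b2^(k))`` with
  ``A1 = D^-1 (A + I)``, producing ``Z1`` (n x N2);
* **HGCN branch** — an input MLP ``x2 = BatchNorm(W4 ReLU(W3 x0 + b3))``
  (per-channel batch normalization over all n nodes), then a two-stage
  hypergraph convolution ``Y = H^T Dv^{-1/2} X2`` (node -> hyperedge) and
  ``Z2 = ReLU(Dv^{-1/2} H W5 Dr^{-1} Y)`` (hyperedge -> node), with W5 a
  learnable hyperedge-mixing matrix initialized to the identity.

Fusion concatenates the branches per node, ``z3 = W6 (z1 || z2) + b6``.

For each candidate reaction the squeeze-and-excitation block squeezes by
averaging z3 over the reaction's members, excites through the bottleneck
``s1 = sigmoid(W8 ReLU(W7 s0))``, rescales each member embedding
channel-wise and layer-normalizes it (no learned affine terms).  The head
averages the enhanced member vectors, applies ``ReLU(W9 . + b9)`` and a
final sigmoid-ed linear layer to yield a confidence score in (0, 1).

Ablation variants zero out one component: ``no_gcn`` feeds zeros for Z1,
``no_hgcn`` zeros for Z2, and ``no_se`` replaces the SE rescaling with a
plain layer normalization of z3 (W7/W8 are then absent from the state).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, concat
from .gem_io import Reaction, ValidationError
from .topology import GraphTopology, HypergraphTopology

__all__ = [
    "Hyperparams",
    "ModelState",
    "ScoredReaction",
    "init_model",
    "gcn_forward",
    "hgcn_forward",
    "fuse_features",
    "se_enhance",
    "score_reaction",
    "forward",
    "forward_scores",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA = 1
# float64 pipeline: a 1e-6 epsilon keeps standardized rows within 1e-4 of
# unit variance for any realistic feature scale
_LAYERNORM_EPS = 1e-6
_BATCHNORM_EPS = 1e-5
_BATCHNORM_MOMENTUM = 0.1

VARIANTS = ("full", "no_gcn", "no_hgcn", "no_se")


@dataclass(frozen=True)
class Hyperparams:
    """Layer widths and the classification threshold.

    N0 embedding, N1 adaptation, N2 GCN output, N3 HGCN/fusion width,
    N4 SE bottleneck (N4 < N3), N5 head width.
    """

    n0: int = 256
    n1: int = 128
    n2: int = 128
    n3: int = 128
    n4: int = 16
    n5: int = 64
    classification_threshold: float = 0.5

    def __post_init__(self):
        widths = (self.n0, self.n1, self.n2, self.n3, self.n4, self.n5)
        if any(w < 1 for w in widths):
            raise ValidationError(f"all layer widths must be >= 1, got {widths}")
        if self.n4 > self.n3:
            raise ValidationError("SE bottleneck N4 must not exceed N3")
        if not 0.0 < self.classification_threshold < 1.0:
            raise ValidationError("classification threshold must lie in (0, 1)")


@dataclass(frozen=True)
class ScoredReaction:
    reaction_id: str
    members: frozenset[str]
    score: float


@dataclass
class ModelState:
    """All learnable tensors plus batch-norm running statistics."""

    params: dict[str, Tensor]
    hp: Hyperparams
    n: int
    m_train: int
    variant: str = "full"
    bn_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bn_var: np.ndarray = field(default_factory=lambda: np.ones(0))
    metabolite_index: Optional[dict[str, int]] = None
    topology_fingerprint: str = ""

    def trainable(self) -> list[Tensor]:
        return [t for t in self.params.values() if t.requires_grad]

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()


def _kaiming_uniform(rng: np.random.Generator, out_dim: int, in_dim: int) -> np.ndarray:
    bound = np.sqrt(6.0 / in_dim)
    return rng.uniform(-bound, bound, size=(out_dim, in_dim))


def init_model(
    n: int, m_train: int, hp: Hyperparams, seed: int, variant: str = "full"
) -> ModelState:
    """Initialize embeddings ~ N(0,1) and fan-in-scaled uniform weights.

    W5 starts at the identity so the untrained HGCN branch is a plain
    degree-normalized hypergraph convolution.  Variant states omit the
    parameters of the removed component.
    """
    if n < 1 or m_train < 1:
        raise ValidationError(f"n and m_train must be positive, got n={n}, m_train={m_train}")
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    rng = np.random.default_rng(seed)
    p: dict[str, Tensor] = {}

    def learn(name: str, arr: np.ndarray) -> None:
        p[name] = Tensor(arr, requires_grad=True)

    learn("embeddings", rng.standard_normal((n, hp.n0)))
    if variant != "no_gcn":
        learn("W1", _kaiming_uniform(rng, hp.n1, hp.n0))
        learn("b1", np.zeros(hp.n1))
        learn("W2_0", _kaiming_uniform(rng, hp.n2, hp.n1))
        learn("b2_0", np.zeros(hp.n2))
        learn("W2_1", _kaiming_uniform(rng, hp.n2, hp.n2))
        learn("b2_1", np.zeros(hp.n2))
    if variant != "no_hgcn":
        learn("W3", _kaiming_uniform(rng, hp.n2, hp.n0))
        learn("b3", np.zeros(hp.n2))
        learn("W4", _kaiming_uniform(rng, hp.n3, hp.n2))
        learn("W5", np.eye(m_train))
    learn("W6", _kaiming_uniform(rng, hp.n3, hp.n2 + hp.n3))
    learn("b6", np.zeros(hp.n3))
    if variant != "no_se":
        learn("W7", _kaiming_uniform(rng, hp.n4, hp.n3))
        learn("W8", _kaiming_uniform(rng, hp.n3, hp.n4))
    learn("W9", _kaiming_uniform(rng, hp.n5, hp.n3))
    learn("b9", np.zeros(hp.n5))
    learn("W10", _kaiming_uniform(rng, 1, hp.n5))
    learn("b10", np.zeros(1))
    return ModelState(
        params=p,
        hp=hp,
        n=n,
        m_train=m_train,
        variant=variant,
        bn_mean=np.zeros(hp.n3),
        bn_var=np.ones(hp.n3),
    )


# ---------------------------------------------------------------------------
# forward building blocks


def _layernorm_rows(x: Tensor) -> Tensor:
    """Per-row standardization without learned affine terms."""
    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(axis=1, keepdims=True)
    return xc / (var + _LAYERNORM_EPS).sqrt()


def _batchnorm(x: Tensor, state: ModelState, training: bool) -> Tensor:
    """Per-channel normalization over all n nodes; running stats in eval."""
    if training:
        mu = x.mean(axis=0, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=0, keepdims=True)
        out = xc / (var + _BATCHNORM_EPS).sqrt()
        m = _BATCHNORM_MOMENTUM
        state.bn_mean = (1 - m) * state.bn_mean + m * mu.data.ravel()
        state.bn_var = (1 - m) * state.bn_var + m * var.data.ravel()
        return out
    return (x - state.bn_mean[None, :]) / np.sqrt(state.bn_var[None, :] + _BATCHNORM_EPS)


def gcn_forward(state: ModelState, graph: GraphTopology) -> Tensor:
    """Adaptation projection plus two propagation rounds; returns Z1 (n x N2)."""
    p = state.params
    if graph.propagation.shape[0] != state.n:
        raise ValidationError(
            f"graph has {graph.propagation.shape[0]} nodes but model expects {state.n}"
        )
    X1 = (p["embeddings"] @ p["W1"].T + p["b1"]).relu()
    # node i aggregates column i of A1: row-major that is A1^T @ X
    P = Tensor(graph.propagation.T)
    h = (P @ X1 @ p["W2_0"].T + p["b2_0"]).relu()
    return (P @ h @ p["W2_1"].T + p["b2_1"]).relu()


def hgcn_forward(state: ModelState, hyper: HypergraphTopology, training: bool = False) -> Tensor:
    """Input MLP + batch norm, then two-stage hypergraph convolution (Z2, n x N3)."""
    p = state.params
    if hyper.n != state.n:
        raise ValidationError(f"hypergraph has {hyper.n} nodes but model expects {state.n}")
    if hyper.m != state.m_train:
        raise ValidationError(
            f"W5 is sized for {state.m_train} hyperedges but hypergraph has {hyper.m}"
        )
    pre = ((p["embeddings"] @ p["W3"].T + p["b3"]).relu()) @ p["W4"].T
    X2 = _batchnorm(pre, state, training)
    dv = np.where(hyper.node_degree > 0, hyper.node_degree, 1.0)
    dr = np.where(hyper.edge_degree > 0, hyper.edge_degree, 1.0)
    B = hyper.incidence / np.sqrt(dv)[:, None]  # Dv^{-1/2} H, constant
    Y = Tensor(B.T) @ X2  # (m, N3): hyperedge features
    Y = Y * (1.0 / dr)[:, None]  # Dr^{-1} Y
    return (Tensor(B) @ (p["W5"] @ Y)).relu()


def fuse_features(state: ModelState, Z1: Tensor, Z2: Tensor) -> Tensor:
    """Per-node linear fusion of the two branches: Z3 = [Z1 || Z2] W6^T + b6."""
    if Z1.shape[0] != Z2.shape[0]:
        raise ValidationError("branch outputs disagree on node count")
    p = state.params
    return concat([Z1, Z2], axis=1) @ p["W6"].T + p["b6"]


def se_enhance(state: ModelState, Z3: Tensor, members: Sequence[int]) -> Tensor:
    """Squeeze-and-excitation over one reaction's member set.

    Returns the enhanced, layer-normalized member embeddings (|members| x N3).
    """
    idx = sorted(int(i) for i in members)
    if not idx:
        raise ValidationError("SE block needs a non-empty member set")
    if min(idx) < 0 or max(idx) >= Z3.shape[0]:
        raise ValidationError("member index out of range")
    Zm = Z3.take(idx)
    if state.variant == "no_se":
        return _layernorm_rows(Zm)
    p = state.params
    s0 = Zm.mean(axis=0, keepdims=True)  # squeeze: (1, N3)
    s1 = ((s0 @ p["W7"].T).relu() @ p["W8"].T).sigmoid()  # excitation
    return _layernorm_rows(Zm * s1)  # scale + LayerNorm


def score_reaction(state: ModelState, z4_members: Tensor) -> Tensor:
    """Average-pool enhanced member vectors and map to a confidence in (0,1)."""
    if z4_members.shape[0] < 1:
        raise ValidationError("cannot score a reaction with no member vectors")
    p = state.params
    pooled = z4_members.mean(axis=0, keepdims=True)
    r = (pooled @ p["W9"].T + p["b9"]).relu()
    return (r @ p["W10"].T + p["b10"]).sigmoid()


# ---------------------------------------------------------------------------
# composed forward pass


def _node_features(
    state: ModelState,
    graph: GraphTopology,
    hyper: HypergraphTopology,
    training: bool,
) -> Tensor:
    hp = state.hp
    if state.variant == "no_gcn":
        Z1 = Tensor(np.zeros((state.n, hp.n2)))
    else:
        Z1 = gcn_forward(state, graph)
    if state.variant == "no_hgcn":
        Z2 = Tensor(np.zeros((state.n, hp.n3)))
    else:
        Z2 = hgcn_forward(state, hyper, training=training)
    return fuse_features(state, Z1, Z2)


def forward_scores(
    state: ModelState,
    graph: GraphTopology,
    hyper: HypergraphTopology,
    member_index_lists: Sequence[Sequence[int]],
    training: bool = False,
) -> Tensor:
    """Score a batch of reactions given member node-index lists.

    The node-level branches run once; the SE block and head are evaluated
    for all reactions in one vectorized pass over the flattened
    (reaction, member) pairs.  Returns a (batch, 1) tensor of scores.
    """
    if not member_index_lists:
        raise ValidationError("empty reaction batch")
    Z3 = _node_features(state, graph, hyper, training)
    p = state.params
    sizes = np.array([len(mem) for mem in member_index_lists])
    if np.any(sizes == 0):
        raise ValidationError("a reaction in the batch has no members")
    batch = len(member_index_lists)
    mem_idx = np.concatenate([np.sort(np.asarray(mem, dtype=np.intp)) for mem in member_index_lists])
    if mem_idx.min() < 0 or mem_idx.max() >= state.n:
        raise ValidationError("member index out of range")
    rxn_idx = np.repeat(np.arange(batch), sizes)
    # (batch, pairs) mean-pooling matrix, row k holds 1/|Mk| on k's pairs
    pool = np.zeros((batch, mem_idx.size))
    pool[rxn_idx, np.arange(mem_idx.size)] = 1.0 / sizes[rxn_idx]
    Zm = Z3.take(mem_idx)  # (pairs, N3)
    if state.variant == "no_se":
        z4 = _layernorm_rows(Zm)
    else:
        s0 = Tensor(pool) @ Zm  # squeeze per reaction
        s1 = ((s0 @ p["W7"].T).relu() @ p["W8"].T).sigmoid()
        z4 = _layernorm_rows(Zm * s1.take(rxn_idx))
    r = (Tensor(pool) @ z4 @ p["W9"].T + p["b9"]).relu()
    return (r @ p["W10"].T + p["b10"]).sigmoid()


def forward(
    state: ModelState,
    graph: GraphTopology,
    hyper: HypergraphTopology,
    batch: Sequence[Reaction],
    training: bool = False,
) -> list[ScoredReaction]:
    """Score reactions (by metabolite id) with the composed network."""
    if state.metabolite_index is None:
        raise ValidationError("model state carries no metabolite index map")
    member_lists = []
    for r in batch:
        try:
            member_lists.append([state.metabolite_index[mid] for mid in sorted(r.members)])
        except KeyError as exc:
            raise ValidationError(
                f"reaction {r.id!r} uses metabolite {exc.args[0]!r} unknown to the "
                "trained index map; retrain with a merged universe"
            ) from None
    scores = forward_scores(state, graph, hyper, member_lists, training=training)
    return [
        ScoredReaction(reaction_id=r.id, members=r.members, score=float(s))
        for r, s in zip(batch, scores.data.ravel())
    ]


# ---------------------------------------------------------------------------
# checkpointing


def topology_fingerprint(graph: GraphTopology, hyper: HypergraphTopology) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(graph.adjacency).tobytes())
    h.update(np.ascontiguousarray(hyper.incidence).tobytes())
    return h.hexdigest()[:16]


def save_checkpoint(state: ModelState, path: str | Path) -> None:
    """Serialize tensors, hyperparameters and the metabolite index map."""
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "hp": state.hp.__dict__,
        "n": state.n,
        "m_train": state.m_train,
        "variant": state.variant,
        "metabolite_ids": (
            None
            if state.metabolite_index is None
            else [mid for mid, _ in sorted(state.metabolite_index.items(), key=lambda kv: kv[1])]
        ),
        "topology_fingerprint": state.topology_fingerprint,
    }
    arrays = {k: t.data for k, t in state.params.items()}
    arrays["__bn_mean"] = state.bn_mean
    arrays["__bn_var"] = state.bn_var
    np.savez(path, __meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> ModelState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta"]).decode())
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ValidationError(f"unsupported checkpoint schema {meta['schema']}")
        params = {
            k: Tensor(data[k], requires_grad=True)
            for k in data.files
            if not k.startswith("__")
        }
        state = ModelState(
            params=params,
            hp=Hyperparams(**meta["hp"]),
            n=meta["n"],
            m_train=meta["m_train"],
            variant=meta["variant"],
            bn_mean=np.array(data["__bn_mean"]),
            bn_var=np.array(data["__bn_var"]),
            topology_fingerprint=meta.get("topology_fingerprint", ""),
        )
    ids = meta.get("metabolite_ids")
    if ids is not None:
        state.metabolite_index = {mid: i for i, mid in enumerate(ids)}
    return state
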