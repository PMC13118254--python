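"""Graph and hypergraph construction from positive reactions.

Two complementary views of the same reaction set over a fixed metabolite
universe:

* the **co-participation graph** — every reaction becomes a clique over
  its members; ``A`` is the binary, symmetric, zero-diagonal adjacency and
  the propagation matrix is ``A1 = D^-1 (A + I)`` (row-normalized
  adjacency with self loops);
* the **reaction hypergraph** — the binary incidence ``H`` (n x m) with
  one column per reaction, plus node and hyperedge degree vectors.

Both are built from *positive training reactions only*: held-out
reactions and candidates are scored against this topology but never
contribute edges.

Isolated nodes (pool-only or candidate-only metabolites) have degree 0;
every inverse or inverse square root substitutes degree 1 for them, so an
isolated node's propagation row is a unit self-pass-through and no NaNs
enter the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .gem_io import MetabolicNetwork, Reaction, ValidationError

__all__ = ["GraphTopology", "HypergraphTopology", "build_graph", "build_hypergraph"]


@dataclass
class GraphTopology:
    adjacency: np.ndarray  # (n, n) binary symmetric, zero diagonal
    degree: np.ndarray  # (n,)
    propagation: np.ndarray  # (n, n)  A1 = D^-1 (A + I)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def export_coordinates(self, path: str | Path) -> None:
        """Write non-zero adjacency entries as `i j` coordinate text."""
        ii, jj = np.nonzero(self.adjacency)
        with open(path, "w") as fh:
            fh.write(f"# adjacency n={self.n}\n")
            for i, j in zip(ii, jj):
                fh.write(f"{i} {j}\n")


@dataclass
class HypergraphTopology:
    incidence: np.ndarray  # (n, m) binary
    node_degree: np.ndarray  # (n,)
    edge_degree: np.ndarray  # (m,)

    @property
    def n(self) -> int:
        return self.incidence.shape[0]

    @property
    def m(self) -> int:
        return self.incidence.shape[1]

    def export_coordinates(self, path: str | Path) -> None:
        ii, jj = np.nonzero(self.incidence)
        with open(path, "w") as fh:
            fh.write(f"# incidence n={self.n} m={self.m}\n")
            for i, j in zip(ii, jj):
                fh.write(f"{i} {j}\n")


def _member_indices(reactions: Sequence[Reaction], universe: MetabolicNetwork) -> list[list[int]]:
    index = universe.index_map()
    out = []
    for r in reactions:
        try:
            out.append(sorted(index[mid] for mid in r.members))
        except KeyError as exc:
            raise ValidationError(
                f"reaction {r.id!r} references metabolite {exc.args[0]!r} "
                "absent from the universe"
            ) from None
    return out


def build_graph(reactions: Sequence[Reaction], universe: MetabolicNetwork) -> GraphTopology:
    """Clique-expand reactions into the binary co-participation graph."""
    n = universe.n
    A = np.zeros((n, n), dtype=np.float64)
    for members in _member_indices(reactions, universe):
        for i, j in combinations(members, 2):
            A[i, j] = 1.0
            A[j, i] = 1.0
    degree = A.sum(axis=1)
    d_safe = np.where(degree > 0, degree, 1.0)  # isolated-node convention
    propagation = (A + np.eye(n)) / d_safe[:, None]
    return GraphTopology(adjacency=A, degree=degree, propagation=propagation)


def build_hypergraph(
    reactions: Sequence[Reaction], universe: MetabolicNetwork
) -> HypergraphTopology:
    """Build the binary incidence matrix; column order follows reaction order."""
    if len(reactions) == 0:
        raise ValidationError("hypergraph needs at least one reaction")
    n = universe.n
    H = np.zeros((n, len(reactions)), dtype=np.float64)
    for j, members in enumerate(_member_indices(reactions, universe)):
        H[members, j] = 1.0
    return HypergraphTopology(
        incidence=H,
        node_degree=H.sum(axis=1),
        edge_degree=H.sum(axis=0),
    )
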