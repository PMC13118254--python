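"""GEM input/output and the internal metabolic-network data model.

A genome-scale metabolic model (GEM) is reduced here to pure topology:
an ordered universe of compartmentalized metabolites (the graph /
hypergraph nodes) and a list of reactions, each a *set* of participant
metabolite ids.  Stoichiometric coefficients, substrate/product roles and
reversibility are discarded at parse time — the downstream graph and
hypergraph constructions are undirected and binary, so participation is
the only information they consume.

Parsing of the standard formats (BiGG JSON and SBML Level 3) is delegated
to cobrapy.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import cobra
from cobra.io import load_json_model, read_sbml_model, save_json_model

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "ValidationError",
    "load_model_file",
    "load_universal_pool",
    "merge_universe",
    "write_bigg_json",
]

SourceLabel = Literal["model", "pool", "synthetic", "negative"]

_COMPARTMENT_SUFFIX = re.compile(r"^(?P<base>.*)_(?P<comp>[a-zA-Z0-9]+)$")


class ValidationError(ValueError):
    """A network or sample violates a structural contract."""


@dataclass(frozen=True)
class Metabolite:
    """A compartmentalized metabolite; one node of the network.

    The same chemical species in two compartments (e.g. ``glc__D_c`` and
    ``glc__D_e``) is two distinct nodes.
    """

    id: str
    base_id: str = ""
    compartment: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if not self.base_id:
            m = _COMPARTMENT_SUFFIX.match(self.id)
            base, comp = (m.group("base"), m.group("comp")) if m else (self.id, "")
            object.__setattr__(self, "base_id", base)
            if not self.compartment:
                object.__setattr__(self, "compartment", comp)


@dataclass(frozen=True)
class Reaction:
    """A reaction as the set of its participant metabolites (a hyperedge)."""

    id: str
    members: frozenset[str]
    source_label: SourceLabel = "model"

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"reaction {self.id!r} has no participant metabolites")


@dataclass
class MetabolicNetwork:
    """Ordered metabolite universe plus reaction list.

    Metabolite positions define the node indices 0..n-1 used by every
    matrix downstream, so the order is part of the contract.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    name: str = ""

    def __post_init__(self):
        if not self.metabolites:
            raise ValidationError("network must contain at least one metabolite")
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate metabolite ids in universe")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ValidationError("duplicate reaction ids")
        universe = set(ids)
        for r in self.reactions:
            missing = r.members - universe
            if missing:
                raise ValidationError(
                    f"reaction {r.id!r} references unknown metabolite(s): {sorted(missing)}"
                )

    @property
    def n(self) -> int:
        return len(self.metabolites)

    @property
    def m(self) -> int:
        return len(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def index_map(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def member_sets(self) -> set[frozenset[str]]:
        return {r.members for r in self.reactions}


# ---------------------------------------------------------------------------
# parsing


def _from_cobra(model: cobra.Model, source_label: SourceLabel, name: str) -> MetabolicNetwork:
    metabolites = [
        Metabolite(id=met.id, compartment=met.compartment or "")
        for met in model.metabolites
    ]
    reactions = []
    for rxn in model.reactions:
        members = frozenset(met.id for met in rxn.metabolites)
        if not members:
            raise ValidationError(f"reaction {rxn.id!r} has an empty participant list")
        reactions.append(Reaction(id=rxn.id, members=members, source_label=source_label))
    return MetabolicNetwork(metabolites=metabolites, reactions=reactions, name=name)


def _sniff_format(path: Path) -> str:
    if path.suffix.lower() == ".json":
        return "bigg_json"
    if path.suffix.lower() in {".xml", ".sbml"}:
        return "sbml"
    head = path.read_bytes()[:512].lstrip()
    return "bigg_json" if head.startswith(b"{") else "sbml"


def load_model_file(
    path: str | Path,
    format_hint: Literal["bigg_json", "sbml", "auto"] = "auto",
) -> MetabolicNetwork:
    """Load a GEM from BiGG JSON or SBML into a :class:`MetabolicNetwork`.

    Reaction members are the union of substrates and products with
    stoichiometric coefficients dropped; reversibility is ignored.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"model file not found: {path}")
    fmt = _sniff_format(path) if format_hint == "auto" else format_hint
    try:
        if fmt == "bigg_json":
            cobra_model = load_json_model(str(path))
        elif fmt == "sbml":
            cobra_model = read_sbml_model(str(path))
        else:
            raise ValidationError(f"unknown format hint {fmt!r}")
    except ValidationError:
        raise
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise IOError(f"failed to parse {path} as {fmt}: {exc}") from exc
    name = cobra_model.id or path.stem
    return _from_cobra(cobra_model, "model", name)


def load_universal_pool(path: str | Path) -> MetabolicNetwork:
    """Load a universal candidate-reaction pool (same formats as a GEM)."""
    net = load_model_file(path)
    if not net.reactions:
        raise ValidationError(f"candidate pool {path} contains no reactions")
    return MetabolicNetwork(
        metabolites=net.metabolites,
        reactions=[
            Reaction(id=r.id, members=r.members, source_label="pool") for r in net.reactions
        ],
        name=net.name,
    )


def merge_universe(model: MetabolicNetwork, pool: MetabolicNetwork) -> MetabolicNetwork:
    """Model metabolites followed by pool-only metabolites; model reactions.

    Establishes the global node indexing shared by all tensors: a model
    metabolite keeps its index, pool-only metabolites are appended in the
    pool's order.
    """
    known = set(model.metabolite_ids)
    merged = list(model.metabolites) + [m for m in pool.metabolites if m.id not in known]
    return MetabolicNetwork(
        metabolites=merged,
        reactions=list(model.reactions),
        name=model.name or "merged",
    )


# ---------------------------------------------------------------------------
# writing


def write_bigg_json(
    network: MetabolicNetwork,
    path: str | Path,
    annotations: Optional[dict[str, dict]] = None,
) -> None:
    """Write a network as BiGG JSON (via cobrapy).

    Members carry coefficient -1.0: roles are not represented in the
    internal model, and the downstream constructions ignore them anyway.
    ``annotations`` maps reaction id -> notes dict (e.g. gap-fill provenance).
    """
    model = cobra.Model(network.name or "network")
    mets = {}
    for met in network.metabolites:
        cm = cobra.Metabolite(met.id, compartment=met.compartment or "c")
        mets[met.id] = cm
    model.add_metabolites(list(mets.values()))
    rxns = []
    for r in network.reactions:
        cr = cobra.Reaction(r.id)
        rxns.append(cr)
    model.add_reactions(rxns)
    for r, cr in zip(network.reactions, rxns):
        cr.add_metabolites({mets[mid]: -1.0 for mid in sorted(r.members)})
        if annotations and r.id in annotations:
            cr.notes.update(annotations[r.id])
    save_json_model(model, str(path))
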