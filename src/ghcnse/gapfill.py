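"""Gap-filling: score a universal candidate pool and select reactions.

A trained model assigns a confidence score to every pool reaction whose
member set is not already present in the GEM; candidates are ranked by
descending score and selected either by top-k or by a score threshold.
Selection here uses confidence alone; a pluggable secondary score can be
supplied for re-ranking schemes that combine additional evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Optional, Sequence

from .gem_io import MetabolicNetwork, Reaction, ValidationError, write_bigg_json
from .model import ModelState, ScoredReaction, forward
from .topology import GraphTopology, HypergraphTopology

__all__ = ["GapfillProposal", "score_candidate_pool", "select_gapfill_reactions", "apply_gapfill"]


@dataclass
class GapfillProposal:
    ranked: list[ScoredReaction]
    selected: list[ScoredReaction]
    provenance: dict = field(default_factory=dict)

    def to_table(self) -> list[str]:
        lines = ["reaction_id\tmembers\tscore\tselected"]
        chosen = {sr.reaction_id for sr in self.selected}
        for sr in self.ranked:
            lines.append(
                f"{sr.reaction_id}\t{';'.join(sorted(sr.members))}\t{sr.score:.6f}"
                f"\t{int(sr.reaction_id in chosen)}"
            )
        return lines

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.write_text("\n".join(self.to_table()) + "\n")
        path.with_suffix(".provenance.json").write_text(json.dumps(self.provenance, indent=2))


def score_candidate_pool(
    state: ModelState,
    graph: GraphTopology,
    hyper: HypergraphTopology,
    pool: MetabolicNetwork,
    model: MetabolicNetwork,
) -> list[ScoredReaction]:
    """Score every pool reaction absent from the GEM; sort descending.

    Fails with a named metabolite if the pool reaches outside the trained
    index map (the model must have been trained on the merged universe).
    """
    if state.metabolite_index is None:
        raise ValidationError("model state carries no metabolite index map")
    gem_sets = model.member_sets()
    candidates = [r for r in pool.reactions if r.members not in gem_sets]
    for r in candidates:
        for mid in r.members:
            if mid not in state.metabolite_index:
                raise ValidationError(
                    f"pool metabolite {mid!r} (reaction {r.id!r}) is absent from the "
                    "trained index map; retrain with the merged model+pool universe"
                )
    if not candidates:
        return []
    scored = forward(state, graph, hyper, candidates)
    return sorted(scored, key=lambda sr: (-sr.score, sr.reaction_id))


def select_gapfill_reactions(
    ranked: Sequence[ScoredReaction],
    mode: Literal["top_k", "threshold"] = "top_k",
    value: float = 25,
    secondary_score: Optional[Callable[[ScoredReaction], float]] = None,
    provenance: Optional[dict] = None,
) -> GapfillProposal:
    """Select candidates by top-k count or confidence threshold."""
    ranked = list(ranked)
    if any(
        ranked[i].score < ranked[i + 1].score for i in range(len(ranked) - 1)
    ):
        raise ValidationError("ranked list must be sorted by descending score")
    if secondary_score is not None:
        ranked = sorted(ranked, key=lambda sr: (-secondary_score(sr), sr.reaction_id))
    if mode == "top_k":
        k = int(value)
        if k <= 0:
            raise ValidationError("top_k selection needs k >= 1")
        selected = ranked[:k]
    elif mode == "threshold":
        if not 0.0 < value < 1.0:
            raise ValidationError("threshold must lie in (0, 1)")
        selected = [sr for sr in ranked if sr.score >= value]
    else:
        raise ValidationError(f"unknown selection mode {mode!r}")
    return GapfillProposal(ranked=ranked, selected=selected, provenance=provenance or {})


def apply_gapfill(
    model: MetabolicNetwork,
    proposal: GapfillProposal,
    out_path: Optional[str | Path] = None,
    tool: str = "ghcnse",
) -> MetabolicNetwork:
    """Add selected reactions to the GEM; optionally export BiGG JSON.

    Added reactions carry a provenance note (tool, score, checkpoint hash).
    """
    existing_ids = {r.id for r in model.reactions}
    new_reactions = list(model.reactions)
    annotations: dict[str, dict] = {}
    for sr in proposal.selected:
        rid = sr.reaction_id
        while rid in existing_ids:
            rid = rid + "_gf"
        existing_ids.add(rid)
        new_reactions.append(Reaction(id=rid, members=sr.members, source_label="pool"))
        annotations[rid] = {
            "gapfill_tool": tool,
            "gapfill_score": round(sr.score, 6),
            "gapfill_checkpoint": proposal.provenance.get("checkpoint_hash", ""),
        }
    pool_only = {mid for sr in proposal.selected for mid in sr.members}
    known = set(model.metabolite_ids)
    from .gem_io import Metabolite

    metabolites = list(model.metabolites) + [
        Metabolite(id=mid) for mid in sorted(pool_only - known)
    ]
    filled = MetabolicNetwork(
        metabolites=metabolites, reactions=new_reactions, name=model.name
    )
    if out_path is not None:
        write_bigg_json(filled, out_path, annotations=annotations)
    return filled
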