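"""Negative sampling, cross-validation folds, and the recovery test set.

Negative reactions are formed by single-metabolite substitution: one
member drawn uniformly from the reaction is replaced by a metabolite
drawn uniformly from the rest of the universe.  The resulting member set
has the same size as the positive's and differs from it in exactly two
elements (one out, one in).  The dataset keeps a 1:1 positive:negative
ratio, and stratified 5-fold splitting yields a 4:1 train:test ratio with
balanced classes on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .gem_io import MetabolicNetwork, Reaction, ValidationError

__all__ = [
    "LabeledSample",
    "FoldSplit",
    "corrupt_reaction",
    "generate_negative_set",
    "stratified_folds",
    "assemble_recovery_testset",
]

logger = logging.getLogger(__name__)

_MAX_COLLISION_RETRIES = 100


@dataclass(frozen=True)
class LabeledSample:
    reaction: Reaction
    label: int  # 1 positive, 0 negative

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValidationError("label must be 0 or 1")


@dataclass
class FoldSplit:
    fold_index: int
    train: list[LabeledSample]
    test: list[LabeledSample]


def corrupt_reaction(
    reaction: Reaction, universe: MetabolicNetwork, rng: np.random.Generator
) -> Reaction:
    """Swap one uniformly chosen member for a uniformly chosen outsider."""
    members = sorted(reaction.members)
    outside = [mid for mid in universe.metabolite_ids if mid not in reaction.members]
    if not outside:
        raise ValidationError(
            f"universe too small to corrupt reaction {reaction.id!r}: "
            "no replacement metabolite available"
        )
    removed = members[rng.integers(len(members))]
    replacement = outside[rng.integers(len(outside))]
    new_members = (reaction.members - {removed}) | {replacement}
    return Reaction(id=f"{reaction.id}__neg", members=new_members, source_label="negative")


def generate_negative_set(
    positives: Sequence[Reaction], universe: MetabolicNetwork, seed: int
) -> list[LabeledSample]:
    """One substitution negative per positive (1:1 ratio).

    A negative whose member set coincides with any positive's is resampled
    up to a bounded number of times, then accepted with a warning.
    """
    if not positives:
        raise ValidationError("no positive reactions to corrupt")
    rng = np.random.default_rng(seed)
    positive_sets = {r.members for r in positives}
    out: list[LabeledSample] = []
    for k, pos in enumerate(positives):
        neg = corrupt_reaction(pos, universe, rng)
        retries = 0
        while neg.members in positive_sets and retries < _MAX_COLLISION_RETRIES:
            neg = corrupt_reaction(pos, universe, rng)
            retries += 1
        if neg.members in positive_sets:
            logger.warning(
                "negative for %s still collides with a positive after %d retries; keeping it",
                pos.id,
                _MAX_COLLISION_RETRIES,
            )
        out.append(
            LabeledSample(
                reaction=Reaction(
                    id=f"{pos.id}__neg{k}", members=neg.members, source_label="negative"
                ),
                label=0,
            )
        )
    return out


def stratified_folds(
    samples: Sequence[LabeledSample], k: int = 5, seed: int = 0
) -> list[FoldSplit]:
    """Class-stratified k-fold partition of a balanced sample list."""
    n_pos = sum(s.label == 1 for s in samples)
    n_neg = sum(s.label == 0 for s in samples)
    if n_pos != n_neg:
        raise ValidationError(f"class imbalance: {n_pos} positives vs {n_neg} negatives")
    if k < 2:
        raise ValidationError("k-fold split requires k >= 2")
    if min(n_pos, n_neg) < k:
        raise ValidationError(f"need at least {k} samples per class for {k} folds")
    labels = np.array([s.label for s in samples])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32 - 1))
    folds = []
    for fold_index, (train_idx, test_idx) in enumerate(skf.split(labels, labels)):
        folds.append(
            FoldSplit(
                fold_index=fold_index,
                train=[samples[i] for i in train_idx],
                test=[samples[i] for i in test_idx],
            )
        )
    return folds


def assemble_recovery_testset(
    test_positives: Sequence[Reaction],
    pool: MetabolicNetwork,
    model: MetabolicNetwork,
) -> list[LabeledSample]:
    """Test positives plus every pool reaction not already in the GEM.

    Pool-vs-GEM identity is by member set, not by reaction id.
    """
    if not pool.reactions:
        raise ValidationError("candidate pool is empty")
    gem_sets = model.member_sets()
    out = [LabeledSample(reaction=r, label=1) for r in test_positives]
    out.extend(
        LabeledSample(reaction=r, label=0)
        for r in pool.reactions
        if r.members not in gem_sets
    )
    return out


def samples_to_table(samples: Sequence[LabeledSample], fold: int | None = None) -> list[str]:
    """Serialize samples as tab-separated lines: id, members, label, fold."""
    rows = []
    for s in samples:
        rows.append(
            "\t".join(
                [
                    s.reaction.id,
                    ";".join(sorted(s.reaction.members)),
                    str(s.label),
                    "" if fold is None else str(fold),
                ]
            )
        )
    return rows
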