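"""Shared domain types and the bait-target score collapse.

Every pairwise evidence channel in the platform produces (bait, target,
score) triples, where baits are members of a curated reference set of
known spindle proteins and targets are arbitrary proteome members.  The
platform reduces those triples to a single best score per target before
converting scores to empirical p-values; that collapse, together with
the proteome registry and reference-set bookkeeping, lives here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple


class SpipError(Exception):
    """Base class for platform errors."""


class NoScore(SpipError):
    """Raised when a scorer cannot produce a defined score.

    Distinct from a score of zero: zero means "no supporting signal",
    NoScore means "the quantity is undefined for this input" (isolated
    node, missing family, degenerate variance, ...).
    """


class ScoredPair(NamedTuple):
    """One bait-target prediction from a pairwise method."""

    bait: str
    target: str
    method: str
    score: float


@dataclass(frozen=True)
class ProteomeRegistry:
    """The universe of protein identifiers scores are defined over.

    Identifiers are opaque tokens compared by exact string equality; no
    accession mapping or isoform logic is applied.
    """

    proteins: frozenset[str]

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError("registry must contain at least one protein")
        if any(not p for p in self.proteins):
            raise ValueError("empty protein identifier in registry")

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "ProteomeRegistry":
        return cls(frozenset(ids))

    @property
    def size(self) -> int:
        return len(self.proteins)

    def __contains__(self, pid: str) -> bool:
        return pid in self.proteins


@dataclass(frozen=True)
class ReferenceSet:
    """A named curated set of known positives (e.g. SEED, EXPERT)."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_ids(cls, name: str, ids: Iterable[str]) -> "ReferenceSet":
        return cls(name, frozenset(ids))

    def validate(self, registry: ProteomeRegistry) -> None:
        stray = self.members - registry.proteins
        if stray:
            raise ValueError(
                f"reference set {self.name!r} has members outside the "
                f"registry: {sorted(stray)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, pid: str) -> bool:
        return pid in self.members


@dataclass
class TargetScoreList:
    """Per-target best scores for one evidence channel.

    ``scores`` holds exactly one entry per detected target; targets a
    method never detected are absent, not zero-filled.  ``n_baits``
    records how many bait pairs contributed to each target (diagnostic
    metadata only; ties do not change the collapsed score).
    """

    method: str
    scores: dict[str, float] = field(default_factory=dict)
    higher_is_better: bool = True
    n_baits: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.scores)

    def items(self):
        return self.scores.items()


def collapse_pairs(
    pairs: Iterable[ScoredPair], higher_is_better: bool = True
) -> TargetScoreList:
    """Collapse bait-target pairs to one best score per target.

    Each target is scored by the extreme score over all pairs in which
    it was detected (maximum when higher is better, minimum otherwise).
    An empty input yields an empty list.  Mixed method tags or
    non-finite scores are rejected.
    """
    pairs = list(pairs)
    if not pairs:
        return TargetScoreList(method="", higher_is_better=higher_is_better)
    methods = {p.method for p in pairs}
    if len(methods) > 1:
        raise ValueError(f"mixed method tags in collapse: {sorted(methods)}")
    best: dict[str, float] = {}
    counts: dict[str, int] = {}
    pick = max if higher_is_better else min
    for p in pairs:
        if not math.isfinite(p.score):
            raise ValueError(f"non-finite score for pair {p.bait}-{p.target}")
        if p.target in best:
            best[p.target] = pick(best[p.target], p.score)
            counts[p.target] += 1
        else:
            best[p.target] = p.score
            counts[p.target] = 1
    return TargetScoreList(
        method=methods.pop(),
        scores=best,
        higher_is_better=higher_is_better,
        n_baits=counts,
    )


def combine_reference_sets(
    a: ReferenceSet,
    b: ReferenceSet,
    registry: ProteomeRegistry | None = None,
    name: str | None = None,
) -> tuple[ReferenceSet, int]:
    """Union two reference sets; returns the union and the overlap size.

    Two disjoint curated sets of 149 and 73 known spindle proteins, for
    instance, combine into a 223-member set with overlap 0.
    """
    if registry is not None:
        a.validate(registry)
        b.validate(registry)
    overlap = len(a.members & b.members)
    combined = ReferenceSet(
        name=name or f"{a.name}+{b.name}", members=a.members | b.members
    )
    return combined, overlap


def scores_to_pairs(
    scores: Mapping[str, float], bait: str, method: str
) -> list[ScoredPair]:
    """Convenience inverse used by single-bait scorers."""
    return [ScoredPair(bait, t, method, s) for t, s in scores.items()]
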