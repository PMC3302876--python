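"""Homology-inherited protein-protein interaction (interolog) scoring.

Protein families are sub-clustered at 11 nested sequence-identity
levels ("S-levels", numbered 1-11 for identity thresholds from 0% up to
100%).  A known interaction between A1 and B1 is inherited by a
candidate pair (A2, B2) from the same two families; the inherited score
is the mean of the S-levels at which each candidate shares a cluster
with its evidence protein, so inheritance from close homologues (high
shared S-level) outweighs inheritance from remote ones.  Supporting
interactions seen with several independent experiment types or in
several species earn a halving bonus series on top of the base score,
and a candidate pair supported by several distinct known interactions
sums their contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .core import NoScore, ReferenceSet, ScoredPair, TargetScoreList, collapse_pairs

N_LEVELS = 11


@dataclass(frozen=True)
class KnownInteraction:
    """An experimentally observed interaction with its provenance."""

    a: str
    b: str
    evidence_types: frozenset[str]
    species: frozenset[str]

    def __post_init__(self) -> None:
        if not self.evidence_types or not self.species:
            raise ValueError("known interaction needs >=1 evidence type and species")


@dataclass
class FamilyClustering:
    """Family membership plus per-protein cluster IDs at the 11 S-levels.

    Clusters must nest: two proteins sharing a cluster at level L share
    one at every level below L.  Level 1 is the family itself (0%
    identity threshold), so within a family two proteins always share
    at least the level-1 cluster.
    """

    family_of: dict[str, str] = field(default_factory=dict)
    levels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def add(self, protein: str, family: str, cluster_ids: Iterable[str]) -> None:
        ids = tuple(cluster_ids)
        if len(ids) != N_LEVELS:
            raise ValueError(
                f"{protein!r}: expected {N_LEVELS} cluster IDs, got {len(ids)}"
            )
        if protein in self.family_of:
            raise ValueError(f"duplicate clustering row for {protein!r}")
        self.family_of[protein] = family
        self.levels[protein] = ids

    def validate_nesting(self) -> None:
        """Same cluster at level L must imply same cluster at all lower levels."""
        by_family: dict[str, list[str]] = {}
        for p, fam in self.family_of.items():
            by_family.setdefault(fam, []).append(p)
        for members in by_family.values():
            for i, p in enumerate(members):
                for q in members[i + 1 :]:
                    shared = [
                        self.levels[p][k] == self.levels[q][k] for k in range(N_LEVELS)
                    ]
                    top = max((k for k, s in enumerate(shared) if s), default=-1)
                    if top >= 0 and not all(shared[: top + 1]):
                        raise ValueError(
                            f"non-nested clusters for {p!r}/{q!r}"
                        )

    def members(self, family: str) -> list[str]:
        return sorted(p for p, f in self.family_of.items() if f == family)


def slevel_of(
    clustering: FamilyClustering, inheritor: str, evidence_protein: str
) -> int:
    """Highest S-level (1-11) at which the two proteins share a cluster.

    A protein shares the top cluster (level 11) with itself.  Proteins
    from different families have no shared cluster: NoScore.
    """
    fam_i = clustering.family_of.get(inheritor)
    fam_e = clustering.family_of.get(evidence_protein)
    if fam_i is None or fam_e is None or fam_i != fam_e:
        raise NoScore(
            f"{inheritor!r} and {evidence_protein!r} are not in the same family"
        )
    if inheritor == evidence_protein:
        return N_LEVELS
    li = clustering.levels[inheritor]
    le = clustering.levels[evidence_protein]
    level = 0
    for k in range(N_LEVELS):
        if li[k] == le[k]:
            level = k + 1
        else:
            break
    if level == 0:
        raise NoScore(
            f"{inheritor!r} and {evidence_protein!r} share no cluster"
        )
    return level


def base_inherit_score(level_a: int, level_b: int) -> float:
    """Mean of the two shared S-levels; e.g. levels (9, 7) -> 8."""
    for lvl in (level_a, level_b):
        if not 1 <= lvl <= N_LEVELS:
            raise ValueError(f"S-level {lvl} outside 1..{N_LEVELS}")
    return (level_a + level_b) / 2.0


def evidence_bonus(base: float, n_evidence_types: int, n_species: int) -> float:
    """Total score after the halving bonus series.

    Beyond the first evidence type and first species, each extra unit
    (extra evidence types counted first, then extra species) adds half
    of the previous increment: base 8 with a second source adds 4; a
    second species then adds a further 2.
    """
    if n_evidence_types < 1 or n_species < 1:
        raise ValueError("need at least one evidence type and one species")
    extras = (n_evidence_types - 1) + (n_species - 1)
    total = base
    step = base
    for _ in range(extras):
        step /= 2.0
        total += step
    return total


def _supports(
    a_i: str,
    b_j: str,
    clustering: FamilyClustering,
    known: Iterable[KnownInteraction],
) -> list[tuple[KnownInteraction, int, int]]:
    """Known interactions whose endpoints are homologous to (a_i, b_j),
    with the shared S-levels, in either endpoint orientation."""
    fam = clustering.family_of
    out = []
    for k in known:
        for ev_a, ev_b in ((k.a, k.b), (k.b, k.a)):
            if fam.get(ev_a) == fam.get(a_i) and fam.get(a_i) is not None and \
               fam.get(ev_b) == fam.get(b_j) and fam.get(b_j) is not None:
                out.append((k, slevel_of(clustering, a_i, ev_a),
                            slevel_of(clustering, b_j, ev_b)))
                break  # one orientation per known pair
    return out


def hippi_pair_score(
    a_i: str,
    b_j: str,
    clustering: FamilyClustering,
    known: Iterable[KnownInteraction],
) -> float:
    """Sum of inherited contributions over all supporting known interactions.

    Each distinct known pair contributes base + bonus computed from its
    own shared S-levels; no support at all raises NoScore.
    """
    supports = _supports(a_i, b_j, clustering, known)
    if not supports:
        raise NoScore(f"no supporting known interaction for ({a_i!r}, {b_j!r})")
    total = 0.0
    for k, lvl_a, lvl_b in supports:
        base = base_inherit_score(lvl_a, lvl_b)
        total += evidence_bonus(base, len(k.evidence_types), len(k.species))
    return total


def hippi_all_pairs(
    clustering: FamilyClustering,
    known: Iterable[KnownInteraction],
    reference: ReferenceSet,
) -> list[ScoredPair]:
    """Every scorable (bait, target) inherited-interaction pair reachable
    from a known interaction through the two families."""
    known = list(known)
    by_family: dict[str, list[str]] = {}
    for p, fam in clustering.family_of.items():
        by_family.setdefault(fam, []).append(p)
    acc: dict[tuple[str, str], float] = {}
    fam = clustering.family_of
    for k in known:
        fam_a, fam_b = fam.get(k.a), fam.get(k.b)
        if fam_a is None or fam_b is None:
            continue
        # For a same-family known pair only one orientation is counted,
        # matching hippi_pair_score's first-matching-orientation rule.
        orientations = [(k.a, k.b)] if fam_a == fam_b else [(k.a, k.b), (k.b, k.a)]
        for ev_bait, ev_target in orientations:
            for bait in by_family[fam[ev_bait]]:
                if bait not in reference.members:
                    continue
                lvl_bait = slevel_of(clustering, bait, ev_bait)
                base_bonus_cache: dict[int, float] = {}
                for target in by_family[fam[ev_target]]:
                    if target in reference.members:
                        continue
                    lvl_t = slevel_of(clustering, target, ev_target)
                    if lvl_t not in base_bonus_cache:
                        base = base_inherit_score(lvl_bait, lvl_t)
                        base_bonus_cache[lvl_t] = evidence_bonus(
                            base, len(k.evidence_types), len(k.species)
                        )
                    key = (bait, target)
                    acc[key] = acc.get(key, 0.0) + base_bonus_cache[lvl_t]
    return [ScoredPair(b, t, "hiPPI", s) for (b, t), s in sorted(acc.items())]


def score_all_hippi(
    clustering: FamilyClustering,
    known: Iterable[KnownInteraction],
    reference: ReferenceSet,
) -> TargetScoreList:
    """Inherited-interaction channel, collapsed to the best score per target."""
    return collapse_pairs(
        hippi_all_pairs(clustering, known, reference), higher_is_better=True
    )
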