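"""Knowledgegram/Predictogram construction and hidden-hub mining.

Two interaction graphs are compared per protein: the KG
("Knowledgegram"), built from experimentally supported edge sources,
and the PG ("Predictogram"), the union of pair-level predictions from
the ab-initio channels (co-expression, inherited interactions, domain
fusion) that pass a p-value gate (default 0.014, a precision-motivated
operating point).  A hidden hub is a protein with few experimentally
known interactions but many predicted ones — at least five times more
PG than KG edges — concentrated on the known-spindle set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

DEFAULT_P_GATE = 0.014
DEFAULT_MIN_RATIO = 5.0
DEFAULT_MAX_KG_DEGREE = 5
DEFAULT_MIN_SPINDLE_FRACTION = 0.5


@dataclass
class EvidenceGraph:
    """Simple undirected graph with per-edge source tags."""

    kind: str  # "KG" or "PG"
    graph: nx.Graph

    @classmethod
    def from_sources(
        cls, kind: str, sources: Mapping[str, Iterable[tuple[str, str]]]
    ) -> "EvidenceGraph":
        g = nx.Graph()
        for tag, edges in sources.items():
            for u, v in edges:
                if u == v:
                    continue
                if g.has_edge(u, v):
                    g[u][v]["sources"].add(tag)
                else:
                    g.add_edge(u, v, sources={tag})
        return cls(kind, g)

    def degree(self, node: str) -> int:
        return self.graph.degree(node) if node in self.graph else 0

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node)) if node in self.graph else set()


def build_pg(
    channel_pairs: Mapping[str, Iterable[tuple[str, str, float]]],
    p_gate: float = DEFAULT_P_GATE,
) -> EvidenceGraph:
    """Union of channel pair predictions with p <= gate, merged simple graph.

    ``channel_pairs`` maps channel name to (protein, protein, p-value)
    triples; an edge predicted by several channels keeps one edge with
    the union of source tags.
    """
    if not 0 < p_gate <= 1:
        raise ValueError("p-value gate must lie in (0, 1]")
    sources = {
        chan: [(u, v) for u, v, p in triples if p <= p_gate]
        for chan, triples in channel_pairs.items()
    }
    return EvidenceGraph.from_sources("PG", sources)


def build_kg(
    sources: Mapping[str, Iterable[tuple[str, str]]]
) -> EvidenceGraph:
    """Merge experimental edge sources into the Knowledgegram."""
    return EvidenceGraph.from_sources("KG", sources)


def select_top_fraction(targets_in_rank_order: Sequence[str], fraction: float = 0.02) -> list[str]:
    """Top floor(fraction * n) targets of a ranked list (2% of 32,145 -> 642)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(len(targets_in_rank_order) * fraction)
    return list(targets_in_rank_order[:k])


@dataclass
class DegreeRecord:
    """Connectivity of one candidate in the two graphs."""

    protein: str
    kg_degree: int
    pg_degree: int
    spindle_degree_pg: int

    @property
    def spindle_fraction(self) -> float:
        """PG-edge fraction landing on known spindle proteins; NaN at degree 0."""
        if self.pg_degree == 0:
            return math.nan
        return self.spindle_degree_pg / self.pg_degree


def degree_stats(
    candidates: Sequence[str],
    kg: EvidenceGraph,
    pg: EvidenceGraph,
    spindle_set: Iterable[str],
) -> list[DegreeRecord]:
    """KG/PG degrees plus spindle-specific PG connectivity per candidate."""
    spindle = set(spindle_set)
    records = []
    for c in candidates:
        pg_neigh = pg.neighbors(c)
        records.append(
            DegreeRecord(
                protein=c,
                kg_degree=kg.degree(c),
                pg_degree=len(pg_neigh),
                spindle_degree_pg=len(pg_neigh & spindle),
            )
        )
    return records


def hidden_hub_rank(
    records: Iterable[DegreeRecord],
    min_ratio: float = DEFAULT_MIN_RATIO,
    max_kg_degree: int = DEFAULT_MAX_KG_DEGREE,
    min_spindle_fraction: float = DEFAULT_MIN_SPINDLE_FRACTION,
) -> list[DegreeRecord]:
    """Filter and rank hidden-hub candidates.

    Keep records with kg_degree <= max_kg_degree, pg_degree >=
    min_ratio * max(kg_degree, 1) (the 5x rule, with KG degree 0
    floored at 1 so fully unknown proteins are not divided by zero),
    and spindle_fraction >= min_spindle_fraction.  Rank by PG degree
    descending, then spindle fraction descending, then identifier.
    """
    kept = [
        r
        for r in records
        if r.kg_degree <= max_kg_degree
        and r.pg_degree >= min_ratio * max(r.kg_degree, 1)
        and not math.isnan(r.spindle_fraction)
        and r.spindle_fraction >= min_spindle_fraction
    ]
    kept.sort(key=lambda r: (-r.pg_degree, -r.spindle_fraction, r.protein))
    return kept
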