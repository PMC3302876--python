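"""Resnik semantic similarity (GOSS) over an annotation ontology.

Terms form a DAG of is-a relations rooted at a single term.  A term's
probability p(c) is the fraction of annotated proteins annotated to the
term or any of its descendants; its information content is -ln p(c).
The Resnik similarity of two terms is the information content of their
most informative common ancestor (MICA), and two proteins compare by
aggregating term-level similarities across their annotation sets
(default aggregation: the maximum, matching the platform-wide
best-score convention; best-match-average is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .core import NoScore, ReferenceSet, TargetScoreList


@dataclass
class AnnotationDAG:
    """Ontology DAG (edges child -> parent) plus protein annotations."""

    graph: nx.DiGraph
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _p: dict[str, float] = field(default_factory=dict, repr=False)
    _sim_cache: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    @classmethod
    def build(
        cls,
        edges: Iterable[tuple[str, str]],
        annotations: Mapping[str, Iterable[str]],
    ) -> "AnnotationDAG":
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("annotation graph contains a cycle")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected a single root, found {sorted(roots)}")
        dag = cls(graph=g)
        for prot, terms in annotations.items():
            terms = frozenset(terms)
            unknown = [t for t in terms if t not in g]
            if unknown:
                raise ValueError(f"{prot!r} annotated to unknown terms {unknown}")
            dag.annotations[prot] = terms
        dag._index()
        return dag

    @property
    def root(self) -> str:
        return next(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    def _index(self) -> None:
        # ancestors include the term itself (a term is its own common ancestor)
        for t in self.graph.nodes:
            self._ancestors[t] = frozenset(nx.descendants(self.graph, t)) | {t}
        total = len(self.annotations)
        if total == 0:
            raise ValueError("no annotated proteins")
        counts: dict[str, int] = {t: 0 for t in self.graph.nodes}
        for terms in self.annotations.values():
            covered: set[str] = set()
            for t in terms:
                covered |= self._ancestors[t]
            for t in covered:
                counts[t] += 1
        self._p = {t: counts[t] / total for t in counts}

    def ancestors(self, term: str) -> frozenset[str]:
        return self._ancestors[term]

    def p(self, term: str) -> float:
        return self._p[term]


def information_content(dag: AnnotationDAG, term: str) -> float:
    """IC(c) = -ln p(c); zero at the root, NoScore for unannotated terms."""
    if term not in dag.graph:
        raise KeyError(f"unknown term {term!r}")
    p = dag.p(term)
    if p == 0:
        raise NoScore(f"term {term!r} annotates no protein (p = 0)")
    return -math.log(p)


def resnik_term_sim(dag: AnnotationDAG, t1: str, t2: str) -> float:
    """IC of the most informative common ancestor of t1 and t2."""
    key = (t1, t2) if t1 <= t2 else (t2, t1)
    cached = dag._sim_cache.get(key)
    if cached is not None:
        return cached
    common = dag.ancestors(t1) & dag.ancestors(t2)
    best = 0.0
    for c in common:
        p = dag.p(c)
        if 0 < p < 1:
            best = max(best, -math.log(p))
        # p == 1 (the root or an all-covering term) contributes IC 0
    dag._sim_cache[key] = best
    return best


def goss_protein_sim(
    dag: AnnotationDAG, prot1: str, prot2: str, aggregation: str = "max"
) -> float:
    """Aggregate Resnik similarity across two proteins' annotation sets."""
    for p in (prot1, prot2):
        if p not in dag.annotations or not dag.annotations[p]:
            raise NoScore(f"protein {p!r} has no annotations")
    terms1 = dag.annotations[prot1]
    terms2 = dag.annotations[prot2]
    sims = [[resnik_term_sim(dag, a, b) for b in terms2] for a in terms1]
    if aggregation == "max":
        return max(max(row) for row in sims)
    if aggregation == "bma":
        # best-match average, symmetrized
        fwd = sum(max(row) for row in sims) / len(terms1)
        rev = sum(max(sims[i][j] for i in range(len(terms1)))
                  for j in range(len(terms2))) / len(terms2)
        return (fwd + rev) / 2.0
    raise ValueError(f"unknown aggregation {aggregation!r}")


def score_all_goss(
    dag: AnnotationDAG,
    reference: ReferenceSet,
    aggregation: str = "max",
) -> TargetScoreList:
    """Best protein-level similarity of each annotated non-reference
    protein to any reference member; zero-similarity proteins (sharing
    only the root with every bait) are treated as undetected."""
    baits = [b for b in sorted(reference.members) if b in dag.annotations]
    out = TargetScoreList(method="GOSS", metadata={"aggregation": aggregation})
    for target in dag.annotations:
        if target in reference.members:
            continue
        best = 0.0
        for b in baits:
            best = max(best, goss_protein_sim(dag, target, b, aggregation))
        if best > 0:
            out.scores[target] = best
    return out
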