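"""Co-citation specificity scoring over a literature interaction network.

The input is an undirected protein-protein network extracted from the
literature in which every edge carries a relation-class tag; only edges
whose relation was classified as "physical" are kept for scoring.  Two
scores are computed against a reference set R of known positives:

* S1 (direct, "d-COCITE") rewards proteins whose direct neighbours are
  specifically reference members rather than promiscuous hubs.
* S2 (indirect, "i-COCITE") does the same for distance-2 contacts
  through connector proteins c.

The exact algebraic combination of the specificity counts is pluggable
(registered functional forms); the default form

    S1 = n_ri^2 / (N_r * N_i)
    S2 = n_rci^2 / (N_r2 * N_c * N_i)

is zero exactly when no (direct / two-hop) reference contact exists,
grows with the number of reference contacts, and shrinks as the protein
or its partners become "sticky" (high total degree).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import networkx as nx

from .core import NoScore, ReferenceSet, TargetScoreList

PHYSICAL = "physical"

# Registered S1 functional forms: f(n_ri, N_r, N_i) -> score.
S1_FORMS: dict[str, Callable[[int, int, int], float]] = {
    "default": lambda n_ri, N_r, N_i: (n_ri * n_ri) / (N_r * N_i) if n_ri else 0.0,
}
# Registered S2 forms: f(n_rci, N_r2, N_c, N_i) -> score.
S2_FORMS: dict[str, Callable[[int, int, int, int], float]] = {
    "default": lambda n, N_r2, N_c, N_i: (n * n) / (N_r2 * N_c * N_i) if n else 0.0,
}


@dataclass
class CocitationNetwork:
    """Simple undirected network with a relation class per edge.

    Multi-edges in the input collapse to simple edges (sentence-level
    multiplicity is not modelled); self-loops are rejected.
    """

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, str]]) -> "CocitationNetwork":
        g = nx.Graph()
        for u, v, rel in edges:
            if not rel:
                raise ValueError(f"untagged edge {u}-{v}")
            if u == v:
                raise ValueError(f"self-loop on {u}")
            # keep "physical" if any duplicate of the edge is physical
            if g.has_edge(u, v) and g[u][v]["relation"] == PHYSICAL:
                continue
            g.add_edge(u, v, relation=rel)
        return cls(g)

    def nodes(self):
        return self.graph.nodes()

    def degree(self, node: str) -> int:
        return self.graph.degree(node)


def filter_physical(network: CocitationNetwork) -> CocitationNetwork:
    """Restrict to edges tagged "physical"; drop isolated endpoints."""
    g = nx.Graph()
    for u, v, data in network.graph.edges(data=True):
        rel = data.get("relation")
        if rel is None:
            raise ValueError(f"untagged edge {u}-{v}")
        if rel == PHYSICAL:
            g.add_edge(u, v, relation=PHYSICAL)
    return CocitationNetwork(g)


def _direct_context(g: nx.Graph, reference: frozenset[str], i: str):
    """(n_ri, N_r, N_i) counted over i's immediate neighbourhood.

    N_r sums degrees over only those reference members actually
    touching i, not over the whole reference set.
    """
    neigh = set(g.neighbors(i))
    touching = neigh & reference
    n_ri = len(touching)
    N_r = sum(g.degree(r) for r in touching)
    N_i = g.degree(i)
    return n_ri, N_r, N_i


def s1_score(
    network: CocitationNetwork,
    reference: ReferenceSet,
    i: str,
    form: str = "default",
) -> float:
    """Direct co-citation specificity of protein i toward the reference set."""
    g = network.graph
    if i not in g:
        raise KeyError(f"protein {i!r} not in network")
    if not reference.members:
        raise ValueError("empty reference set")
    n_ri, N_r, N_i = _direct_context(g, reference.members, i)
    if N_i == 0:
        raise NoScore(f"protein {i!r} is isolated (N_i = 0)")
    if n_ri == 0:
        return 0.0
    return S1_FORMS[form](n_ri, N_r, N_i)


def _indirect_context(g: nx.Graph, reference: frozenset[str], i: str):
    """Length-2 path counts from i into the reference set.

    A connector c is any neighbour of i (other than i) with at least one
    edge to a reference member r != i.  n_rci counts distinct (c, r)
    path pairs; N_c and N_r2 sum degrees over the distinct connectors
    and the distinct reference members reached.
    """
    connectors: set[str] = set()
    reached: set[str] = set()
    n_rci = 0
    for c in g.neighbors(i):
        rs = {r for r in g.neighbors(c) if r in reference and r != i}
        if rs:
            connectors.add(c)
            reached |= rs
            n_rci += len(rs)
    N_c = sum(g.degree(c) for c in connectors)
    N_r2 = sum(g.degree(r) for r in reached)
    return n_rci, N_r2, N_c


def s2_score(
    network: CocitationNetwork,
    reference: ReferenceSet,
    i: str,
    form: str = "default",
) -> float:
    """Indirect (distance = 2) co-citation specificity of protein i."""
    g = network.graph
    if i not in g:
        raise KeyError(f"protein {i!r} not in network")
    if not reference.members:
        raise ValueError("empty reference set")
    N_i = g.degree(i)
    if N_i == 0:
        raise NoScore(f"protein {i!r} is isolated (N_i = 0)")
    n_rci, N_r2, N_c = _indirect_context(g, reference.members, i)
    if n_rci == 0:
        return 0.0
    return S2_FORMS[form](n_rci, N_r2, N_c, N_i)


def score_all_cocite(
    network: CocitationNetwork,
    reference: ReferenceSet,
    form: str = "default",
) -> tuple[TargetScoreList, TargetScoreList]:
    """Score every non-reference node; returns (d-COCITE, i-COCITE) lists.

    Nodes with no direct (resp. two-hop) reference contact are treated
    as undetected by the channel and omitted from the list, mirroring
    the fact that a literature method only predicts proteins it
    actually sees co-cited with the reference set.
    """
    direct = TargetScoreList(method="dCOCITE", metadata={"form": form})
    indirect = TargetScoreList(method="iCOCITE", metadata={"form": form})
    for node in network.graph.nodes():
        if node in reference.members:
            continue
        s1 = s1_score(network, reference, node, form)
        if s1 > 0:
            direct.scores[node] = s1
        s2 = s2_score(network, reference, node, form)
        if s2 > 0:
            indirect.scores[node] = s2
    return direct, indirect
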