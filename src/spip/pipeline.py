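"""End-to-end orchestration: evidence channels -> p-values -> integration.

Runs the seven methods (nine channels: direct and indirect co-citation,
the neural-network predictor, inherited interactions, two domain-fusion
channels from independent annotation vocabularies, domain
over-representation, co-expression and semantic similarity) against a
benchmark bundle, converts each channel's best-per-target scores into
empirical p-values, assembles the prediction matrix and produces the
integrated ranking.  Also exposes the pair-level p-values the
Predictogram construction needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cocite import filter_physical, score_all_cocite
from .core import ScoredPair, TargetScoreList
from .domains import score_all_coda, score_all_dora
from .fixtures import QUERY_GENOME, BenchmarkBundle
from .geco import score_all_geco
from .goss import score_all_goss
from .hippi import score_all_hippi
from .integrate import (
    PredictionMatrix,
    RankedList,
    empirical_pvalue,
    spip_integrate,
)
from .mlnn import score_all_mlnn


def run_channels(bundle: BenchmarkBundle, seed: int = 0) -> dict[str, TargetScoreList]:
    """Score every evidence channel against the bundle's SEED reference."""
    reference = bundle.seed_set
    physical = filter_physical(bundle.cocitation)
    d_cocite, i_cocite = score_all_cocite(physical, reference)
    channels = {
        "dCOCITE": d_cocite,
        "iCOCITE": i_cocite,
        "CODAcath": score_all_coda(
            bundle.arch_cath, QUERY_GENOME, reference, method="CODAcath"
        ),
        "CODApfam": score_all_coda(
            bundle.arch_pfam, QUERY_GENOME, reference, method="CODApfam"
        ),
        "DORA": score_all_dora(bundle.arch_pfam, QUERY_GENOME, reference),
        "GECO": score_all_geco(bundle.expression, reference),
        "GOSS": score_all_goss(bundle.dag(), reference),
        "hiPPI": score_all_hippi(
            bundle.clustering, bundle.known_interactions, reference
        ),
        "MLNN": score_all_mlnn(
            bundle.features, bundle.labels, bundle.similarity, seed=seed
        ),
    }
    return channels


def build_matrix(
    channels: dict[str, TargetScoreList], exclude: frozenset[str] = frozenset()
) -> PredictionMatrix:
    """Empirical p-values per channel, assembled into the prediction matrix.

    ``exclude`` removes reference members (baits) from the target rows.
    """
    pvals = {}
    for name, tsl in channels.items():
        pv = empirical_pvalue(tsl)
        pvals[name] = {t: p for t, p in pv.items() if t not in exclude}
    return PredictionMatrix.from_channels(pvals)


@dataclass
class SpipRun:
    """Result of a full platform run on one bundle."""

    channels: dict[str, TargetScoreList]
    matrix: PredictionMatrix
    ranking: RankedList
    seed: int
    mode: str = "two-stage"
    metadata: dict = field(default_factory=dict)


def run_spip(
    bundle: BenchmarkBundle, seed: int = 0, mode: str = "two-stage"
) -> SpipRun:
    """Full run: channels, prediction matrix, integrated ranking."""
    channels = run_channels(bundle, seed=seed)
    matrix = build_matrix(channels, exclude=bundle.seed_set.members)
    ranking = spip_integrate(matrix, mode=mode)
    return SpipRun(channels=channels, matrix=matrix, ranking=ranking, seed=seed, mode=mode)


def channel_pair_pvalues(
    pairs: list[ScoredPair],
) -> list[tuple[str, str, float]]:
    """Pair-level add-one empirical p-values for one pairwise channel.

    The Predictogram gates pair predictions, not collapsed targets, so
    the cumulative distribution runs over pair scores.
    """
    if not pairs:
        return []
    scores = np.array([p.score for p in pairs], dtype=float)
    order = np.sort(scores)
    n = len(scores)
    geq = n - np.searchsorted(order, scores, side="left")
    pv = (1.0 + geq) / (n + 1.0)
    return [(p.bait, p.target, float(q)) for p, q in zip(pairs, pv)]
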