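"""Gene-expression correlation (GECO) between reference and candidate genes.

Scores are plain Pearson correlations of expression profiles across a
compendium of conditions.  A profile with more than ``max_missing``
missing values (default 5) is masked out entirely; otherwise the
correlation is computed over the conditions observed in both profiles,
requiring at least 3 common observations and non-degenerate variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import NoScore, ReferenceSet, ScoredPair, TargetScoreList, collapse_pairs

DEFAULT_MAX_MISSING = 5


def geco_pair(
    matrix: pd.DataFrame, g1: str, g2: str, max_missing: int = DEFAULT_MAX_MISSING
) -> float:
    """Pearson correlation of two expression profiles, or NoScore.

    NoScore when either profile exceeds the missing-value budget, the
    common support is below 3 conditions, or either profile is constant
    on the common support.
    """
    for g in (g1, g2):
        if g not in matrix.index:
            raise KeyError(f"gene {g!r} not in expression matrix")
    x = matrix.loc[g1].to_numpy(dtype=float)
    y = matrix.loc[g2].to_numpy(dtype=float)
    for g, v in ((g1, x), (g2, y)):
        if np.isnan(v).sum() > max_missing:
            raise NoScore(f"profile {g!r} exceeds {max_missing} missing values")
    mask = ~np.isnan(x) & ~np.isnan(y)
    if mask.sum() < 3:
        raise NoScore(f"fewer than 3 common observations for ({g1!r}, {g2!r})")
    xs, ys = x[mask], y[mask]
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise NoScore(f"zero-variance profile in ({g1!r}, {g2!r})")
    return float(np.corrcoef(xs, ys)[0, 1])


def geco_all_pairs(
    matrix: pd.DataFrame,
    reference: ReferenceSet,
    max_missing: int = DEFAULT_MAX_MISSING,
) -> list[ScoredPair]:
    """All scorable (bait, candidate) correlation pairs.

    Baits outside the matrix, over-missing profiles and degenerate
    pairs simply contribute no pair.
    """
    baits = [b for b in sorted(reference.members) if b in matrix.index]
    pairs: list[ScoredPair] = []
    values = matrix.to_numpy(dtype=float)
    index = list(matrix.index)
    pos = {g: i for i, g in enumerate(index)}
    missing = np.isnan(values).sum(axis=1)
    ok = missing <= max_missing
    for b in baits:
        bi = pos[b]
        if not ok[bi]:
            continue
        bx = values[bi]
        for t in index:
            if t in reference.members:
                continue
            ti = pos[t]
            if not ok[ti]:
                continue
            tx = values[ti]
            mask = ~np.isnan(bx) & ~np.isnan(tx)
            if mask.sum() < 3:
                continue
            xs, ys = bx[mask], tx[mask]
            if xs.std() == 0 or ys.std() == 0:
                continue
            r = float(np.corrcoef(xs, ys)[0, 1])
            pairs.append(ScoredPair(b, t, "GECO", r))
    return pairs


def score_all_geco(
    matrix: pd.DataFrame,
    reference: ReferenceSet,
    max_missing: int = DEFAULT_MAX_MISSING,
) -> TargetScoreList:
    """Best (most positive) correlation of each candidate with any bait;
    candidates with no scorable pair are absent from the output."""
    return collapse_pairs(
        geco_all_pairs(matrix, reference, max_missing), higher_is_better=True
    )
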