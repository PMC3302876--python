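"""Score-to-p-value conversion, two-stage Fisher combination and
independence diagnostics.

Each evidence channel's best-per-target scores are converted to
add-one empirical right-tail p-values: p(s) = (1 + #{scores >= s}) /
(n + 1).  This estimator is distribution-free, monotone in the score
and never produces 0, so Fisher's statistic X = -2 sum(ln p) ~ chi2 with
2k degrees of freedom is always finite.  Channels group into three
approaches — literature mining (LM), neural-network inference (NNI)
and domain/genomic context (DGC) — and combination runs in two stages:
channels within an approach, then approach-level p-values into the
final integrated score.  Targets missing a channel or a whole approach
are combined over what is available, with the degrees of freedom
reduced accordingly rather than imputing p = 1 (a protein invisible to
the literature is not thereby evidence against membership).

The mutual-information distance D(X,Y) = 1 - I(X;Y)/H(X,Y) (a
normalised variation-of-information metric, 0 when either series
determines the other, 1 under exact empirical independence) serves as
the pairwise independence diagnostic across channels, which Fisher's
method implicitly assumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import TargetScoreList

#: evidence channel -> approach (literature mining / NN inference /
#: domain-genomic context)
CHANNEL_APPROACH: dict[str, str] = {
    "dCOCITE": "LM",
    "iCOCITE": "LM",
    "MLNN": "NNI",
    "hiPPI": "DGC",
    "CODAcath": "DGC",
    "CODApfam": "DGC",
    "DORA": "DGC",
    "GECO": "DGC",
    "GOSS": "DGC",
}


def empirical_pvalue(scores: TargetScoreList) -> dict[str, float]:
    """Add-one right-tail empirical p-value per target.

    p(s) = (1 + #{scores >= s}) / (n + 1) over the channel's own score
    distribution (scores flipped first for lower-is-better channels),
    so better scores map to smaller p and p is always in (0, 1].
    """
    items = list(scores.items())
    if len(items) < 2 or len({s for _, s in items}) < 2:
        if items and len({s for _, s in items}) == 1:
            warnings.warn(
                f"channel {scores.method!r}: all scores identical; p = 1 for all"
            )
            return {t: 1.0 for t, _ in items}
        return {t: 1.0 for t, _ in items}
    vals = np.array([s for _, s in items], dtype=float)
    if not scores.higher_is_better:
        vals = -vals
    order = np.sort(vals)
    n = len(vals)
    # count of scores >= s via searchsorted on the sorted array
    geq = n - np.searchsorted(order, vals, side="left")
    p = (1.0 + geq) / (n + 1.0)
    return {t: float(pv) for (t, _), pv in zip(items, p)}


def fisher_combine(pvals: Sequence[float]) -> float:
    """Fisher's method: upper chi-square tail of -2 sum(ln p) at 2k df."""
    if len(pvals) == 0:
        raise ValueError("no p-values to combine")
    for p in pvals:
        if not 0 < p <= 1:
            raise ValueError(f"p-value {p} outside (0, 1]")
    X = -2.0 * sum(math.log(p) for p in pvals)
    return float(stats.chi2.sf(X, df=2 * len(pvals)))


@dataclass
class PredictionMatrix:
    """Targets x channels of p-values in (0, 1], with missingness."""

    pvalues: pd.DataFrame
    channel_approach: dict[str, str] = field(default_factory=lambda: dict(CHANNEL_APPROACH))

    def __post_init__(self) -> None:
        vals = self.pvalues.to_numpy(dtype=float)
        bad = (vals <= 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            raise ValueError("stored p-values must lie in (0, 1]")
        unknown = [c for c in self.pvalues.columns if c not in self.channel_approach]
        if unknown:
            raise ValueError(f"channels without an approach mapping: {unknown}")

    @classmethod
    def from_channels(
        cls,
        channels: Mapping[str, Mapping[str, float]],
        channel_approach: Mapping[str, str] | None = None,
    ) -> "PredictionMatrix":
        df = pd.DataFrame(
            {name: pd.Series(pv, dtype=float) for name, pv in channels.items()}
        )
        df = df.sort_index()
        mapping = dict(channel_approach) if channel_approach else dict(CHANNEL_APPROACH)
        return cls(df, mapping)


@dataclass
class RankedList:
    """Targets ordered by ascending integrated p-value."""

    table: pd.DataFrame  # index: rank 1..n; columns: target, p_spip, p_<approach>...

    def targets(self) -> list[str]:
        return list(self.table["target"])

    def pvalues(self) -> np.ndarray:
        return self.table["p_spip"].to_numpy()


def spip_integrate(
    matrix: PredictionMatrix, mode: str = "two-stage"
) -> RankedList:
    """Combine the prediction matrix into the integrated ranking.

    two-stage (default): Fisher over available channels within each
    approach, then Fisher over the approach-level p-values.  flat:
    a single Fisher over all available channels (sensitivity mode).
    Targets with no channel at all are excluded.  Output sorted by
    ascending p, ties broken by target identifier.
    """
    if mode not in {"two-stage", "flat"}:
        raise ValueError(f"unknown integration mode {mode!r}")
    approaches = sorted(set(matrix.channel_approach.values()))
    rows = []
    for target, row in matrix.pvalues.iterrows():
        avail = row.dropna()
        if avail.empty:
            continue
        rec: dict[str, object] = {"target": target}
        if mode == "flat":
            rec["p_spip"] = fisher_combine(list(avail))
        else:
            approach_p: dict[str, float] = {}
            for app in approaches:
                chans = [
                    c for c in avail.index if matrix.channel_approach[c] == app
                ]
                if chans:
                    approach_p[app] = fisher_combine([avail[c] for c in chans])
            rec["p_spip"] = fisher_combine(list(approach_p.values()))
            for app in approaches:
                rec[f"p_{app}"] = approach_p.get(app, float("nan"))
        rows.append(rec)
    if not rows:
        raise ValueError("no target carries any channel p-value")
    df = pd.DataFrame(rows).sort_values(
        ["p_spip", "target"], kind="mergesort"
    )
    df.insert(0, "rank", range(1, len(df) + 1))
    return RankedList(df.reset_index(drop=True))


def calibration_check(pvals: Sequence[float], alpha: float = 0.05) -> dict:
    """Uniformity diagnostics for a set of p-values.

    Reports the KS statistic against Uniform(0, 1) and a right-tailed
    Z-test on the mean probit transform (under uniformity the probits
    are standard normal, so sqrt(n) * mean(-Phi^{-1}(p)) ~ N(0, 1);
    large positive values flag p-values concentrated near 0).
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) < 30:
        raise ValueError("need at least 30 p-values for calibration")
    ks_stat, ks_p = stats.kstest(p, "uniform")
    # clip to keep the probit finite for p = 1 (add-one estimator boundary)
    probit = -stats.norm.ppf(np.clip(p, 1e-12, 1 - 1e-12))
    z = probit.mean() * math.sqrt(len(p))
    z_p = float(stats.norm.sf(z))
    passed = bool(ks_p >= alpha and z_p >= alpha)
    return {
        "n": int(len(p)),
        "ks_stat": float(ks_stat),
        "ks_p": float(ks_p),
        "z": float(z),
        "z_p": z_p,
        "alpha": alpha,
        "pass": passed,
    }


def bin_series(values: Sequence[float], bins: int = 10) -> np.ndarray:
    """Equal-frequency discretization into integer bin labels."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty series")
    quantiles = np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(quantiles, v, side="right")


def mi_distance(x: Sequence, y: Sequence) -> float:
    """Normalised mutual-information distance D = 1 - I(X;Y) / H(X,Y).

    Plug-in estimates in nats from the empirical joint distribution of
    two discrete series.  D is 0 when each series determines the other
    and 1 when the empirical joint factorises exactly.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if len(x) == 0:
        raise ValueError("empty series")
    joint = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy(dtype=float)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    H = -np.sum(pxy[nz] * np.log(pxy[nz]))
    if H == 0:
        raise ValueError("degenerate joint entropy (both series constant)")
    outer = np.outer(px, py)
    I = np.sum(pxy[nz] * np.log(pxy[nz] / outer[nz]))
    I = max(float(I), 0.0)
    return float(1.0 - I / H)


def channel_distance_matrix(
    matrix: PredictionMatrix, bins: int = 10
) -> pd.DataFrame:
    """Pairwise D between channels over their jointly scored targets."""
    cols = list(matrix.pvalues.columns)
    out = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for i, a in enumerate(cols):
        out.loc[a, a] = 0.0
        for b in cols[i + 1 :]:
            sub = matrix.pvalues[[a, b]].dropna()
            if len(sub) < bins * 2:
                continue
            d = mi_distance(
                bin_series(sub[a].to_numpy(), bins),
                bin_series(sub[b].to_numpy(), bins),
            )
            out.loc[a, b] = d
            out.loc[b, a] = d
    return out
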