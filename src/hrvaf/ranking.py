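"""Feature ranking by single-feature AUC and by greedy MRMR.

AUC uses the Mann-Whitney rank-sum identity with midranks for ties, with
AF as the positive class; scores are orientation-fixed to [0.5, 1] and the
flip recorded.

MRMR (minimum redundancy, maximum relevance) greedily selects features:
the first pick maximizes relevance, the mutual information MI(f, y) between
the feature and the class; each later pick maximizes the quotient
relevance / mean redundancy over the already-selected set (MIQ; the
difference form MID is available).  Mutual information is the plug-in
estimate (log base 2) on an equal-frequency discretization of the feature
values (default 16 bins); the class variable is categorical and never
binned.  Redundancy between two features is, by default, their *normalized*
mutual information MI / sqrt(H_a H_b): an exact duplicate of a selected
feature then has redundancy 1 regardless of cardinality, while a feature
binned into many cells is not made to look artificially redundant by the
entropy of its own discretization.  Raw-MI redundancy is available via
``redundancy="mi"``.  Ranking must only ever see training-split rows; the
pipeline enforces that.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

_EPS = 1e-12  # floor for redundancy denominators


@dataclass
class RankingResult:
    method: str                       # "AUC" or "MRMR"
    pool: list[str]
    order: list[str]
    scores: dict[str, float]
    binning: int | None = None        # MI bins (MRMR only)
    flipped: dict[str, bool] = field(default_factory=dict)  # AUC orientation
    criterion: str | None = None      # "MIQ" or "MID" (MRMR only)

    def __post_init__(self):
        assert sorted(self.order) == sorted(self.pool), "order must permute pool"


def feature_auc(table: pd.DataFrame, feature: str, *,
                positive_class: str = "AF",
                class_col: str = "rhythm_class") -> tuple[float, bool]:
    """Single-feature ROC AUC via the rank-sum identity, ties shared.

    Returns ``(max(auc, 1 - auc), flipped)`` where ``flipped`` records
    whether orientation had to be reversed to make the positive (AF) class
    score high.
    """
    y = table[class_col].to_numpy()
    classes = set(y)
    if len(classes) < 2:
        raise ValueError("feature_auc requires both classes present")
    x = table[feature].to_numpy(dtype=float)
    pos = y == positive_class
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(x)  # midranks share ties
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    if auc < 0.5:
        return 1.0 - auc, True
    return float(auc), False


def auc_rank(table: pd.DataFrame, pool: list[str], **kw) -> RankingResult:
    """Rank a feature pool by oriented single-feature AUC (descending)."""
    scores, flips = {}, {}
    for f in pool:
        scores[f], flips[f] = feature_auc(table, f, **kw)
    order = sorted(pool, key=lambda f: -scores[f])  # stable: ties keep pool order
    return RankingResult("AUC", list(pool), order, scores, flipped=flips)


# ---------------------------------------------------------------------------
# mutual information by equal-frequency binning


def equal_frequency_codes(x: np.ndarray, bins: int) -> np.ndarray:
    """Discretize ``x`` into at most ``bins`` equal-frequency cells."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature column must be finite")
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


def _codes_entropy_mi(cx: np.ndarray, cy: np.ndarray) -> tuple[float, float, float]:
    """(H(x), H(y), MI(x, y)) in bits from two integer code arrays."""
    n = len(cx)
    nx, ny = cx.max() + 1, cy.max() + 1
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)

    def h(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    hx, hy = h(px), h(py)
    hxy = h(joint.ravel())
    return hx, hy, max(hx + hy - hxy, 0.0)


def _class_codes(y: np.ndarray) -> np.ndarray:
    _, codes = np.unique(np.asarray(y), return_inverse=True)
    return codes


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 16, *,
                       y_is_class: bool = True) -> float:
    """Plug-in mutual information (bits) between a feature and a second
    variable.

    The feature is equal-frequency binned; ``y`` is treated as categorical
    when ``y_is_class`` (the class label), otherwise it is binned too
    (feature-feature redundancy).  A constant column yields 0 bits.
    """
    cx = equal_frequency_codes(x, bins)
    cy = _class_codes(y) if y_is_class else equal_frequency_codes(np.asarray(y, float), bins)
    return _codes_entropy_mi(cx, cy)[2]


def normalized_mutual_information(x: np.ndarray, z: np.ndarray, bins: int = 16) -> float:
    """MI(x, z) / sqrt(H(x) H(z)) over equal-frequency binnings; 0 if either
    argument is (effectively) constant."""
    cx = equal_frequency_codes(x, bins)
    cz = equal_frequency_codes(np.asarray(z, float), bins)
    hx, hz, mi = _codes_entropy_mi(cx, cz)
    if hx <= 0 or hz <= 0:
        return 0.0
    return mi / np.sqrt(hx * hz)


def mrmr_rank(table: pd.DataFrame, pool: list[str], *, bins: int = 16,
              criterion: str = "MIQ", redundancy: str = "nmi",
              class_col: str = "rhythm_class") -> RankingResult:
    """Greedy MRMR ranking of ``pool`` against the class column.

    ``criterion`` is ``"MIQ"`` (relevance / mean redundancy, default) or
    ``"MID"`` (relevance - mean redundancy); ``redundancy`` is ``"nmi"``
    (normalized MI, default) or ``"mi"`` (raw plug-in MI).  The recorded
    score of each feature is the criterion value at its selection time; the
    first score is the maximum single-feature relevance.  Ties break by
    pool order.
    """
    if not pool:
        raise ValueError("empty feature pool")
    missing = [f for f in pool if f not in table.columns]
    if missing:
        raise ValueError(f"pool features not in table: {missing}")
    if criterion not in ("MIQ", "MID"):
        raise ValueError("criterion must be 'MIQ' or 'MID'")
    if redundancy not in ("nmi", "mi"):
        raise ValueError("redundancy must be 'nmi' or 'mi'")
    y = table[class_col].to_numpy()
    if len(set(y)) < 2:
        raise ValueError("mrmr_rank requires both classes present")

    cols = {f: table[f].to_numpy(dtype=float) for f in pool}
    rel = {f: mutual_information(cols[f], y, bins) for f in pool}

    red_fn = (normalized_mutual_information if redundancy == "nmi"
              else lambda a, b, bins: mutual_information(a, b, bins, y_is_class=False))
    red_cache: dict[tuple[str, str], float] = {}

    def red(f: str, s: str) -> float:
        key = (f, s) if f < s else (s, f)
        if key not in red_cache:
            red_cache[key] = red_fn(cols[key[0]], cols[key[1]], bins=bins)
        return red_cache[key]

    remaining = list(pool)
    # np.argmax keeps the first maximum -> ties break by pool order
    best = remaining[int(np.argmax([rel[f] for f in remaining]))]
    order, scores = [best], {best: rel[best]}
    remaining.remove(best)

    while remaining:
        crit_vals = []
        for f in remaining:
            mean_red = float(np.mean([red(f, s) for s in order]))
            if criterion == "MIQ":
                crit_vals.append(rel[f] / max(mean_red, _EPS))
            else:
                crit_vals.append(rel[f] - mean_red)
        pick = remaining[int(np.argmax(crit_vals))]
        scores[pick] = float(crit_vals[remaining.index(pick)])
        order.append(pick)
        remaining.remove(pick)
    return RankingResult("MRMR", list(pool), order, scores,
                         binning=bins, criterion=criterion)


def ranked_prefixes(result: RankingResult, k_max: int) -> list[list[str]]:
    """The nested k = 1..k_max prefix feature sets of a ranking."""
    if k_max > len(result.pool):
        raise ValueError("k_max exceeds pool size")
    return [result.order[:k] for k in range(1, k_max + 1)]


__all__ = [
    "RankingResult", "feature_auc", "auc_rank", "equal_frequency_codes",
    "mutual_information", "normalized_mutual_information", "mrmr_rank",
    "ranked_prefixes",
]
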