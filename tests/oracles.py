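"""Independent naive recomputations used as oracles in tests.

Everything here is written as direct loops over the definitions, kept
deliberately separate from the vectorized implementations it checks.
"""
from __future__ import annotations

import math

import numpy as np


def naive_features(rr, adjacency, *, ddof: int = 1, threshold: float = 50.0) -> dict:
    """Loop-based recomputation of the 13 HRV descriptors."""
    rr = [float(v) for v in rr]
    n = len(rr)
    pairs = [(rr[i], rr[i + 1]) for i in range(n - 1) if adjacency[i]]

    def mean(xs):
        return sum(xs) / len(xs)

    def sd(xs):
        m = mean(xs)
        denom = len(xs) - ddof
        return math.sqrt(sum((x - m) ** 2 for x in xs) / denom)

    diffs = [b - a for a, b in pairs]
    ratios = [b / a for a, b in pairs]
    mean_rr = mean(rr)
    sdrr = sd(rr)
    rr_range = max(rr) - min(rr)
    rrdif = mean([abs(d) for d in diffs])
    prr = 100.0 * sum(1 for d in diffs if abs(d) >= threshold) / len(diffs)
    sd1 = sd([d / math.sqrt(2) for d in diffs])
    sd2 = sd([(a + b) / math.sqrt(2) for a, b in pairs])
    return {
        "pRR50": prr, "SD1": sd1, "SD2": sd2,
        "SD2/SD1": sd2 / sd1 if sd1 > 0 else float("nan"),
        "SDRR": sdrr, "RRdif": rrdif, "CV": sdrr / mean_rr,
        "relRRdif": rrdif / mean_rr, "meanSuccRat": mean(ratios),
        "SDSuccRat": sd(ratios), "meanRR": mean_rr, "RRrange": rr_range,
        "relRRrange": rr_range / mean_rr,
    }


def naive_mi(x_codes, y_codes) -> float:
    """Plug-in mutual information (bits) from two code sequences, by loops."""
    n = len(x_codes)
    from collections import Counter

    cx, cy, cxy = Counter(x_codes), Counter(y_codes), Counter(zip(x_codes, y_codes))
    mi = 0.0
    for (a, b), c in cxy.items():
        pxy = c / n
        mi += pxy * math.log2(pxy / ((cx[a] / n) * (cy[b] / n)))
    return max(mi, 0.0)


def naive_entropy(codes) -> float:
    from collections import Counter

    n = len(codes)
    return -sum((c / n) * math.log2(c / n) for c in Counter(codes).values())


def brute_force_mrmr(table, pool, y_col="rhythm_class", *, bins=16,
                     criterion="MIQ", redundancy="nmi", eps=1e-12):
    """Non-incremental greedy MRMR: recompute every criterion value at every
    step from scratch, using the naive MI above."""
    from hrvaf.ranking import equal_frequency_codes

    y = list(table[y_col])
    uniq = sorted(set(y))
    y_codes = [uniq.index(v) for v in y]
    codes = {f: list(equal_frequency_codes(table[f].to_numpy(float), bins))
             for f in pool}
    rel = {f: naive_mi(codes[f], y_codes) for f in pool}

    def red(f, s):
        mi = naive_mi(codes[f], codes[s])
        if redundancy == "mi":
            return mi
        ha, hb = naive_entropy(codes[f]), naive_entropy(codes[s])
        return 0.0 if ha <= 0 or hb <= 0 else mi / math.sqrt(ha * hb)

    remaining = list(pool)
    order, scores = [], []
    while remaining:
        best_f, best_v = None, None
        for f in remaining:  # pool order; strict > keeps the first max
            if not order:
                v = rel[f]
            else:
                mean_red = sum(red(f, s) for s in order) / len(order)
                v = rel[f] / max(mean_red, eps) if criterion == "MIQ" \
                    else rel[f] - mean_red
            if best_v is None or v > best_v:
                best_f, best_v = f, v
        order.append(best_f)
        scores.append(best_v)
        remaining.remove(best_f)
    return order, scores


def mrmr_step_scores(table, pool, selected, y_col="rhythm_class", *, bins=16,
                     criterion="MIQ", redundancy="nmi", eps=1e-12):
    """Criterion value of every remaining candidate given ``selected``,
    recomputed from scratch with the naive MI."""
    from hrvaf.ranking import equal_frequency_codes

    y = list(table[y_col])
    uniq = sorted(set(y))
    y_codes = [uniq.index(v) for v in y]
    codes = {f: list(equal_frequency_codes(table[f].to_numpy(float), bins))
             for f in pool}

    def red(f, s):
        mi = naive_mi(codes[f], codes[s])
        if redundancy == "mi":
            return mi
        ha, hb = naive_entropy(codes[f]), naive_entropy(codes[s])
        return 0.0 if ha <= 0 or hb <= 0 else mi / math.sqrt(ha * hb)

    out = {}
    for f in pool:
        if f in selected:
            continue
        rel = naive_mi(codes[f], y_codes)
        if not selected:
            out[f] = rel
        else:
            mean_red = sum(red(f, s) for s in selected) / len(selected)
            out[f] = rel / max(mean_red, eps) if criterion == "MIQ" \
                else rel - mean_red
    return out


def assert_greedy_argmax(table, pool, impl_order, impl_scores, *, tol=1e-9, **kw):
    """Check an MRMR order step-by-step against the naive oracle: each pick
    must attain the oracle's maximum criterion value up to ``tol`` (exact
    numerical ties may legitimately resolve either way), and the recorded
    score must match the oracle's value for that pick."""
    selected = []
    for f in impl_order:
        scores = mrmr_step_scores(table, pool, selected, **kw)
        best = max(scores.values())
        slack = tol * max(1.0, abs(best))
        assert scores[f] >= best - slack, (f, scores)
        assert abs(impl_scores[f] - scores[f]) <= slack, (f, impl_scores[f], scores[f])
        selected.append(f)


def naive_auc(pos_values, neg_values) -> float:
    """Exhaustive pair enumeration with half-credit for ties."""
    wins = 0.0
    for p in pos_values:
        for q in neg_values:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos_values) * len(neg_values))
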