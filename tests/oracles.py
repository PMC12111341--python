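"""Independent brute-force reference implementations used only by tests.

Everything here recomputes quantities by direct enumeration of their
definitions (loops over samples, pairs, positions), deliberately avoiding
the vectorised code paths of the package under test.
"""

from __future__ import annotations

import math

import pandas as pd


def bf_order_probability(x, y) -> tuple[float, float]:
    n = len(x)
    gt = sum(1 for a, b in zip(x, y) if a > b)
    lt = sum(1 for a, b in zip(x, y) if a < b)
    return gt / n, lt / n


def bf_stable_pairs(values: pd.DataFrame, threshold: float):
    """All unordered pairs stable in one direction, by indicator recounting."""
    genes = sorted(values.index)
    out = []
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            p_gt, p_lt = bf_order_probability(values.loc[gi], values.loc[gj])
            if p_gt > threshold:
                out.append(((gi, gj), "gt"))
            elif p_lt > threshold:
                out.append(((gi, gj), "lt"))
    return out


def bf_reversal_pairs(values: pd.DataFrame, labels: pd.Series, threshold: float):
    """Stable reversal pairs by brute-force enumeration; canonical orientation."""
    tum = values.loc[:, labels == "tumor"]
    nor = values.loc[:, labels == "normal"]
    genes = sorted(values.index)
    out = []
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            tg, tl = bf_order_probability(tum.loc[gi], tum.loc[gj])
            ng, nl = bf_order_probability(nor.loc[gi], nor.loc[gj])
            if (tg > threshold and nl > threshold) or (tl > threshold and ng > threshold):
                out.append((gi, gj))
    return out


def bf_auc(scores, labels) -> float:
    """AUC by pairwise concordance count (ties count 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bf_aucell(ranks: dict[str, int], gene_set, top_fraction: float) -> float:
    n = len(ranks)
    eff = [g for g in gene_set if g in ranks]
    t = math.ceil(top_fraction * n)
    raw = 0
    for x in range(1, t + 1):
        raw += sum(1 for g in eff if ranks[g] <= x)
    max_auc = sum(min(x, len(eff)) for x in range(1, t + 1))
    return raw / max_auc


def bf_ssgsea(ranks: dict[str, int], gene_set, alpha: float) -> float:
    n = len(ranks)
    ordered = sorted(ranks, key=lambda g: ranks[g])  # best rank first
    in_set = [g in set(gene_set) for g in ordered]
    m = sum(in_set)
    weights = [(n - pos) ** alpha for pos in range(n)]  # N..1
    denom = sum(w for w, s in zip(weights, in_set) if s)
    running = 0.0
    es = 0.0
    for w, s in zip(weights, in_set):
        running += (w / denom) if s else (-1.0 / (n - m))
        es += running
    return es


def bf_concordance(scores, times, events) -> float:
    """Harrell's C by explicit pair enumeration under right censoring."""
    conc = tied = comparable = 0
    n = len(scores)
    for i in range(n):
        for j in range(i + 1, n):
            # the pair is usable when the earlier time is an event
            ti, tj = times[i], times[j]
            ei, ej = events[i], events[j]
            if ti == tj:
                usable = False  # equal times: usable only if exactly one event
                if ei != ej:
                    usable = True
                    early, late = (i, j) if ei else (j, i)
            elif ti < tj:
                usable = bool(ei)
                early, late = i, j
            else:
                usable = bool(ej)
                early, late = j, i
            if not usable:
                continue
            comparable += 1
            if scores[early] > scores[late]:
                conc += 1
            elif scores[early] == scores[late]:
                tied += 1
    return (conc + 0.5 * tied) / comparable


def bf_logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square from the O-E table."""
    from scipy import stats

    subjects = [(t, e, "a") for t, e in zip(times_a, events_a)] + [
        (t, e, "b") for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in subjects if e})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = sum(1 for tt, _, g in subjects if tt >= t and g == "a")
        n_b = sum(1 for tt, _, g in subjects if tt >= t and g == "b")
        n = n_a + n_b
        d = sum(1 for tt, e, _ in subjects if tt == t and e)
        d_a = sum(1 for tt, e, g in subjects if tt == t and e and g == "a")
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, float(stats.chi2.sf(chi2, df=1))


def bf_km_survival(times, events) -> dict[float, float]:
    """Product-limit estimate at each distinct event time."""
    s = 1.0
    out = {}
    for t in sorted(set(times)):
        at_risk = sum(1 for tt in times if tt >= t)
        d = sum(1 for tt, e in zip(times, events) if tt == t and e)
        s *= 1.0 - d / at_risk
        out[t] = s
    return out
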