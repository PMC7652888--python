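"""Independent brute-force oracles used to cross-check the package.

Everything here is written with explicit Python loops and no reuse of
the package's own code paths, so agreement is meaningful.
"""

from __future__ import annotations

import math


def _dist(u, v, metric: str) -> float:
    d2 = sum((a - b) ** 2 for a, b in zip(u, v))
    return d2 if metric == "squared_euclidean" else math.sqrt(d2)


def oracle_lof(p, refs, k: int, metric: str = "squared_euclidean",
               variant: str = "paper") -> float:
    """Brute-force LOF of an external query against a reference list.

    N_k is the k-distance neighborhood with ties included; lrd(q) of a
    reference excludes q itself from its own neighborhood search; the
    reachability variant replaces d(p, q) with max(kdist(q), d(p, q)).
    """
    refs = [list(map(float, r)) for r in refs]
    p = list(map(float, p))
    n = len(refs)

    def kdist_nbrs(point, pool_idx):
        ds = sorted(_dist(point, refs[i], metric) for i in pool_idx)
        kd = ds[k - 1]
        nbrs = [i for i in pool_idx if _dist(point, refs[i], metric) <= kd]
        return kd, nbrs

    ref_kdist = {}
    for i in range(n):
        ref_kdist[i], _ = kdist_nbrs(refs[i], [j for j in range(n) if j != i])

    def lrd_of(point, pool_idx):
        _, nbrs = kdist_nbrs(point, pool_idx)
        vals = []
        for i in nbrs:
            d = _dist(point, refs[i], metric)
            if variant == "reachability":
                d = max(ref_kdist[i], d)
            vals.append(d)
        mean_d = sum(vals) / len(vals)
        return math.inf if mean_d == 0.0 else 1.0 / mean_d

    lrd_p = lrd_of(p, list(range(n)))
    if math.isinf(lrd_p):
        return 1.0
    _, nbrs = kdist_nbrs(p, list(range(n)))
    ratios = [lrd_of(refs[i], [j for j in range(n) if j != i]) / lrd_p for i in nbrs]
    return sum(ratios) / len(ratios)


def oracle_pair_count_auc(scores, labels) -> float:
    """Mann-Whitney AUC: (#concordant + 0.5 * #tied) / (n_pos * n_neg)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                total += 1.0
            elif x == y:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_average_precision(scores, labels) -> float:
    """AP as the mean of precision at each positive hit in score order
    (ties grouped: precision evaluated at the group boundary)."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    # group ties so that all items with an equal score enter together
    ap, tp, fp, prev_tp = 0.0, 0, 0, 0
    i = 0
    n_pos = sum(labels)
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            j += 1
        group = order[i:j]
        tp += sum(labels[g] for g in group)
        fp += sum(1 - labels[g] for g in group)
        if tp > prev_tp:
            precision = tp / (tp + fp)
            ap += precision * (tp - prev_tp)
        prev_tp = tp
        i = j
    return ap / n_pos


def oracle_best_youden(scores, labels) -> float:
    """Maximum J = sens + spec - 1 over every possible cut of the scores
    (exhaustive over thresholds at each distinct score and beyond)."""
    candidates = sorted(set(scores))
    thresholds = [candidates[0] - 1.0] + candidates  # 'score > t' rules
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    best = -1.0
    for t in thresholds:
        tp = sum(1 for s, l in zip(scores, labels) if l == 1 and s > t)
        tn = sum(1 for s, l in zip(scores, labels) if l == 0 and s <= t)
        best = max(best, tp / n_pos + tn / n_neg - 1.0)
    return best


def oracle_delong_variance(scores, labels) -> float:
    """DeLong variance via explicit structural components."""
    x = [s for s, l in zip(scores, labels) if l == 1]
    y = [s for s, l in zip(scores, labels) if l == 0]
    m, n = len(x), len(y)
    v10 = [sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0 for yj in y) / n for xi in x]
    v01 = [sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x) / m for yj in y]
    auc = sum(v10) / m
    s10 = sum((v - auc) ** 2 for v in v10) / (m - 1)
    s01 = sum((v - auc) ** 2 for v in v01) / (n - 1)
    return s10 / m + s01 / n
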