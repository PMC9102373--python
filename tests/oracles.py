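"""Independent brute-force reference implementations used only by the tests.

Each oracle takes the naive route — full enumeration, exhaustive pairwise
recomputation — so that agreement with the package is evidence about the
package, not about a shared code path.
"""

from __future__ import annotations

import itertools

import numpy as np


def exact_mann_whitney_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every group assignment.

    Tie-free inputs only.  U counts (x_i > y_j) pairs; the two-sided p is
    twice the smaller tail probability, capped at 1.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    n1 = len(x)

    def u_of(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_of(x, y)
    us = [
        u_of(comb, [v for v in pooled if v not in comb])
        for comb in itertools.combinations(pooled, n1)
    ]
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def bh_step_up(pvalues):
    """Benjamini-Hochberg q-values by the textbook step-up recursion."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return q


def naive_upgma(ids, dist):
    """Exhaustive-pair UPGMA over a dense distance matrix.

    Recomputes every inter-cluster mean from the original leaf distances at
    each step.  Tie-break mirrors the published contract: minimal mean
    distance, then lexicographically smallest (key_a, key_b) where a cluster's
    key is its smallest leaf id; the smaller-key child goes left.
    """
    ids = list(ids)
    index = {it: i for i, it in enumerate(ids)}
    clusters = {it: [it] for it in ids}  # label -> leaf list
    merges = []
    step = 0
    while len(clusters) > 1:
        step += 1
        candidates = []
        for la, lb in itertools.combinations(sorted(clusters), 2):
            leaves_a, leaves_b = clusters[la], clusters[lb]
            total = 0.0
            for a in leaves_a:
                for b in leaves_b:
                    total += dist[index[a]][index[b]]
            mean = total / (len(leaves_a) * len(leaves_b))
            ka, kb = min(leaves_a), min(leaves_b)
            (left, right) = (la, lb) if ka <= kb else (lb, la)
            candidates.append((mean, min(ka, kb), max(ka, kb), left, right))
        mean, _, _, left, right = min(candidates)
        merges.append((left, right, mean))
        clusters[f"NODE{step}"] = clusters.pop(left) + clusters.pop(right)
    (leaf_order,) = clusters.values()
    return merges, leaf_order


def best_rule_threshold(pos, neg, direction, min_sensitivity, candidates):
    """Exhaustive search over candidate thresholds: max specificity subject to
    sensitivity >= min_sensitivity; ties to the fewest positives called."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)

    def calls(v, t):
        return v <= t if direction == "low" else v >= t

    feasible = []
    for t in candidates:
        sens = calls(pos, t).mean()
        if sens >= min_sensitivity:
            spec = 1.0 - calls(neg, t).mean()
            n_called = calls(pos, t).sum() + calls(neg, t).sum()
            feasible.append((spec, -n_called, t))
    assert feasible, "no feasible threshold"
    best_spec = max(f[0] for f in feasible)
    tied = [f for f in feasible if f[0] == best_spec]
    fewest = max(f[1] for f in tied)
    tied = [f[2] for f in tied if f[1] == fewest]
    assert len(tied) == 1
    return float(tied[0])
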