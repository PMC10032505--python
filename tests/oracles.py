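"""Independent brute-force reference implementations used only by tests.

Everything here is written directly from the defining formulas, with plain
loops and no shared code paths with the package internals.
"""

import math
from itertools import combinations

import numpy as np


def direct_neg_log_partial_likelihood(beta, X, times, events):
    """-(2/n) * sum over unique failure times of the Breslow term, by loops."""
    beta = np.asarray(beta, dtype=float)
    n = len(times)
    unique_failures = sorted({times[i] for i in range(n) if events[i] == 1})
    total = 0.0
    for t in unique_failures:
        D = [i for i in range(n) if times[i] == t and events[i] == 1]
        R = [i for i in range(n) if times[i] >= t]
        lin = sum(float(X[i] @ beta) for i in D)
        denom = sum(math.exp(float(X[i] @ beta)) for i in R)
        total += lin - len(D) * math.log(denom)
    return -(2.0 / n) * total


def central_difference_gradient(fun, x, h=1e-6):
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for j in range(x.size):
        e = np.zeros_like(x)
        e[j] = h
        g[j] = (fun(x + e) - fun(x - e)) / (2 * h)
    return g


def largest_k_by_subsets(beta, k):
    a = np.abs(np.asarray(beta, dtype=float))
    return max(sum(a[list(s)]) for s in combinations(range(a.size), k))


def cindex_by_pairs(risk, times, events):
    n = len(times)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def auc_by_pairs(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    num = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                num += 1.0
            elif a == b:
                num += 0.5
    return num / (len(pos) * len(neg))


def dominated_by_pairs(points):
    """O(n^2) Pareto-domination flags: minimize cost, maximize accuracy."""
    flags = []
    for i, p in enumerate(points):
        dom = any(
            q.cost <= p.cost
            and q.accuracy >= p.accuracy
            and (q.cost < p.cost or q.accuracy > p.accuracy)
            for j, q in enumerate(points)
            if j != i
        )
        flags.append(dom)
    return flags


def best_subset_objective(data, family, K, fit_restricted, loss_at):
    """Minimum loss over all supports of size <= K via restricted refits."""
    best = np.inf
    for k in range(1, K + 1):
        for s in combinations(range(data.p), k):
            beta = fit_restricted(data, family, support=s)
            best = min(best, loss_at(beta))
    return best
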