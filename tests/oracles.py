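"""Independent brute-force transcriptions of the neighborhood formulas.

Deliberately naive (pure-Python loops, O(n^2)-O(n^3)) and written straight
from the definitions, so they share no code path with the package.  Distance
ties break toward the lower instance index, the same fixed rule the package
declares.
"""

import math

import numpy as np


def _dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def knn_lists(X, k):
    n = len(X)
    out = []
    for i in range(n):
        ranked = sorted((_dist(X[i], X[j]), j) for j in range(n) if j != i)
        out.append([j for _, j in ranked[:k]])
    return out


def rnn_sets(knn):
    n = len(knn)
    out = [set() for _ in range(n)]
    for i in range(n):
        for j in knn[i]:
            out[j].add(i)
    return out


def snn_sets(knn):
    n = len(knn)
    out = [set() for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if j != i and set(knn[i]) & set(knn[j]):
                out[i].add(j)
    return out


def extended_sets(knn):
    rnn, snn = rnn_sets(knn), snn_sets(knn)
    return [
        (set(knn[i]) | rnn[i] | snn[i]) - {i}
        for i in range(len(knn))
    ]


def rdos(X, k, h):
    """Relative density-based outlier factor, straight from the definition."""
    X = np.asarray(X, float)
    n, d = X.shape
    S = extended_sets(knn_lists(X, k))

    def density(j):
        members = sorted(S[j] | {j})
        total = 0.0
        for m in members:
            u2 = sum((a - b) ** 2 for a, b in zip(X[m], X[j])) / h**2
            total += (2 * math.pi) ** (-d / 2) * math.exp(-u2 / 2) / h**d
        return total / len(members)

    dens = [density(j) for j in range(n)]
    return [sum(dens[i] for i in S[j]) / (len(S[j]) * dens[j]) for j in range(n)]


def nan_search(X):
    """Natural-neighbor searching; returns (terminal r, rnb counts)."""
    X = np.asarray(X, float)
    n = len(X)
    full = knn_lists(X, n - 1)
    rnb = [0] * n
    prev = None
    r = 0
    while r < n - 1:
        for i in range(n):
            rnb[full[i][r]] += 1
        r += 1
        zero = frozenset(i for i in range(n) if rnb[i] == 0)
        if not zero or zero == prev:
            break
        prev = zero
    return r, rnb


def nof(X):
    """Natural outlier factor from lrd over the natural influence space."""
    X = np.asarray(X, float)
    n = len(X)
    r, _ = nan_search(X)
    k = math.ceil(r)  # mean neighbor-list length at termination equals r
    knn = knn_lists(X, k)
    rnn = rnn_sets(knn)
    kdist = [_dist(X[j], X[knn[j][-1]]) for j in range(n)]

    def lrd(j):
        s = sum(max(kdist[m], _dist(X[j], X[m])) for m in knn[j])
        return len(knn[j]) / s

    lrds = [lrd(j) for j in range(n)]
    out = []
    for j in range(n):
        nis = sorted(set(knn[j]) | rnn[j])
        out.append(sum(lrds[q] for q in nis) / (len(nis) * lrds[j]))
    return out


def auc_concordance(scores, labels):
    """AUC as the Mann-Whitney concordance probability (ties count half)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
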