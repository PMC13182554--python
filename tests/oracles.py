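"""Independent brute-force oracles shared across test modules."""

import math

import numpy as np


def ari_bruteforce(a, b):
    """ARI from the contingency-table closed form."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    contingency = np.array([[(np.logical_and(a == x, b == y)).sum() for y in ub] for x in ua])
    comb = lambda x: x * (x - 1) / 2
    sum_ij = comb(contingency).sum()
    sum_a = comb(contingency.sum(axis=1)).sum()
    sum_b = comb(contingency.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 0.0
    return (sum_ij - expected) / (max_index - expected)


def entropy(labels):
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return -(p * np.log(p)).sum()


def mi_bruteforce(a, b):
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    mi = 0.0
    for x in np.unique(a):
        for y in np.unique(b):
            nxy = np.logical_and(a == x, b == y).sum()
            if nxy == 0:
                continue
            mi += (nxy / n) * math.log(nxy * n / ((a == x).sum() * (b == y).sum()))
    return mi
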