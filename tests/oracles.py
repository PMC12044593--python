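"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: explicit pair enumeration,
exhaustive permutation/partition search, direct inertia evaluation.
"""

from itertools import combinations, permutations, product

import numpy as np


def ari_pair_counting(a, b) -> float:
    """Adjusted Rand index by explicit enumeration of all sample pairs."""
    a, b = list(a), list(b)
    n = len(a)
    n11 = n10 = n01 = n00 = 0
    for i, j in combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        if sa and sb:
            n11 += 1
        elif sa and not sb:
            n10 += 1
        elif not sa and sb:
            n01 += 1
        else:
            n00 += 1
    index = n11
    expected = (n11 + n10) * (n11 + n01) / (n * (n - 1) / 2)
    maximum = ((n11 + n10) + (n11 + n01)) / 2
    if maximum == expected:  # both partitions trivial
        return 1.0
    return (index - expected) / (maximum - expected)


def best_matching_agreement(assignments, truth) -> int:
    """Max number of correctly labeled samples over all cluster→label
    bijections, by exhaustive permutation search."""
    assignments = list(assignments)
    truth = list(truth)
    clusters = sorted(set(assignments))
    labels = sorted(set(truth))
    best = -1
    for perm in permutations(labels):
        mapping = dict(zip(clusters, perm))
        agree = sum(mapping[c] == t for c, t in zip(assignments, truth))
        best = max(best, agree)
    return best


def kmeans_min_inertia(points: np.ndarray, k: int) -> float:
    """Global minimum k-means inertia by brute force over all assignments."""
    points = np.asarray(points, float)
    n = points.shape[0]
    best = np.inf
    for assign in product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        assign = np.array(assign)
        inertia = 0.0
        for c in range(k):
            pts = points[assign == c]
            inertia += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, inertia)
    return float(best)


def set_partitions(items):
    """All partitions of a list, as lists of blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def partition_to_labels(partition, n) -> list[int]:
    labels = [0] * n
    for bi, block in enumerate(partition):
        for item in block:
            labels[item] = bi
    return labels
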