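"""Independent brute-force oracles used to validate the fast implementations.

These deliberately recompute objectives from scratch at every step (no
Lance–Williams updates, no closed forms) so agreement with the package is
a genuine two-route check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def _sse(X, members):
    pts = X[sorted(members)]
    return float(((pts - pts.mean(axis=0)) ** 2).sum())


def ward_merge_sequence(X, labels):
    """Greedy Ward agglomeration recomputing the variance objective from
    scratch at every step. Returns ``[(frozenset({A, B}), height)]`` with
    A, B frozensets of labels and heights on the distance scale
    (``sqrt(2 * delta_SSE)``). Ties: lexicographically smallest pair of
    min-label keys."""
    X = np.asarray(X, dtype=float)
    clusters = [frozenset([i]) for i in range(len(X))]

    def key(c):
        return min(labels[i] for i in c)

    seq = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            delta = _sse(X, a | b) - _sse(X, a) - _sse(X, b)
            tag = tuple(sorted((key(a), key(b))))
            if best is None or delta < best[0] - 1e-9 * (1 + abs(best[0])) or (
                abs(delta - best[0]) <= 1e-9 * (1 + abs(best[0])) and tag < best[1]
            ):
                best = (delta, tag, a, b)
        delta, _, a, b = best
        seq.append((
            frozenset({frozenset(labels[i] for i in a),
                       frozenset(labels[i] for i in b)}),
            float(np.sqrt(max(2.0 * delta, 0.0))),
        ))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return seq


def upgma_merge_sequence(dist, labels):
    """Greedy average-linkage agglomeration where every inter-cluster
    distance is recomputed as the plain mean over all original cross-pair
    distances."""
    dist = np.asarray(dist, dtype=float)
    clusters = [frozenset([i]) for i in range(len(dist))]

    def key(c):
        return min(labels[i] for i in c)

    def avg(a, b):
        return float(np.mean([dist[i, j] for i in a for j in b]))

    seq = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            d = avg(a, b)
            tag = tuple(sorted((key(a), key(b))))
            if best is None or d < best[0] - 1e-9 * (1 + abs(best[0])) or (
                abs(d - best[0]) <= 1e-9 * (1 + abs(best[0])) and tag < best[1]
            ):
                best = (d, tag, a, b)
        d, _, a, b = best
        seq.append((
            frozenset({frozenset(labels[i] for i in a),
                       frozenset(labels[i] for i in b)}),
            d,
        ))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return seq


def tree_merge_sequence(tree):
    """Merge sequence of a package LinkageTree in the oracle's format."""
    n = tree.n_leaves
    members = {i: frozenset([tree.labels[i]]) for i in range(n)}
    seq = []
    for t, (a, b, h, _) in enumerate(tree.linkage):
        A, B = members[int(a)], members[int(b)]
        members[n + t] = A | B
        seq.append((frozenset({A, B}), float(h)))
    return seq


def assert_sequences_equal(seq_a, seq_b, atol=1e-8):
    assert len(seq_a) == len(seq_b)
    for (pair_a, h_a), (pair_b, h_b) in zip(seq_a, seq_b):
        assert pair_a == pair_b, f"merged {pair_a} vs {pair_b}"
        assert abs(h_a - h_b) <= atol * (1 + abs(h_b)), (h_a, h_b)


def runs_distribution_by_enumeration(n_pos, n_neg):
    """Exact runs distribution by enumerating all sign arrangements."""
    n = n_pos + n_neg
    counts = {}
    total = 0
    for pos in combinations(range(n), n_pos):
        signs = np.full(n, -1)
        signs[list(pos)] = 1
        r = int(1 + np.sum(signs[1:] != signs[:-1]))
        counts[r] = counts.get(r, 0) + 1
        total += 1
    return {r: c / total for r, c in sorted(counts.items())}
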