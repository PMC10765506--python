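"""Agglomerative linkage trees shared by phenotype, fingerprint and sensory
clustering.

Both linkage flavours used in the pipeline are computed by one
Lance–Williams agglomeration engine:

* ``ward`` — Ward's minimum-variance criterion in the Ward.D2 convention:
  the recurrence runs on squared distances and merge heights are reported
  on the distance scale, so two singletons at Euclidean distance *d* merge
  at height *d*.
* ``upgma`` — unweighted pair-group average linkage; the inter-cluster
  distance is the size-weighted arithmetic mean of member distances, which
  equals the plain average of all cross-pair original distances.

Ties among equally close pairs are broken toward the lexicographically
smallest pair of cluster keys, a cluster's key being the smallest leaf
label it contains. This makes the merge sequence deterministic and
invariant under permutation of the input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from skbio import TreeNode

from .exceptions import NotEnoughItems

_TIE_RTOL = 1e-9


def _validate_square(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(dist < -1e-12):
        raise ValueError("distances must be nonnegative")
    return dist


def agglomerate(dist, labels=None, method: str = "ward"):
    """Build a :class:`LinkageTree` from a square distance matrix.

    Parameters
    ----------
    dist : (n, n) array
        Symmetric distance matrix with zero diagonal.
    labels : sequence of str, optional
        Leaf labels; default ``"0".."n-1"``.
    method : {"ward", "upgma"}
    """
    dist = _validate_square(dist)
    n = dist.shape[0]
    if n < 2:
        raise NotEnoughItems("need at least 2 items to cluster")
    if labels is None:
        labels = [str(i) for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")

    if method == "ward":
        work = dist**2  # Lance-Williams on squared distances (Ward.D2)
    elif method == "upgma":
        work = dist.copy()
    else:
        raise ValueError(f"unknown linkage method {method!r}")

    # active cluster state, keyed by scipy node id
    node = {i: {"size": 1, "key": labels[i]} for i in range(n)}
    d = {}  # (node_i, node_j) with i < j -> working distance
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = work[i, j]

    Z = np.zeros((n - 1, 4))
    active = set(range(n))
    next_id = n
    for step in range(n - 1):
        dmin = min(d[pair] for pair in d)
        tol = _TIE_RTOL * (1.0 + abs(dmin))
        candidates = [pair for pair, v in d.items() if v <= dmin + tol]
        pair = min(
            candidates,
            key=lambda p: tuple(sorted((node[p[0]]["key"], node[p[1]]["key"]))),
        )
        i, j = pair
        dij = d.pop(pair)
        ni, nj = node[i]["size"], node[j]["size"]
        height = np.sqrt(max(dij, 0.0)) if method == "ward" else dij
        Z[step] = [i, j, height, ni + nj]

        merged = {"size": ni + nj, "key": min(node[i]["key"], node[j]["key"])}
        active -= {i, j}
        for k in active:
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            nk = node[k]["size"]
            if method == "ward":
                dnew = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            else:
                dnew = (ni * dik + nj * djk) / (ni + nj)
            d[(min(next_id, k), max(next_id, k))] = dnew
        node[next_id] = merged
        active.add(next_id)
        next_id += 1

    return LinkageTree(linkage=Z, labels=list(labels), method=method)


@dataclass
class LinkageTree:
    """A full agglomerative merge history over labelled leaves.

    ``linkage`` is a scipy-format ``(n-1, 4)`` matrix (child ids, merge
    height, merged size), so scipy's dendrogram/cut utilities apply
    directly.
    """

    linkage: np.ndarray
    labels: list = field(default_factory=list)
    method: str = "ward"

    @property
    def n_leaves(self) -> int:
        return self.linkage.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        """Merge heights in merge order (nondecreasing for both methods)."""
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict:
        """Partition the leaves into exactly ``k`` groups.

        Removes the ``k-1`` highest merges. Returns ``{label: group}``
        with group labels contiguous ``1..k`` in order of first
        appearance along the leaf ordering.
        """
        n = self.n_leaves
        if not (1 <= k <= n):
            raise ValueError(f"k must be in [1, {n}], got {k}")
        flat = hierarchy.cut_tree(self.linkage, n_clusters=k).ravel()
        relabel, out = {}, {}
        for label, g in zip(self.labels, flat):
            if g not in relabel:
                relabel[g] = len(relabel) + 1
            out[label] = relabel[g]
        return out

    def select_k(self, k_max: int = 10):
        """Pick the number of groups by the largest-gap dendrogram rule.

        Scans the gaps between consecutive merge heights; cutting inside
        the largest gap (restricted to at most ``k_max`` groups) gives the
        selected ``k``. Ties break toward the smaller ``k``. Returns
        ``(k, gap_profile)`` where ``gap_profile`` maps each candidate
        ``k`` to its gap, for reporting.
        """
        if k_max < 2:
            raise ValueError("k_max must be >= 2")
        h = self.heights
        n = self.n_leaves
        if len(h) < 2:
            return 2, {2: 0.0}
        profile = {}
        for i in range(len(h) - 1):
            k = n - (i + 1)  # clusters left when cutting between merge i and i+1
            profile[k] = float(h[i + 1] - h[i])
        eligible = {k: g for k, g in profile.items() if 2 <= k <= k_max}
        if not eligible or max(eligible.values()) <= 0:
            warnings.warn("degenerate merge-height profile; defaulting to k=2")
            return 2, profile
        best = max(sorted(eligible), key=lambda k: (eligible[k], -k))
        return best, profile

    def to_newick(self) -> str:
        """Serialize as a Newick string with branch lengths."""
        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()
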