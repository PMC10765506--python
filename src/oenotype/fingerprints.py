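"""Fingerprint band-pattern grouping by Dice similarity and UPGMA.

Mirrors the genotyping stage of starter preselection: RAPD or interdelta
PCR fingerprints, already band-called into presence/absence tables, are
compared with the Dice coefficient ``2|A∩B| / (|A|+|B|)``, clustered by
UPGMA on ``1 − similarity``, and a handful of representatives per cluster
(typically 2–5) is carried forward to species identification. Gel-image
processing and band calling are upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .exceptions import EmptyPattern, NotEnoughItems
from .tree import LinkageTree, agglomerate


@dataclass(frozen=True)
class BandPattern:
    """A named set of band identifiers (normalized size bins)."""

    pattern_id: str
    bands: frozenset

    def __post_init__(self):
        if not self.bands:
            raise EmptyPattern(f"pattern {self.pattern_id!r} has no bands")


def dice_similarity(a: BandPattern, b: BandPattern) -> float:
    """Dice coefficient between two band sets: ``2|A∩B| / (|A|+|B|)``."""
    if not a.bands or not b.bands:
        raise EmptyPattern("cannot compare an empty band pattern")
    inter = len(a.bands & b.bands)
    return 2.0 * inter / (len(a.bands) + len(b.bands))


def similarity_matrix(patterns) -> pd.DataFrame:
    """All-pairs Dice similarity, as a labelled symmetric DataFrame."""
    patterns = list(patterns)
    ids = [p.pattern_id for p in patterns]
    if len(set(ids)) != len(ids):
        raise ValueError("pattern ids must be unique")
    n = len(patterns)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = dice_similarity(patterns[i], patterns[j])
    return pd.DataFrame(sim, index=ids, columns=ids)


def upgma(sim: pd.DataFrame) -> LinkageTree:
    """UPGMA tree on distances ``1 − similarity``."""
    values = np.asarray(sim, dtype=float)
    if values.shape[0] < 2:
        raise NotEnoughItems("need at least 2 patterns")
    if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
        raise ValueError("similarities must lie in [0, 1]")
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    labels = list(sim.index) if isinstance(sim, pd.DataFrame) else None
    return agglomerate(dist, labels=labels, method="upgma")


def clusters_at_similarity(tree: LinkageTree, threshold: float = 0.90) -> dict:
    """Cut the UPGMA tree at distance ``1 − threshold``.

    Patterns whose cluster cohesion is at least ``threshold`` similarity
    stay together. Returns ``{pattern_id: cluster label}``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    cutoff = 1.0 - threshold
    k = int(np.sum(tree.heights > cutoff + 1e-12)) + 1
    return tree.cut(k)


def pick_representatives(partition: dict, k_min: int = 2, k_max: int = 5, seed: int = 0) -> dict:
    """Choose 2–5 representative patterns per cluster, reproducibly.

    Singleton (or undersized) clusters contribute all their members.
    Returns ``{cluster label: sorted list of pattern ids}``; the union
    covers every cluster.
    """
    if not partition:
        raise ValueError("empty partition")
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    rng = np.random.default_rng(seed)
    clusters = {}
    for pid, grp in partition.items():
        clusters.setdefault(grp, []).append(pid)
    reps = {}
    for grp in sorted(clusters):
        members = sorted(clusters[grp])
        want = int(rng.integers(k_min, k_max + 1))
        take = min(len(members), want)
        reps[grp] = sorted(rng.choice(members, size=take, replace=False).tolist())
    return reps


class FingerprintClusterer(BaseEstimator, ClusterMixin):
    """Dice/UPGMA clustering of fingerprint band tables.

    Parameters
    ----------
    threshold : float
        Within-cluster similarity cohesion; the tree is cut at distance
        ``1 − threshold`` (default 0.90).

    Attributes
    ----------
    tree_ : LinkageTree
    similarity_ : pd.DataFrame
    labels_ : ndarray of cluster labels in input order
    partition_ : dict pattern_id -> cluster label
    """

    def __init__(self, threshold: float = 0.90):
        self.threshold = threshold

    def fit(self, X, y=None):
        """Fit on a list of BandPatterns or a wide 0/1 band DataFrame."""
        patterns = X if isinstance(X, list) else band_table_to_patterns(X)
        self.similarity_ = similarity_matrix(patterns)
        self.tree_ = upgma(self.similarity_)
        self.partition_ = clusters_at_similarity(self.tree_, self.threshold)
        self.labels_ = np.array([self.partition_[p.pattern_id] for p in patterns])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# IO: wide (pattern_id + 0/1 band columns) and long (pattern_id, band) tables


def band_table_to_patterns(df: pd.DataFrame) -> list:
    """Convert a band table to BandPatterns.

    Wide format: ``pattern_id`` column plus one 0/1 column per band.
    Long format: exactly the columns ``pattern_id`` and ``band``.
    """
    if set(df.columns) == {"pattern_id", "band"}:
        grouped = df.groupby("pattern_id")["band"].apply(list)
        return [
            BandPattern(str(pid), frozenset(map(str, bands)))
            for pid, bands in grouped.items()
        ]
    if "pattern_id" not in df.columns:
        raise ValueError("band table needs a pattern_id column")
    band_cols = [c for c in df.columns if c != "pattern_id"]
    patterns = []
    for _, row in df.iterrows():
        bands = frozenset(str(c) for c in band_cols if int(row[c]) == 1)
        patterns.append(BandPattern(str(row["pattern_id"]), bands))
    return patterns


def read_band_csv(path) -> list:
    return band_table_to_patterns(pd.read_csv(path))
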