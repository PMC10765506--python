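"""Free-sorting sensory analysis.

Each panelist partitions the wine set into self-defined groups. A sheet
becomes a binary wines × wines similarity matrix (1 = sorted together);
summing the sheets over panelists gives the co-occurrence matrix, whose
entries count how many of the *m* panelists co-grouped each pair. Wines
are then clustered hierarchically (Ward by default) on the dissimilarity
``m − count`` and labelled A, B, C, … in dendrogram order.

Free-text aroma descriptors attached to the sheets (floral, fruity,
off-odor, …) are summarized per cluster by frequency.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .exceptions import InvalidSheet, NotEnoughItems
from .tree import LinkageTree, agglomerate


@dataclass(frozen=True)
class SortingSheet:
    """One panelist's partition of the wines (group labels arbitrary)."""

    panelist_id: str
    partition: dict  # wine_id -> group label
    descriptors: dict = field(default_factory=dict, compare=False)  # wine_id -> [tag]

    def __post_init__(self):
        if not self.partition:
            raise InvalidSheet(f"panelist {self.panelist_id!r}: empty sheet")


def individual_similarity(sheet: SortingSheet, wines) -> np.ndarray:
    """Binary co-grouping matrix of one sheet over the listed wine order."""
    wines = list(wines)
    if set(sheet.partition) != set(wines) or len(wines) != len(set(wines)):
        extra = set(sheet.partition) - set(wines)
        missing = set(wines) - set(sheet.partition)
        raise InvalidSheet(
            f"panelist {sheet.panelist_id!r}: sheet does not cover the wine set "
            f"(missing {sorted(missing)}, extra {sorted(extra)})"
        )
    groups = np.array([sheet.partition[w] for w in wines], dtype=object)
    return (groups[:, None] == groups[None, :]).astype(int)


@dataclass
class CooccurrenceMatrix:
    """Summed co-grouping counts across panelists."""

    wines: list
    counts: np.ndarray
    n_panelists: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.wines, columns=self.wines)

    def distances(self, scale: bool = False) -> np.ndarray:
        """Dissimilarity ``m − count`` (or ``1 − count/m`` when scaled)."""
        d = self.n_panelists - self.counts.astype(float)
        if scale:
            d /= self.n_panelists
        np.fill_diagonal(d, 0.0)
        return d


def aggregate_cooccurrence(sheets, wines=None) -> CooccurrenceMatrix:
    """Sum the individual similarity matrices across panelists."""
    sheets = list(sheets)
    if not sheets:
        raise InvalidSheet("need at least one sorting sheet")
    if wines is None:
        wines = sorted(sheets[0].partition)
    wines = list(wines)
    counts = np.zeros((len(wines), len(wines)), dtype=int)
    for sheet in sheets:
        counts += individual_similarity(sheet, wines)
    return CooccurrenceMatrix(wines=wines, counts=counts, n_panelists=len(sheets))


class SensoryClusterer(BaseEstimator, ClusterMixin):
    """Hierarchical clustering of wines from free-sorting co-occurrence.

    Parameters
    ----------
    n_groups : int or "auto"
        Number of sensory clusters; ``"auto"`` uses the largest-gap rule.
    k_max : int
        Bound for automatic selection.
    linkage : {"ward", "upgma"}
        Ward by default; average linkage available as a robustness check.
    scale_distance : bool
        Use ``1 − count/m`` instead of ``m − count`` (same clustering,
        different height units).

    Attributes
    ----------
    cooccurrence_ : CooccurrenceMatrix
    tree_ : LinkageTree
    k_ : int
    assignment_ : dict wine -> letter label ("A", "B", ...)
    labels_ : ndarray of integer labels in wine order
    """

    def __init__(self, n_groups="auto", k_max: int = 8, linkage: str = "ward",
                 scale_distance: bool = False):
        self.n_groups = n_groups
        self.k_max = k_max
        self.linkage = linkage
        self.scale_distance = scale_distance

    def fit(self, X, y=None):
        """Fit from a list of SortingSheets or a CooccurrenceMatrix."""
        cooc = X if isinstance(X, CooccurrenceMatrix) else aggregate_cooccurrence(X)
        if len(cooc.wines) < 2:
            raise NotEnoughItems("need at least 2 wines")
        self.cooccurrence_ = cooc
        dist = cooc.distances(scale=self.scale_distance)
        self.tree_ = agglomerate(dist, labels=cooc.wines, method=self.linkage)
        if self.n_groups == "auto":
            self.k_, self.gap_profile_ = self.tree_.select_k(self.k_max)
        else:
            self.k_ = int(self.n_groups)
            _, self.gap_profile_ = self.tree_.select_k(self.k_max)
        cut = self.tree_.cut(self.k_)
        letters = {g: chr(ord("A") + g - 1) for g in range(1, self.k_ + 1)}
        self.assignment_ = {w: letters[cut[w]] for w in cooc.wines}
        self.labels_ = np.array([cut[w] for w in cooc.wines])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def descriptor_summary(sheets, assignment: dict) -> pd.DataFrame:
    """Frequency of free-text descriptors per sensory cluster."""
    rows = []
    tally = {}
    for sheet in sheets:
        for wine, tags in sheet.descriptors.items():
            cluster = assignment.get(wine)
            if cluster is None:
                continue
            tally.setdefault(cluster, Counter()).update(tags)
    for cluster in sorted(tally):
        total = sum(tally[cluster].values())
        for tag, n in tally[cluster].most_common():
            rows.append({"cluster": cluster, "descriptor": tag,
                         "count": n, "share": n / total})
    return pd.DataFrame(rows, columns=["cluster", "descriptor", "count", "share"])


# ---------------------------------------------------------------------------
# IO: long CSV (panelist_id, wine_id, group_label[, descriptors])


def read_sorting_csv(path) -> list:
    """Read long-format sorting sheets; descriptors are ';'-separated."""
    df = pd.read_csv(path)
    needed = {"panelist_id", "wine_id", "group_label"}
    if not needed <= set(df.columns):
        raise ValueError(f"sorting CSV needs columns {sorted(needed)}")
    sheets = []
    for pid, sub in df.groupby("panelist_id", sort=True):
        if sub["wine_id"].duplicated().any():
            raise InvalidSheet(f"panelist {pid!r} sorted a wine twice")
        partition = dict(zip(sub["wine_id"].astype(str), sub["group_label"]))
        descriptors = {}
        if "descriptors" in sub.columns:
            for _, row in sub.iterrows():
                if isinstance(row["descriptors"], str) and row["descriptors"]:
                    descriptors[str(row["wine_id"])] = row["descriptors"].split(";")
        sheets.append(SortingSheet(str(pid), partition, descriptors))
    return sheets


def write_sorting_csv(sheets, path) -> None:
    rows = []
    for sheet in sheets:
        for wine, grp in sorted(sheet.partition.items()):
            rows.append({
                "panelist_id": sheet.panelist_id,
                "wine_id": wine,
                "group_label": grp,
                "descriptors": ";".join(sheet.descriptors.get(wine, [])),
            })
    pd.DataFrame(rows).to_csv(path, index=False)
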