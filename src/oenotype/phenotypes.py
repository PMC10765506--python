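"""Hierarchical grouping of ordinal phenotype codes.

The distinct 5-digit phenotype codes of a screening panel are clustered
with Euclidean distance and Ward's minimum-variance linkage; the number
of groups is chosen where the dendrogram shows its largest jump in merge
distance (the point where average within-group distance stops falling
sharply), and every isolate inherits the group of its phenotype code.

Groups keep their dendrogram order (colour-coded 1=yellow, 2=grey,
3=green, 4=pink when k=4) and additionally receive a desirability
ranking: killer-sensitive codes, high H₂S, acetic production and low SO₂
resistance are penalized, so the technologically preferred groups can be
identified programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .assays import DIGIT_NAMES, DIGIT_RANGES, PhenotypeCode
from .exceptions import NotEnoughItems
from .tree import LinkageTree, agglomerate

GROUP_COLORS = ("yellow", "grey", "green", "pink")

_KILLER_TEXT = {1: "neutral to killer toxin", 2: "sensitive to killer toxin",
                3: "killer-positive"}
_H2S_TEXT = {0: "no H2S production", 1: "low H2S production",
             2: "high H2S production", 3: "very high H2S production"}
_ACETIC_TEXT = {0: "acetic acid production", 1: "no acetic acid production"}
_SO2_TEXT = {0: "no SO2 resistance", 1: "SO2 resistance up to 300 mg/L",
             2: "SO2 resistance at 400-500 mg/L"}
_BGLU_TEXT = {0: "beta-glucosidase activity", 1: "no beta-glucosidase activity"}
_DIGIT_TEXT = (_KILLER_TEXT, _H2S_TEXT, _ACETIC_TEXT, _SO2_TEXT, _BGLU_TEXT)


def _as_matrix(codes) -> np.ndarray:
    X = np.array(
        [c.digits if isinstance(c, PhenotypeCode) else tuple(c) for c in codes],
        dtype=float,
    )
    if X.ndim != 2 or X.shape[1] != 5:
        raise ValueError("codes must be 5-digit vectors")
    return X


def euclidean_distance_matrix(codes, weights=None) -> np.ndarray:
    """Pairwise (weighted) Euclidean distances between phenotype codes.

    ``weights`` is a positive 5-vector applied per digit inside the square
    root: ``sqrt(sum_d w_d (x_d - y_d)^2)``; default all ones.
    """
    X = _as_matrix(codes)
    if X.shape[0] < 2:
        raise NotEnoughItems("need at least 2 codes")
    w = np.ones(5) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (5,) or np.any(w <= 0):
        raise ValueError("weights must be a positive 5-vector")
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((w * diff**2).sum(axis=-1))


def ward_linkage(dist: np.ndarray, labels=None) -> LinkageTree:
    """Ward (D2 convention) linkage tree from a distance matrix."""
    return agglomerate(dist, labels=labels, method="ward")


def desirability_penalty(code) -> float:
    """Oenological badness of one code; lower is a better starter candidate.

    Penalizes killer sensitivity (heaviest: such isolates are rejected
    outright), H₂S production, acetic production and low SO₂ resistance.
    """
    d = code.digits if isinstance(code, PhenotypeCode) else tuple(code)
    return 2.0 * (d[0] >= 2) + d[1] / 3.0 + (1 - d[2]) + (2 - d[3]) / 2.0


@dataclass
class GroupAssignment:
    """A partition of items into groups ``1..k`` with display metadata."""

    mapping: dict  # item label -> group in 1..k
    k: int
    colors: dict = field(default_factory=dict)  # group -> colour name
    desirability_rank: dict = field(default_factory=dict)  # group -> 1=best

    def members(self, group: int) -> list:
        return sorted(lbl for lbl, g in self.mapping.items() if g == group)


class WardPhenotypeClusterer(BaseEstimator, ClusterMixin):
    """Ward clustering of phenotype codes with largest-gap model selection.

    Parameters
    ----------
    n_groups : int or "auto"
        Number of groups; ``"auto"`` applies the largest merge-height gap
        rule (ties toward fewer groups).
    k_max : int
        Upper bound for automatic selection.
    weights : array-like of shape (5,), optional
        Per-digit distance weights (default unweighted; the digit priority
        order carries no weight under plain Euclidean distance).
    on_distinct : bool
        Cluster the distinct codes and let duplicates inherit the group
        (default, matching the screening workflow); ``False`` clusters
        rows directly.

    Attributes
    ----------
    tree_ : LinkageTree over the clustered units
    k_ : selected number of groups
    gap_profile_ : dict k -> merge-height gap
    assignment_ : GroupAssignment over the clustered units
    labels_ : ndarray, group of each input row
    """

    def __init__(self, n_groups="auto", k_max: int = 10, weights=None,
                 on_distinct: bool = True):
        self.n_groups = n_groups
        self.k_max = k_max
        self.weights = weights
        self.on_distinct = on_distinct

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if self.on_distinct:
            units, inverse = np.unique(X, axis=0, return_inverse=True)
        else:
            units, inverse = X, np.arange(len(X))
        if units.shape[0] < 2:
            raise NotEnoughItems("need at least 2 distinct codes to cluster")
        labels = ["".join(str(int(d)) for d in row) for row in units]
        dist = euclidean_distance_matrix(units, self.weights)
        self.tree_ = ward_linkage(dist, labels=labels)
        if self.n_groups == "auto":
            self.k_, self.gap_profile_ = self.tree_.select_k(self.k_max)
        else:
            self.k_ = int(self.n_groups)
            _, self.gap_profile_ = self.tree_.select_k(self.k_max)
        cut = self.tree_.cut(self.k_)
        colors = {g + 1: GROUP_COLORS[g] for g in range(min(self.k_, 4))}
        penalty = {
            g: float(np.mean([desirability_penalty(units[i])
                              for i, lbl in enumerate(labels) if cut[lbl] == g]))
            for g in range(1, self.k_ + 1)
        }
        order = sorted(penalty, key=lambda g: (penalty[g], g))
        rank = {g: r + 1 for r, g in enumerate(order)}
        self.assignment_ = GroupAssignment(cut, self.k_, colors, rank)
        self.units_ = units
        self.unit_labels_ = labels
        self.labels_ = np.array([cut[labels[i]] for i in inverse])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def characterize_groups(assignment: GroupAssignment, codes) -> pd.DataFrame:
    """Per-group digit profile: modal digit, range, and a text summary.

    ``codes`` maps each assigned item label to its PhenotypeCode (or a
    list aligned with ``sorted(assignment.mapping)``).
    """
    if not isinstance(codes, dict):
        codes = dict(zip(sorted(assignment.mapping), codes))
    rows = []
    for g in range(1, assignment.k + 1):
        members = assignment.members(g)
        digits = np.array([
            codes[m].digits if isinstance(codes[m], PhenotypeCode) else tuple(codes[m])
            for m in members
        ], dtype=int)
        row = {"group": g, "color": assignment.colors.get(g, ""), "n_codes": len(members)}
        phrases = []
        for d, name in enumerate(DIGIT_NAMES):
            col = digits[:, d]
            vals, counts = np.unique(col, return_counts=True)
            mode = int(vals[np.argmax(counts)])
            lo, hi = int(col.min()), int(col.max())
            assert DIGIT_RANGES[d][0] <= lo and hi <= max(DIGIT_RANGES[d][1], 3)
            row[f"{name}_mode"] = mode
            row[f"{name}_range"] = f"{lo}-{hi}" if lo != hi else str(lo)
            if lo == hi:
                phrases.append(_DIGIT_TEXT[d][mode])
            else:
                phrases.append(f"variable {name} (mostly {_DIGIT_TEXT[d][mode]})")
        row["summary"] = "; ".join(phrases)
        rows.append(row)
    return pd.DataFrame(rows)


def species_composition(groups, species) -> pd.DataFrame:
    """Group × species contingency table; row sums equal group sizes.

    ``groups`` and ``species`` are aligned per-isolate sequences.
    """
    df = pd.DataFrame({"group": list(groups), "species": list(species)})
    return pd.crosstab(df["group"], df["species"])
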