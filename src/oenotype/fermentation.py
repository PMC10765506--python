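"""Fermentation-outcome classification and concordance validation.

Micro-fermentations of pasteurized grape must are monitored by daily
glucose/fructose measurements; a strain has *fermentation capacity* when
its wine finishes dry, i.e. residual sugar (glucose + fructose at the
final day, averaged over replicates) does not exceed 10 g/L. Wines above
the threshold are stuck/sluggish and their strains rejected. Capacity,
sensory cluster (from the free-sorting stage) and preliminary phenotypic
group are then joined per strain and summarized into a concordance table,
from which the favorable phenotypic groups — those whose capable strains
land predominantly in desirable sensory clusters — are identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyDataset

DRYNESS_THRESHOLD = 10.0  # g/L residual sugar

#: distinct-strain counts delimiting community richness types
RICHNESS_BOUNDS = (2, 4)  # type 1: <=2, type 2: 3-4, type 3: >=5


@dataclass(frozen=True)
class FermentationCurve:
    """Daily sugar measurements of one fermentation replicate."""

    strain_id: str
    days: tuple
    glucose: tuple  # g/L
    fructose: tuple  # g/L
    replicate: str = "1"

    def __post_init__(self):
        if len(self.days) == 0:
            raise EmptyDataset(f"strain {self.strain_id!r}: empty curve")
        if not (len(self.days) == len(self.glucose) == len(self.fructose)):
            raise ValueError("days/glucose/fructose lengths differ")
        if any(d2 <= d1 for d1, d2 in zip(self.days, self.days[1:])):
            raise ValueError("day series must be strictly increasing")
        if min(self.glucose) < 0 or min(self.fructose) < 0:
            raise ValueError("sugar concentrations must be nonnegative")


def residual_sugar(curves) -> float:
    """Residual sugar in g/L: glucose + fructose at the final day.

    Accepts one curve or an iterable of replicate curves of the same
    strain (averaged).
    """
    if isinstance(curves, FermentationCurve):
        curves = [curves]
    curves = list(curves)
    if not curves:
        raise EmptyDataset("no fermentation curves")
    finals = [c.glucose[-1] + c.fructose[-1] for c in curves]
    return float(np.mean(finals))


def fermentation_capacity(curves, threshold: float = DRYNESS_THRESHOLD) -> bool:
    """True when the wine finishes dry (residual sugar ≤ threshold).

    Residual sugar strictly greater than the threshold (default 10 g/L)
    marks a stuck fermentation; exactly at the boundary passes.
    """
    return residual_sugar(curves) <= threshold


def classify_strains(curves, threshold: float = DRYNESS_THRESHOLD) -> pd.DataFrame:
    """Per-strain residual sugar and capacity from a pool of replicates."""
    by_strain = {}
    for c in curves:
        by_strain.setdefault(c.strain_id, []).append(c)
    rows = [
        {
            "strain_id": sid,
            "residual_sugar": residual_sugar(reps),
            "capacity": fermentation_capacity(reps, threshold),
            "n_replicates": len(reps),
        }
        for sid, reps in sorted(by_strain.items())
    ]
    return pd.DataFrame(rows)


@dataclass
class ConcordanceSummary:
    """Aggregate view of the strain validation table."""

    n_strains: int
    capacity_count: int
    capacity_rate: float
    n_sensory_wines: int
    group_sizes: dict  # preliminary group -> strain count
    cross_tab: pd.DataFrame  # preliminary group x sensory group
    validation_rate: float
    favorable: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "n_strains": self.n_strains,
            "capacity_count": self.capacity_count,
            "capacity_rate": self.capacity_rate,
            "n_sensory_wines": self.n_sensory_wines,
            "group_sizes": dict(self.group_sizes),
            "cross_tab": {str(k): v for k, v in
                          self.cross_tab.to_dict(orient="index").items()},
            "validation_rate": self.validation_rate,
            "favorable_groups": sorted(self.favorable),
        }


def concordance_table(outcomes: pd.DataFrame,
                      desirable=frozenset({"A", "B"})) -> ConcordanceSummary:
    """Summarize the strain outcome table.

    ``outcomes`` needs columns ``strain_id``, ``fermentation_capacity``
    (bool), ``sensory_group`` (letter or "none"), ``preliminary_group``
    and ``validated`` (bool). Failed fermentations carry no sensory
    group: only capable strains' wines enter the sorting stage.
    """
    if outcomes.empty:
        raise EmptyDataset("no strain outcomes")
    cap = outcomes["fermentation_capacity"].astype(bool)
    bad = outcomes.loc[~cap & (outcomes["sensory_group"] != "none"), "strain_id"]
    if not bad.empty:
        raise ValueError(f"strains without capacity cannot have a sensory group: "
                         f"{sorted(bad)}")
    n = len(outcomes)
    sizes = outcomes["preliminary_group"].value_counts().to_dict()
    cross = pd.crosstab(outcomes["preliminary_group"], outcomes["sensory_group"])
    summary = ConcordanceSummary(
        n_strains=n,
        capacity_count=int(cap.sum()),
        capacity_rate=float(cap.mean()),
        n_sensory_wines=int(cap.sum()),
        group_sizes={str(k): int(v) for k, v in sizes.items()},
        cross_tab=cross,
        validation_rate=float(outcomes["validated"].astype(bool).mean()),
    )
    summary.favorable = favorable_groups(outcomes, desirable)
    return summary


def favorable_groups(outcomes: pd.DataFrame,
                     desirable=frozenset({"A", "B"})) -> set:
    """Phenotypic groups whose capable strains fall predominantly (>50%)
    in desirable sensory clusters; groups with no capable strains are
    never favorable."""
    capable = outcomes[outcomes["fermentation_capacity"].astype(bool)]
    out = set()
    for group, sub in capable.groupby("preliminary_group"):
        share = sub["sensory_group"].isin(desirable).mean()
        if share > 0.5:
            out.add(str(group))
    return out


def region_sharing(incidence: pd.DataFrame) -> dict:
    """Unique vs shared strains per region from a boolean incidence table.

    Returns ``exclusive`` (region -> strains found only there), ``shared``
    (region -> strains found there and elsewhere), ``in_all_regions``,
    and per-strain region counts.
    """
    inc = incidence.astype(bool)
    if not inc.any(axis=1).all():
        missing = inc.index[~inc.any(axis=1)]
        raise ValueError(f"strains present nowhere: {sorted(missing)}")
    n_regions = inc.sum(axis=1)
    exclusive = {
        r: set(inc.index[inc[r] & (n_regions == 1)]) for r in inc.columns
    }
    shared = {
        r: set(inc.index[inc[r] & (n_regions > 1)]) for r in inc.columns
    }
    return {
        "exclusive": exclusive,
        "shared": shared,
        "in_all_regions": set(inc.index[n_regions == len(inc.columns)]),
        "region_counts": n_regions.to_dict(),
    }


def wine_type_sharing(incidence: pd.DataFrame) -> dict:
    """Strain sets found in both wine types, red only, and white only."""
    inc = incidence.astype(bool)
    return {
        "both": set(inc.index[inc["red"] & inc["white"]]),
        "red_only": set(inc.index[inc["red"] & ~inc["white"]]),
        "white_only": set(inc.index[~inc["red"] & inc["white"]]),
    }


def community_richness(strain_counts: dict, bounds=RICHNESS_BOUNDS) -> dict:
    """Community type per sample from its distinct-strain count.

    Type 1: up to ``bounds[0]`` strains (one or two dominants); type 2:
    up to ``bounds[1]``; type 3: richer communities (the published
    exemplars ran to seven–eight strains). Counts strictly between the
    published exemplars fall in type 3 by default.
    """
    lo, hi = bounds
    out = {}
    for sample, n in strain_counts.items():
        out[sample] = 1 if n <= lo else (2 if n <= hi else 3)
    return out


# ---------------------------------------------------------------------------
# IO


def read_fermentation_csv(path) -> list:
    """Read long-format daily sugar measurements into curves.

    Columns: ``strain_id, day, glucose, fructose[, replicate]``.
    """
    df = pd.read_csv(path)
    needed = {"strain_id", "day", "glucose", "fructose"}
    if not needed <= set(df.columns):
        raise ValueError(f"fermentation CSV needs columns {sorted(needed)}")
    if "replicate" not in df.columns:
        df = df.assign(replicate="1")
    curves = []
    for (sid, rep), sub in df.groupby(["strain_id", "replicate"], sort=True):
        sub = sub.sort_values("day")
        curves.append(FermentationCurve(
            strain_id=str(sid),
            days=tuple(sub["day"]),
            glucose=tuple(sub["glucose"]),
            fructose=tuple(sub["fructose"]),
            replicate=str(rep),
        ))
    return curves


def read_outcomes_csv(path) -> pd.DataFrame:
    """Read a strain outcome table in the bundled-reference dialect."""
    df = pd.read_csv(path)
    needed = {"strain_id", "fermentation_capacity", "sensory_group",
              "preliminary_group", "validated"}
    if not needed <= set(df.columns):
        raise ValueError(f"outcomes CSV needs columns {sorted(needed)}")
    for col in ("fermentation_capacity", "validated"):
        if df[col].dtype == object:
            df[col] = df[col].isin(["yes", "true", "True", "1"])
    return df
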