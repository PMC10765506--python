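"""Bundled reference dataset from a screening survey of indigenous wine
yeasts (14 spontaneously fermented Greek wines, 190 isolates, 20
*S. cerevisiae* strains).

Shipped here are the published summary tables of that survey: the sample
provenance table, the per-strain validation table (fermentation capacity,
sensory cluster, preliminary phenotypic group), the species/assay marginal
counts, and the strain-sharing lists across regions and wine types. They
serve as a worked example and as ground truth for the concordance
analysis. The full strain × region incidence matrix was not published;
:func:`reference_region_incidence` returns a synthetic completion that is
consistent with every published constraint (see its docstring).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: isolates identified per species across the 190-isolate survey
SPECIES_COUNTS = {
    "Saccharomyces cerevisiae": 168,
    "Trigonopsis californica": 1,
    "Brettanomyces bruxellensis": 5,
    "Zygosaccharomyces bailii": 8,
    "Priceomyces carsonii": 1,
    "Pichia manshurica": 7,
}

#: marginal assay counts over the 190 isolates
ASSAY_COUNTS = {
    "killer_sensitive": 23,
    "acetic_producers": 137,
    "acetic_non_producers": 53,
    "bglu_positive": 12,
    "so2_sensitive_at": {100: 6, 200: 12, 300: 11},
    "distinct_phenotypes": 29,
}

REGIONS = ("Santorini", "Pelion", "Nemea", "Goumenissa")

#: published strain-sharing facts across sampling regions
STRAINS_ALL_REGIONS = frozenset({"S10"})
REGION_EXCLUSIVE = {
    "Santorini": frozenset({"S15", "S17", "S18"}),
    "Nemea": frozenset({"S11", "S12", "S13"}),
    "Pelion": frozenset({"S1", "S2"}),
    "Goumenissa": frozenset(),
}

#: published strain-sharing facts across wine types
WINE_TYPE_BOTH = frozenset(
    {"S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9", "S10", "S20"}
)
WINE_TYPE_RED_ONLY = frozenset({"S1", "S11", "S12", "S13", "S14", "S19"})
WINE_TYPE_WHITE_ONLY = frozenset({"S15", "S16", "S17", "S18"})

ALL_STRAINS = tuple(f"S{i}" for i in range(1, 21))

#: sensory clusters considered desirable (fruity/floral B, complex A) vs
#: the off-odor clusters C and D — panel metadata, not computed
DESIRABLE_SENSORY = frozenset({"A", "B"})


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("oenotype.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_samples() -> pd.DataFrame:
    """The 14-sample provenance table (region, variety, type, vintage,
    isolates recovered)."""
    return _read_csv("samples.csv")


def load_strain_outcomes() -> pd.DataFrame:
    """The 20-strain validation table: fermentation capacity, sensory
    cluster, preliminary phenotypic group and validation flag."""
    df = _read_csv("strain_outcomes.csv")
    df["fermentation_capacity"] = df["fermentation_capacity"] == "yes"
    df["validated"] = df["validated"] == "yes"
    return df


def reference_region_incidence() -> pd.DataFrame:
    """Strain × region boolean incidence, completed synthetically.

    Published constraints honoured exactly: S10 occurs in all four
    regions; S15/S17/S18 only in Santorini, S11/S12/S13 only in Nemea,
    S1/S2 only in Pelion. The remaining strains are known to be shared
    (present in more than one region but not all) without a published
    matrix; they are placed deterministically in two regions each, so the
    completion is synthetic beyond the listed facts.
    """
    exclusive = {s: r for r, ss in REGION_EXCLUSIVE.items() for s in ss}
    pairs = [
        ("Santorini", "Pelion"),
        ("Pelion", "Nemea"),
        ("Nemea", "Goumenissa"),
        ("Goumenissa", "Santorini"),
    ]
    rows = {}
    shared_i = 0
    for s in ALL_STRAINS:
        row = {r: False for r in REGIONS}
        if s in STRAINS_ALL_REGIONS:
            row = {r: True for r in REGIONS}
        elif s in exclusive:
            row[exclusive[s]] = True
        else:
            a, b = pairs[shared_i % len(pairs)]
            row[a] = row[b] = True
            shared_i += 1
        rows[s] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(REGIONS)]


def reference_wine_type_incidence() -> pd.DataFrame:
    """Strain × wine-type boolean incidence from the published lists."""
    rows = {}
    for s in ALL_STRAINS:
        rows[s] = {
            "red": s in WINE_TYPE_BOTH or s in WINE_TYPE_RED_ONLY,
            "white": s in WINE_TYPE_BOTH or s in WINE_TYPE_WHITE_ONLY,
        }
    return pd.DataFrame.from_dict(rows, orient="index")[["red", "white"]]
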