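"""Isolate/assay data model and ordinal phenotype coding.

Five plate assays are screened per isolate — killer-toxin character, H₂S
production (colony browning scored 0–3 at days 2/5/8), acetic-acid halo,
growth on increasing free-SO₂ doses, and β-glucosidase (arbutin) activity —
and collapsed into a 5-digit ordinal phenotype code ordered by oenological
priority: killer, H₂S, acetic acid, SO₂ resistance, β-glucosidase.

The coding scheme:

====== ==================== =============================================
digit  assay                coding
====== ==================== =============================================
1      killer character     1 = neutral, 2 = sensitive
2      H₂S production       0 none, 1 low, 2 high, 3 very high
3      acetic acid          0 = production, 1 = no production
4      SO₂ resistance       0 none, 1 up to 300 mg/L, 2 at 400–500 mg/L
5      β-glucosidase        0 = positive, 1 = negative
====== ==================== =============================================

Note the inverted polarity of digits 3 and 5: zero marks the *presence* of
the trait (acetic production is undesirable, β-glucosidase is desirable).
Killer-positive isolates have no code by default — none occur in wine-fit
screening panels — but an opt-in extension maps them to 3.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    EmptyDataset,
    IncompleteAssay,
    NonMonotoneProfile,
    UnsupportedPhenotype,
)

H2S_DAYS = (2, 5, 8)
SO2_DOSES = (0, 100, 200, 300, 400, 500)  # mg/L free SO2
H2S_POLICIES = ("day8", "max", "mean")

KILLER_STATES = ("killer_positive", "sensitive", "neutral")
REGIONS = ("Santorini", "Pelion", "Nemea", "Goumenissa", "other")

#: inclusive (low, high) range of each code digit
DIGIT_RANGES = ((1, 2), (0, 3), (0, 1), (0, 2), (0, 1))

DIGIT_NAMES = ("killer", "h2s", "acetic", "so2", "bglu")


@dataclass(frozen=True)
class AssayPanel:
    """Raw outcomes of the five screening assays for one isolate."""

    killer: str
    h2s_scores: dict  # day in {2,5,8} -> score in {0..3}
    acetic: str  # "producer" | "non_producer"
    so2_growth: dict  # dose mg/L in {0..500} -> bool grew
    bglu: str  # "positive" | "negative"

    def __post_init__(self):
        if self.killer not in KILLER_STATES:
            raise ValueError(f"unknown killer state {self.killer!r}")
        if self.acetic not in ("producer", "non_producer"):
            raise ValueError(f"unknown acetic state {self.acetic!r}")
        if self.bglu not in ("positive", "negative"):
            raise ValueError(f"unknown bglu state {self.bglu!r}")
        for day in H2S_DAYS:
            if day in self.h2s_scores and self.h2s_scores[day] not in (0, 1, 2, 3):
                raise ValueError(f"H2S score at day {day} outside 0-3")
        if 0 in self.so2_growth and not self.so2_growth[0]:
            raise ValueError("no growth on the SO2-free control plate")


@dataclass(frozen=True)
class IsolateRecord:
    """One isolate with its provenance metadata and assay panel."""

    isolate_id: str
    sample_id: str
    region: str
    variety: str
    wine_type: str  # "red" | "white"
    vintage: int
    species: str
    assays: AssayPanel
    group_truth: int | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (1900 <= int(self.vintage) <= 2100):
            raise ValueError(f"vintage {self.vintage} outside [1900, 2100]")
        if self.wine_type not in ("red", "white"):
            raise ValueError(f"wine_type must be red/white, got {self.wine_type!r}")


@dataclass(frozen=True, order=True)
class PhenotypeCode:
    """Ordered 5-digit ordinal phenotype (killer, H₂S, acetic, SO₂, β-glu)."""

    digits: tuple

    def __post_init__(self):
        if len(self.digits) != 5:
            raise ValueError("phenotype code has exactly 5 digits")
        for d, (lo, hi) in zip(self.digits, DIGIT_RANGES):
            # digit 1 may be 3 only through the opt-in killer-positive mapping
            hi_eff = 3 if (lo, hi) == (1, 2) else hi
            if not (lo <= d <= hi_eff):
                raise ValueError(f"digit {d} outside [{lo}, {hi_eff}]")

    def __str__(self):
        return "".join(str(d) for d in self.digits)

    def as_array(self):
        return np.asarray(self.digits, dtype=float)


def encode_killer(killer: str, allow_killer_positive: bool = False) -> int:
    """Code the killer character: neutral→1, sensitive→2.

    Killer-positive isolates are outside the scheme and raise
    :class:`UnsupportedPhenotype` unless ``allow_killer_positive`` maps
    them to the extension digit 3.
    """
    if killer == "neutral":
        return 1
    if killer == "sensitive":
        return 2
    if killer == "killer_positive":
        if allow_killer_positive:
            return 3
        raise UnsupportedPhenotype(
            "killer-positive isolates have no code in the default scheme; "
            "pass allow_killer_positive=True to map them to 3"
        )
    raise ValueError(f"unknown killer state {killer!r}")


def encode_h2s(h2s_scores: dict, policy: str = "day8") -> int:
    """Collapse the day-2/5/8 H₂S colour scores to one digit 0–3.

    ``policy`` is one of ``day8`` (final reading, default), ``max``
    (worst reading), or ``mean`` (arithmetic mean rounded half up).
    """
    missing = [d for d in H2S_DAYS if d not in h2s_scores]
    if missing:
        raise IncompleteAssay(f"H2S series missing day(s) {missing}")
    series = [h2s_scores[d] for d in H2S_DAYS]
    if policy == "day8":
        return int(h2s_scores[8])
    if policy == "max":
        return int(max(series))
    if policy == "mean":
        return int(np.floor(np.mean(series) + 0.5))
    raise ValueError(f"unknown H2S policy {policy!r}; choose from {H2S_POLICIES}")


def encode_acetic(acetic: str) -> int:
    """Acetic-acid halo: producer→0, non-producer→1 (0 is the bad state)."""
    if acetic == "producer":
        return 0
    if acetic == "non_producer":
        return 1
    raise ValueError(f"unknown acetic state {acetic!r}")


def decode_acetic(digit: int) -> str:
    return {0: "producer", 1: "non_producer"}[digit]


def encode_so2(so2_growth: dict) -> int:
    """SO₂-resistance digit from the growth/no-growth dose series.

    2 if the isolate grew at 400 or 500 mg/L, 1 if it grew at any of
    100–300 mg/L only, 0 if it grew on the control plate only. A
    non-monotone profile (growth at a high dose but not at a lower one)
    warns and is coded from the highest dose with growth.
    """
    missing = [c for c in SO2_DOSES if c not in so2_growth]
    if missing:
        raise IncompleteAssay(f"SO2 series missing dose(s) {missing}")
    if not so2_growth[0]:
        raise ValueError("no growth on the SO2-free control plate")
    grew = [c for c in SO2_DOSES if so2_growth[c]]
    top = max(grew)
    holes = [c for c in SO2_DOSES if c < top and not so2_growth[c]]
    if holes:
        warnings.warn(
            f"non-monotone SO2 profile: growth at {top} but not at {holes} mg/L; "
            "coding from the highest dose with growth",
            NonMonotoneProfile,
        )
    if top >= 400:
        return 2
    if top >= 100:
        return 1
    return 0


def encode_bglu(bglu: str) -> int:
    """β-glucosidase (arbutin browning): positive→0, negative→1."""
    if bglu == "positive":
        return 0
    if bglu == "negative":
        return 1
    raise ValueError(f"unknown bglu state {bglu!r}")


def decode_bglu(digit: int) -> str:
    return {0: "positive", 1: "negative"}[digit]


def encode_phenotype(
    panel: AssayPanel,
    policy: str = "day8",
    allow_killer_positive: bool = False,
) -> PhenotypeCode:
    """Encode a full assay panel into its 5-digit phenotype code."""
    return PhenotypeCode(
        (
            encode_killer(panel.killer, allow_killer_positive),
            encode_h2s(panel.h2s_scores, policy),
            encode_acetic(panel.acetic),
            encode_so2(panel.so2_growth),
            encode_bglu(panel.bglu),
        )
    )


def distinct_phenotypes(records) -> list:
    """Unique phenotype codes with multiplicities, lexicographically sorted.

    Accepts IsolateRecords (encoded with default policy) or PhenotypeCodes.
    Returns a list of ``(PhenotypeCode, count)``; counts sum to ``len(records)``.
    """
    records = list(records)
    if not records:
        raise EmptyDataset("no records to tabulate")
    codes = [
        r if isinstance(r, PhenotypeCode) else encode_phenotype(r.assays)
        for r in records
    ]
    counts = Counter(codes)
    return sorted(counts.items(), key=lambda kv: kv[0].digits)


class PhenotypeEncoder(BaseEstimator, TransformerMixin):
    """Transformer from assay panels to the 5-digit ordinal code matrix.

    Parameters
    ----------
    h2s_policy : {"day8", "max", "mean"}
        How the three H₂S time points collapse to one digit.
    allow_killer_positive : bool
        Map killer-positive isolates to the extension digit 3 instead of
        raising.

    Attributes
    ----------
    codes_ : list of PhenotypeCode
        Codes of the panels seen at the last ``transform``.
    """

    def __init__(self, h2s_policy: str = "day8", allow_killer_positive: bool = False):
        self.h2s_policy = h2s_policy
        self.allow_killer_positive = allow_killer_positive

    def fit(self, X, y=None):
        if self.h2s_policy not in H2S_POLICIES:
            raise ValueError(f"h2s_policy must be one of {H2S_POLICIES}")
        self.n_features_in_ = 5
        return self

    def transform(self, X):
        """Encode panels (or IsolateRecords) to an ``(n, 5)`` integer array."""
        self.fit(X)
        panels = [x.assays if isinstance(x, IsolateRecord) else x for x in X]
        self.codes_ = [
            encode_phenotype(p, self.h2s_policy, self.allow_killer_positive)
            for p in panels
        ]
        return np.array([c.digits for c in self.codes_], dtype=int)


# ---------------------------------------------------------------------------
# CSV dialect: one row per isolate
# isolate_id,sample_id,region,variety,wine_type,vintage,species,killer,
# h2s_d2,h2s_d5,h2s_d8,acetic,so2_100,...,so2_500,bglu

_SO2_COLS = [f"so2_{c}" for c in SO2_DOSES if c > 0]
ASSAY_COLUMNS = (
    ["isolate_id", "sample_id", "region", "variety", "wine_type", "vintage", "species"]
    + ["killer", "h2s_d2", "h2s_d5", "h2s_d8", "acetic"]
    + _SO2_COLS
    + ["bglu"]
)


def read_assay_csv(path) -> list:
    """Read the per-isolate assay table into IsolateRecords."""
    df = pd.read_csv(path)
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assay CSV missing column(s): {sorted(missing)}")
    if df.empty:
        raise EmptyDataset(f"assay CSV {path} has no rows")
    dup = df["isolate_id"][df["isolate_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate isolate_id(s): {sorted(dup.unique())}")
    records = []
    for _, row in df.iterrows():
        panel = AssayPanel(
            killer=row["killer"],
            h2s_scores={d: int(row[f"h2s_d{d}"]) for d in H2S_DAYS},
            acetic=row["acetic"],
            so2_growth={0: True, **{c: bool(int(row[f"so2_{c}"])) for c in SO2_DOSES if c}},
            bglu=row["bglu"],
        )
        records.append(
            IsolateRecord(
                isolate_id=str(row["isolate_id"]),
                sample_id=str(row["sample_id"]),
                region=str(row["region"]),
                variety=str(row["variety"]),
                wine_type=str(row["wine_type"]),
                vintage=int(row["vintage"]),
                species=str(row["species"]),
                assays=panel,
            )
        )
    return records


def write_assay_csv(records, path) -> None:
    """Write IsolateRecords back to the assay CSV dialect."""
    rows = []
    for r in records:
        p = r.assays
        row = {
            "isolate_id": r.isolate_id,
            "sample_id": r.sample_id,
            "region": r.region,
            "variety": r.variety,
            "wine_type": r.wine_type,
            "vintage": r.vintage,
            "species": r.species,
            "killer": p.killer,
            "acetic": p.acetic,
            "bglu": p.bglu,
        }
        for d in H2S_DAYS:
            row[f"h2s_d{d}"] = p.h2s_scores[d]
        for c in SO2_DOSES:
            if c:
                row[f"so2_{c}"] = int(p.so2_growth[c])
        rows.append(row)
    pd.DataFrame(rows, columns=ASSAY_COLUMNS).to_csv(path, index=False)


def write_phenotype_csv(records, path, policy: str = "day8") -> None:
    """Encode records and write the phenotype table (one digit per column)."""
    rows = []
    for r in records:
        code = encode_phenotype(r.assays, policy)
        row = {"isolate_id": r.isolate_id}
        row.update({f"d_{n}": d for n, d in zip(DIGIT_NAMES, code.digits)})
        row["code"] = str(code)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_phenotype_csv(path) -> pd.DataFrame:
    """Read a phenotype table written by :func:`write_phenotype_csv`."""
    df = pd.read_csv(path, dtype={"code": str})
    needed = {"isolate_id"} | {f"d_{n}" for n in DIGIT_NAMES}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing column(s): {sorted(missing)}")
    return df
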