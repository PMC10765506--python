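"""Seeded synthetic-data generators mirroring the screening study design.

Three generators produce inputs with the statistical structure the
analysis stages assume:

* an isolate panel (default 190 isolates) drawn from four phenotype
  prototypes with per-digit ordinal perturbation — grading error moves a
  digit to an *adjacent* legal value, as colour/dose scales err by one
  step, not arbitrarily;
* a free-sorting panel (default 10 panelists × 13 wines) where each
  panelist copies a consensus partition and reassigns each wine with
  probability ``1 − agreement`` to a uniformly random other group;
* fermentation curves with exponential sugar depletion from the must's
  initial 119.5 g/L glucose and 120.1 g/L fructose, plus truncated
  Gaussian measurement noise; slow strains plateau above the 10 g/L
  dryness threshold.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import DIGIT_RANGES, AssayPanel, IsolateRecord, PhenotypeCode
from .data import reference
from .fermentation import FermentationCurve

#: default group prototypes, one per phenotypic group observed in practice:
#: 1 killer-sensitive / very high H2S / acetic / no SO2 resistance; 2 neutral /
#: no H2S / no acetic / little SO2 resistance; 3 neutral / low H2S / acetic /
#: resistant; 4 neutral / very high H2S / acetic / resistant / bglu-positive.
#: Pairwise Euclidean separation >= 2.2, so a single one-step grading slip
#: (distance 1) never moves a code closer to a foreign prototype.
DEFAULT_PROTOTYPES = (
    PhenotypeCode((2, 3, 0, 0, 1)),
    PhenotypeCode((1, 0, 1, 0, 1)),
    PhenotypeCode((1, 1, 0, 2, 1)),
    PhenotypeCode((1, 3, 0, 2, 0)),
)

#: group mixing weights, mirroring the observed marginals (~12% of isolates
#: killer-sensitive; two large neutral groups; a small high-H2S group)
DEFAULT_GROUP_WEIGHTS = (0.12, 0.35, 0.40, 0.13)

DEFAULT_SPECIES_MIX = (
    {"Saccharomyces cerevisiae": 0.85, "Zygosaccharomyces bailii": 0.1,
     "Trigonopsis californica": 0.05},
    {"Saccharomyces cerevisiae": 0.9, "Pichia manshurica": 0.1},
    {"Saccharomyces cerevisiae": 0.95, "Zygosaccharomyces bailii": 0.05},
    {"Saccharomyces cerevisiae": 0.8, "Brettanomyces bruxellensis": 0.2},
)

INITIAL_GLUCOSE = 119.5  # g/L
INITIAL_FRUCTOSE = 120.1  # g/L
FAST_RATE = 0.5  # 1/day, finishes dry within two weeks
SLOW_RATE = 0.05  # 1/day, stalls above the dryness threshold

DEFAULT_WINES = tuple(f"W{i:02d}" for i in range(1, 14))
#: 13 wines in 4 consensus aroma groups
DEFAULT_CONSENSUS = {
    "W01": 1, "W02": 1, "W03": 1, "W04": 1,
    "W05": 2, "W06": 2, "W07": 2,
    "W08": 3, "W09": 3, "W10": 3,
    "W11": 4, "W12": 4, "W13": 4,
}


@dataclass
class SimulationConfig:
    """Bundle of generator settings; defaults mirror the study design."""

    seed: int = 0
    n_isolates: int = 190
    prototypes: tuple = DEFAULT_PROTOTYPES
    group_weights: tuple = DEFAULT_GROUP_WEIGHTS
    flip_prob: float = 0.03
    species_mix: tuple = DEFAULT_SPECIES_MIX
    n_panelists: int = 10
    consensus: dict = field(default_factory=lambda: dict(DEFAULT_CONSENSUS))
    agreement: float = 0.9
    n_strains: int = 20
    n_slow_strains: int = 7
    fast_rate: float = FAST_RATE
    slow_rate: float = SLOW_RATE
    n_days: int = 14
    noise_sd: float = 1.0

    def __post_init__(self):
        if not self.prototypes:
            raise ValueError("need at least one prototype")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be in [0, 1]")
        if not (0.0 <= self.agreement <= 1.0):
            raise ValueError("agreement must be in [0, 1]")
        if self.fast_rate <= 0 or self.slow_rate <= 0:
            raise ValueError("decay rates must be positive")


def _perturb_code(digits, flip_prob, rng) -> tuple:
    """Move each digit to an adjacent legal value with prob ``flip_prob``."""
    out = []
    for d, (lo, hi) in zip(digits, DIGIT_RANGES):
        if rng.random() < flip_prob:
            if d <= lo:
                d = d + 1
            elif d >= hi:
                d = d - 1
            else:
                d = d + (1 if rng.random() < 0.5 else -1)
        out.append(int(d))
    return tuple(out)


def _panel_from_code(code: tuple) -> AssayPanel:
    """Construct an assay panel that encodes (day-8 policy) to ``code``."""
    k, h, a, s, b = code
    return AssayPanel(
        killer={1: "neutral", 2: "sensitive", 3: "killer_positive"}[k],
        h2s_scores={2: max(h - 2, 0), 5: max(h - 1, 0), 8: h},
        acetic={0: "producer", 1: "non_producer"}[a],
        so2_growth={0: True, 100: s >= 1, 200: s >= 1, 300: s >= 1,
                    400: s >= 2, 500: s >= 2},
        bglu={0: "positive", 1: "negative"}[b],
    )


def gen_isolate_panel(config: SimulationConfig | None = None, *, rng=None):
    """Generate an isolate panel with planted phenotype groups.

    Returns ``(records, truth)`` where ``truth`` is the planted group
    index (1-based) per record; the records also carry it in
    ``group_truth``. Sample provenance is drawn from the bundled
    14-sample reference table, weighted by its isolate counts.
    """
    config = config or SimulationConfig()
    rng = rng or np.random.default_rng(config.seed)
    for proto in config.prototypes:
        PhenotypeCode(tuple(proto.digits))  # re-validate: raises if illegal
    weights = np.asarray(config.group_weights, dtype=float)
    weights = weights / weights.sum()
    samples = reference.load_samples()
    sample_p = samples["isolates"].to_numpy(float)
    sample_p /= sample_p.sum()

    records, truth = [], []
    for i in range(config.n_isolates):
        g = int(rng.choice(len(config.prototypes), p=weights))
        code = _perturb_code(config.prototypes[g].digits, config.flip_prob, rng)
        mix = config.species_mix[g % len(config.species_mix)]
        species = str(rng.choice(list(mix), p=np.array(list(mix.values()))
                                 / sum(mix.values())))
        srow = samples.iloc[int(rng.choice(len(samples), p=sample_p))]
        records.append(IsolateRecord(
            isolate_id=f"Y{i + 1:03d}",
            sample_id=str(srow["sample_id"]),
            region=str(srow["region"]),
            variety=str(srow["variety"]),
            wine_type=str(srow["wine_type"]),
            vintage=int(srow["vintage"]),
            species=species,
            assays=_panel_from_code(code),
            group_truth=g + 1,
        ))
        truth.append(g + 1)
    return records, np.array(truth)


def gen_sorting_panel(config: SimulationConfig | None = None, *, rng=None):
    """Generate panelist sorting sheets around a consensus partition.

    Each panelist copies the consensus and reassigns each wine with
    probability ``1 − agreement`` to a uniformly random *other* group.
    Returns ``(sheets, consensus)``.
    """
    from .sorting import SortingSheet  # local import avoids a cycle

    config = config or SimulationConfig()
    rng = rng or np.random.default_rng(config.seed)
    consensus = dict(config.consensus)
    if not consensus:
        raise ValueError("consensus partition is empty")
    groups = sorted(set(consensus.values()))
    sheets = []
    for p in range(config.n_panelists):
        partition = {}
        for wine in sorted(consensus):
            g = consensus[wine]
            if len(groups) > 1 and rng.random() > config.agreement:
                others = [x for x in groups if x != g]
                g = others[int(rng.integers(len(others)))]
            partition[wine] = g
        sheets.append(SortingSheet(panelist_id=f"P{p + 1:02d}", partition=partition))
    return sheets, consensus


def sugar_curve(rate: float, days, initial: float) -> np.ndarray:
    """Noise-free exponential depletion ``initial * exp(-rate * day)``."""
    return initial * np.exp(-rate * np.asarray(days, dtype=float))


def gen_fermentation(config: SimulationConfig | None = None, *, rng=None,
                     n_replicates: int = 2):
    """Generate fermentation curves for fast (dry) and slow (stuck) strains.

    The first ``n_strains − n_slow_strains`` strains deplete at
    ``fast_rate`` and finish dry; the rest at ``slow_rate`` and plateau
    above the dryness threshold. Returns ``(curves, capacity_truth)``.
    """
    config = config or SimulationConfig()
    rng = rng or np.random.default_rng(config.seed)
    days = tuple(range(config.n_days + 1))
    curves, truth = [], {}
    for i in range(config.n_strains):
        sid = f"S{i + 1}"
        slow = i >= config.n_strains - config.n_slow_strains
        rate = config.slow_rate if slow else config.fast_rate
        truth[sid] = not slow
        for rep in range(n_replicates):
            glu = sugar_curve(rate, days, INITIAL_GLUCOSE)
            fru = sugar_curve(rate, days, INITIAL_FRUCTOSE)
            if config.noise_sd > 0:
                glu = np.maximum(glu + rng.normal(0, config.noise_sd, len(days)), 0)
                fru = np.maximum(fru + rng.normal(0, config.noise_sd, len(days)), 0)
            curves.append(FermentationCurve(
                strain_id=sid, days=days,
                glucose=tuple(np.round(glu, 3)),
                fructose=tuple(np.round(fru, 3)),
                replicate=str(rep + 1),
            ))
    return curves, truth
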