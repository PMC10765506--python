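# Methods

This note documents the models, numerical choices and limitations of the
`oenotype` pipeline in the order the stages run.

## Ordinal phenotype coding

Five plate assays map to one digit each, in oenological priority order
(killer, H₂S, acetic acid, SO₂ resistance, β-glucosidase):

| digit | range | coding |
|---|---|---|
| killer | 1–2 | 1 neutral, 2 sensitive |
| H₂S | 0–3 | colony browning score |
| acetic | 0–1 | 0 production, 1 none |
| SO₂ | 0–2 | 0 none, 1 up to 300 mg/L, 2 at 400–500 mg/L |
| β-glu | 0–1 | 0 positive, 1 negative |

Choices worth stating:

* **Killer-positive isolates have no code.** They do not occur in
  end-of-fermentation wine isolations (a killer strain would have
  suppressed the rest), so the default is a hard
  `UnsupportedPhenotype` error; `allow_killer_positive=True` maps them
  to an extension digit 3 for forward compatibility.
* **H₂S is measured at days 2/5/8 but coded as one digit.** No single
  collapse is canonical, so the policy is explicit: `day8` (default,
  the reading at assay end), `max` (worst browning seen), or `mean`
  (rounded half up). The choice is a parameter of
  `PhenotypeEncoder`/`encode`, recorded in outputs.
* **SO₂ digit comes from the highest dose with growth.** Non-monotone
  dose series (growth at 400 but not 200 mg/L) are plate artifacts;
  they warn (`NonMonotoneProfile`) rather than fail and are coded from
  the top growing dose.
* Codes are stored as integer vectors, never concatenated strings, so
  per-digit distance weights remain possible.

## Linkage engine

Both clustering flavours run through one Lance–Williams agglomeration
(`oenotype.tree.agglomerate`):

* **Ward** in the D2 convention: the recurrence operates on squared
  distances and heights are reported on the distance scale
  (`sqrt(2·ΔSSE)`), the standard Ward for Euclidean input. Two
  singletons at distance *d* merge at height *d*.
* **UPGMA**: size-weighted average linkage, equal to the plain mean of
  all original cross-pair distances.

Phenotype codes are small integers, so exactly tied merge candidates are
common; scipy's merge order is then an implementation accident. The
in-package engine breaks ties toward the lexicographically smallest pair
of cluster keys (a cluster's key is its smallest leaf label), which
makes trees deterministic and invariant under permutation of the input
rows. The engine is validated two ways in the test suite: against
from-scratch oracles that recompute the Ward variance objective /
cross-pair averages at every step (200 random integer instances each),
and against `scipy.cluster.hierarchy` on tie-free float data. Trees
export as scipy-format linkage matrices and Newick (via scikit-bio).

## Choosing the number of groups

`LinkageTree.select_k` formalizes the dendrogram reading "cut where the
distance axis shows its greatest change": *k* = the cluster count
obtained by cutting inside the largest gap between consecutive merge
heights, bounded by `k_max` (default 10), ties toward fewer groups, and
the full gap profile is returned for reporting. A degenerate profile
(all heights equal) warns and returns k = 2.

Two clustering units are supported. The default clusters the *distinct*
codes (the unit a screening lab inspects; duplicates inherit the group).
`on_distinct=False` clusters isolate rows directly, which weights each
code by its multiplicity — this is the variance objective over isolates
and is the variant recommended for automatic k selection: on unweighted
distinct codes the gap rule leans toward the coarse 2-split whenever the
between-group separations are uneven, mirroring the judgment a manual
dendrogram reading needs. Digit priority carries no weight under plain
Euclidean distance; a positive 5-vector of weights is accepted where
users want to encode it.

Groups keep dendrogram order for display (colours yellow/grey/green/pink
when k = 4) and additionally get a desirability rank from the mean
penalty `2·[killer-sensitive] + H₂S/3 + [acetic producer] +
(2 − SO₂)/2` — lower is a better starter candidate. β-glucosidase is
deliberately left out of the penalty: it is a bonus trait, not a
rejection criterion.

## Fingerprint grouping

Band patterns are sets of normalized band identifiers; gel image
processing and band calling are out of scope (they happen in acquisition
software). Dice similarity feeds UPGMA on 1 − similarity; the tree is
cut at distance 1 − threshold with threshold 0.90 by default, read as
"clusters cohesive at ≥ 90 % similarity stay together" (merges exactly
at the cutoff remain merged). Representative picking draws a seeded
count in [2, 5] per cluster (all members if fewer), reproducible under
the seed.

## Sensory free-sorting analysis

A sheet (one panelist's partition of the wines) becomes a binary
wines × wines matrix (1 = co-grouped, diagonal 1); sheets sum to the
co-occurrence matrix. The co-occurrence-to-distance conversion is the
linear `m − count` (m = number of panelists); no canonical conversion
exists, so the scaled `1 − count/m` is available as an option — both
give the same tree up to height units. Ward on this non-Euclidean
distance is accepted deliberately (it is the field's practice for
co-occurrence data); average linkage is available as a robustness flag.
Clusters are labelled A, B, C… in dendrogram order. Which clusters count
as "desirable" is panel metadata supplied by the user (the bundled
reference marks A and B desirable), never computed from the tree.
Free-text aroma descriptors are tallied per cluster by frequency only.

## ANOVA battery for H₂S

The model is the one-way group-means fit Y_ij = μ_i + ε_ij. The omnibus
F test (scipy) is guarded by:

* **Levene** on absolute deviations from group means (classical
  variant; `center="median"` gives Brown–Forsythe);
* **Kolmogorov–Smirnov** of standardized, externally studentized
  residuals against N(0, 1). Mean/SD are estimated from the residuals,
  so the nominal p is conservative (Lilliefors caveat) — exactness is
  not claimed;
* **runs test** of residual signs about the median: exact combinatorial
  distribution of the number of runs for n ≤ 20, normal approximation
  (μ = 1 + 2n₁n₂/n) beyond; two-sided p as the doubled smaller tail.
  The closed-form distribution is verified against brute-force
  enumeration of all sign arrangements in the tests.

Studentized residuals use leverage 1/n_group and the leave-one-out
error estimate s₍ᵢ₎; singleton groups are rejected. Post-hoc pairwise
comparisons and repeated-measures modelling of the three incubation
days are out of scope — the screening question stops at the omnibus
test.

## Fermentation classification and concordance

Residual sugar is glucose + fructose at the final measured day, averaged
over replicates. The dryness rule fails a wine strictly above 10 g/L;
exactly 10 g/L passes. The concordance summary counts strains per
phenotypic group, the capacity fraction, the preliminary-group ×
sensory-cluster cross-tab and the validation rate; *favorable* groups
are those whose capable strains fall predominantly (> 50 %) in desirable
sensory clusters, with zero-capacity groups never favorable. Community
richness types per sample: ≤ 2 distinct strains → type 1, 3–4 → type 2,
≥ 5 → type 3 (counts between the published exemplars default to the
rich type; boundaries configurable).

The package bundles the reference survey tables it validates against
(14 samples / 190 isolates / 20 strains). The strain × region incidence
is only partially published; the loader completes the unlisted strains
deterministically to two regions consistent with every published
constraint and says so in its docstring — region-sharing conclusions
beyond the published facts should not be read off that completion.

## Synthetic data

The generators emulate the survey's design, with defaults fixed at the
study's scale:

* **Isolate panels** (n = 190): four prototype codes matching the four
  observed group characters, mixed 0.12/0.35/0.40/0.13 (the
  killer-sensitive marginal is ~12 %); each digit independently moves
  to an *adjacent* legal value with probability 0.03 (default) —
  ordinal scales err by one step, not by uniform resampling. Prototypes
  are pairwise ≥ 2.2 apart in Euclidean distance, so one grading slip
  never moves a code closer to a foreign prototype. Provenance is drawn
  from the bundled sample table weighted by its isolate counts.
* **Sorting panels**: 10 panelists, 13 wines, 4 consensus groups;
  each panelist copies the consensus and reassigns each wine with
  probability 1 − agreement (default agreement 0.9) to a uniformly
  random other group.
* **Fermentations**: exponential depletion from the must's initial
  119.5 g/L glucose + 120.1 g/L fructose over 14 days with truncated
  Gaussian noise (sd 1 g/L); 13 fast strains (0.5/day) finish dry,
  7 slow strains (0.05/day) stall above threshold. Exponential decay is
  the simplest monotone depletion consistent with daily monitoring; no
  lag or Monod phase is modelled.

What passing the recovery tests shows — and does not. The generators
plant exactly the structure the pipeline assumes: well-separated
prototypes, independent digit noise, panelist errors independent across
wines, monotone sugar curves. Real panels have correlated assay errors,
intermediate phenotypes, panelists with idiosyncratic criteria, and
sluggish-but-finishing fermentations; recovery rates here are an upper
bound on field performance, not an estimate of it.

Problem sizes used by the test suite and the acceptance script — 200
random instances (n ≤ 10 and n ≤ 12) for the linkage oracles, 100 seeds
for each recovery experiment, 2000 null replicates for the F-test
calibration — are chosen so the whole validation runs in about a minute
while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* The coding scheme is tied to this assay battery; adding an assay
  means a new digit and a revised desirability penalty.
* The largest-gap rule is a formalization of a visual judgment; on
  small trees with uneven group separations it legitimately prefers
  fewer groups, so reports always include the full gap profile.
* Ward on co-occurrence distances has no variance interpretation; it is
  retained for fidelity to sensory practice.
* No MIC interpolation between SO₂ doses, no plate-image processing,
  no kinetic model of fermentation, no MANOVA (whose assumptions the
  0–3 ordinal H₂S data cannot meet), and no DISTATIS/MDS embedding of
  the sorting data.
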