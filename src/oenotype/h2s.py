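"""One-way ANOVA battery for H₂S production with assumption diagnostics.

The screening records a 0–3 H₂S colour score per isolate at incubation
days 2, 5 and 8 (time levels 1, 2, 3). Mean score per origin or species
is modelled as ``Y_ij = μ_i + ε_ij`` and the omnibus hypothesis
``H0: μ_1 = … = μ_k`` is tested with the classical F statistic, guarded
by the usual battery: Levene's test for homoscedasticity, a
Kolmogorov–Smirnov check of normality on (externally) studentized
residuals, and a runs test of residual independence. The runs test uses
the exact combinatorial distribution of the number of sign runs for
small samples and the normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyDataset, OenotypeError

EXACT_RUNS_MAX_N = 20


def _group_arrays(df: pd.DataFrame, factor: str, value: str) -> list:
    if df.empty:
        raise EmptyDataset("no observations")
    groups = [np.asarray(sub[value], dtype=float) for _, sub in df.groupby(factor)]
    if len(groups) < 2:
        raise OenotypeError("need at least 2 factor levels")
    if any(len(g) < 2 for g in groups):
        raise OenotypeError("need at least 2 observations per level")
    return groups


@dataclass
class AnovaReport:
    """Omnibus F test plus assumption-check verdicts at a given alpha."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    levene_stat: float
    levene_p: float
    ks_stat: float
    ks_p: float
    runs_stat: int
    runs_p: float
    alpha: float = 0.05

    @property
    def assumptions(self) -> dict:
        """True = the assumption is *not* rejected at ``alpha``."""
        return {
            "homoscedastic": self.levene_p > self.alpha,
            "normal_errors": self.ks_p > self.alpha,
            "independent_errors": self.runs_p > self.alpha,
        }

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "f_statistic", "df_between", "df_within", "p_value",
            "levene_stat", "levene_p", "ks_stat", "ks_p",
            "runs_stat", "runs_p", "alpha")}
        out["assumptions"] = self.assumptions
        out["significant"] = self.significant
        return out


def one_way_anova(df: pd.DataFrame, factor: str, value: str = "response",
                  alpha: float = 0.05, levene_center: str = "mean") -> AnovaReport:
    """Classical one-way ANOVA of ``value`` by ``factor`` with diagnostics."""
    groups = _group_arrays(df, factor, value)
    f_stat, p = stats.f_oneway(*groups)
    lev_stat, lev_p = levene_test(df, factor, value, center=levene_center)
    resid = studentized_residuals(df, factor, value)
    try:
        ks_stat, ks_p = ks_normality(resid)
    except OenotypeError:
        ks_stat, ks_p = float("nan"), float("nan")
    runs_stat, runs_p = runs_test(raw_residuals(df, factor, value))
    n = sum(len(g) for g in groups)
    return AnovaReport(
        f_statistic=float(f_stat), df_between=len(groups) - 1, df_within=n - len(groups),
        p_value=float(p), levene_stat=float(lev_stat), levene_p=float(lev_p),
        ks_stat=float(ks_stat), ks_p=float(ks_p),
        runs_stat=int(runs_stat), runs_p=float(runs_p), alpha=alpha,
    )


def levene_test(df: pd.DataFrame, factor: str, value: str = "response",
                center: str = "mean"):
    """Levene's homoscedasticity test (mean-centered classical variant;
    ``center="median"`` gives Brown–Forsythe)."""
    groups = _group_arrays(df, factor, value)
    stat, p = stats.levene(*groups, center=center)
    return float(stat), float(p)


def raw_residuals(df: pd.DataFrame, factor: str, value: str = "response") -> np.ndarray:
    """Residuals from the group-means fit, in input row order."""
    y = np.asarray(df[value], dtype=float)
    means = df.groupby(factor)[value].transform("mean").to_numpy(dtype=float)
    return y - means


def studentized_residuals(df: pd.DataFrame, factor: str,
                          value: str = "response") -> np.ndarray:
    """Externally studentized residuals of the one-way group-means model.

    Leverage of an observation in group *g* is ``1/n_g``; each residual is
    scaled by the error estimate from the fit that leaves it out,
    ``t_i = e_i / (s_(i) * sqrt(1 - h_i))``.
    """
    groups = _group_arrays(df, factor, value)
    sizes = df.groupby(factor)[value].transform("count").to_numpy(dtype=float)
    if np.any(sizes < 2):
        raise OenotypeError("studentized residuals undefined for singleton groups")
    e = raw_residuals(df, factor, value)
    n = len(e)
    k = len(groups)
    dof = n - k
    if dof <= 1:
        raise OenotypeError("not enough residual degrees of freedom")
    sse = float(np.sum(e**2))
    if sse <= 0:
        raise OenotypeError("zero residual variance")
    h = 1.0 / sizes
    s2_loo = (sse - e**2 / (1.0 - h)) / (dof - 1)
    s2_loo = np.maximum(s2_loo, np.finfo(float).tiny)
    return e / np.sqrt(s2_loo * (1.0 - h))


def ks_normality(residuals) -> tuple:
    """One-sample KS test of standardized residuals against N(0, 1).

    Mean and SD are estimated from the residuals themselves, so the
    nominal KS null distribution is conservative (Lilliefors caveat).
    """
    r = np.asarray(residuals, dtype=float)
    if len(r) < 3:
        raise OenotypeError("need at least 3 residuals")
    sd = r.std(ddof=1)
    if sd == 0:
        raise OenotypeError("zero-variance residuals")
    z = (r - r.mean()) / sd
    stat, p = stats.kstest(z, "norm")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# runs test


def count_runs(signs: np.ndarray) -> int:
    """Number of maximal blocks of equal sign in a ±1 sequence."""
    return int(1 + np.sum(signs[1:] != signs[:-1]))


def runs_distribution(n_pos: int, n_neg: int) -> dict:
    """Exact null distribution of the number of runs.

    For a random arrangement of ``n_pos`` pluses and ``n_neg`` minuses:
    ``P(R=2k) = 2 C(n1-1,k-1) C(n2-1,k-1) / C(n,n1)`` and
    ``P(R=2k+1) = [C(n1-1,k) C(n2-1,k-1) + C(n1-1,k-1) C(n2-1,k)] / C(n,n1)``.
    """
    n = n_pos + n_neg
    total = comb(n, n_pos)
    dist = {}
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            num = 2 * comb(n_pos - 1, k - 1) * comb(n_neg - 1, k - 1)
        else:
            k = (r - 1) // 2
            num = (comb(n_pos - 1, k) * comb(n_neg - 1, k - 1)
                   + comb(n_pos - 1, k - 1) * comb(n_neg - 1, k))
        if num:
            dist[r] = num / total
    return dist


def _two_sided_from_distribution(dist: dict, observed: int) -> float:
    lo = sum(p for r, p in dist.items() if r <= observed)
    hi = sum(p for r, p in dist.items() if r >= observed)
    return min(1.0, 2.0 * min(lo, hi))


def runs_test(residuals, exact_max_n: int = EXACT_RUNS_MAX_N) -> tuple:
    """Two-sided runs test of randomness on residual signs about the median.

    Returns ``(n_runs, p)``. Exact combinatorial p for ``n <= exact_max_n``,
    normal approximation (mean ``1 + 2 n1 n2 / n``) otherwise. Values equal
    to the median are dropped.
    """
    r = np.asarray(residuals, dtype=float)
    med = np.median(r)
    signs = np.sign(r - med).astype(int)
    signs = signs[signs != 0]
    n = len(signs)
    if n < 2:
        raise OenotypeError("runs test needs >= 2 non-tied observations")
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise OenotypeError("runs test undefined when all signs agree")
    obs = count_runs(signs)
    if n <= exact_max_n:
        p = _two_sided_from_distribution(runs_distribution(n_pos, n_neg), obs)
    else:
        mu = 1.0 + 2.0 * n_pos * n_neg / n
        var = (2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n)) / (n**2 * (n - 1))
        z = (obs - mu) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return obs, float(p)


def expected_runs(n_pos: int, n_neg: int) -> float:
    """Closed-form expectation ``1 + 2 n1 n2 / n`` of the number of runs."""
    return 1.0 + 2.0 * n_pos * n_neg / (n_pos + n_neg)
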