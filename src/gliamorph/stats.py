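"""Normality-gated two-group statistics and densitometry normalization.

The comparison protocol mirrors the study design it reconstructs: each
per-animal dataset is screened with the Kolmogorov-Smirnov normality test
using the Dallal-Wilkinson approximation for the Lilliefors correction
(mean and variance estimated from the sample); groups that both pass are
compared with a two-tailed unpaired Student's t-test (pooled variance),
otherwise with a two-tailed Mann-Whitney U test.  Western-blot band
intensities are expressed relative to the beta-actin loading control and
normalized so the wild-type mean of each blot is exactly 100%.

No multiple-testing correction is applied anywhere: the protocol tests each
morphological parameter and region separately, so across ~8 parameters x 2
regions the family-wise error rate at alpha = 0.05 is roughly
1 - 0.95^16 ~ 0.56 under the global null.  Reports carry this caveat.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "LillieforsResult",
    "TTestResult",
    "MannWhitneyResult",
    "ComparisonResult",
    "lilliefors_ks",
    "student_t_two_sample",
    "welch_t_two_sample",
    "mann_whitney_u",
    "summary_ttest",
    "compare_parameter",
    "densitometry_percent",
    "significance_stars",
    "EXACT_MW_MAX_N",
]

#: Largest pooled sample size for which the Mann-Whitney p is computed by
#: full enumeration of group assignments (C(12, 6) = 924 arrangements).
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class GroupSample:
    """Per-animal values of one parameter for one genotype (animal = unit)."""

    genotype: str
    parameter: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", tuple(float(v) for v in arr))

    @property
    def n(self) -> int:
        return len(self.values)


class LillieforsResult(NamedTuple):
    statistic: float      # KS distance against N(mean, sd) estimated from data
    pvalue: float
    n: int
    zero_variance: bool = False


class TTestResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


class MannWhitneyResult(NamedTuple):
    statistic: float      # U of the first sample
    pvalue: float
    method: str           # "exact" (enumeration) or "asymptotic"
    tied: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group test outcome under the normality-gated protocol."""

    parameter: str
    test_used: str                 # "student_t" or "mann_whitney"
    statistic: float
    p_two_tailed: float
    normal_wt: bool
    normal_mut: bool
    significant: bool
    alpha: float
    n_wt: int
    n_mut: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p_two_tailed)


def significance_stars(p: float) -> str:
    """'*' for p < 0.05, '**' for p < 0.01, 'NS' otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


# ---------------------------------------------------------------------------
# normality


def lilliefors_ks(values: Sequence[float]) -> LillieforsResult:
    """Kolmogorov-Smirnov normality test with the Lilliefors correction,
    p-value from the Dallal-Wilkinson approximation.

    The KS distance is computed against a normal distribution whose mean and
    standard deviation are estimated from the sample; the Dallal-Wilkinson
    formula approximates the corrected p for 4 <= n <= 100 (samples beyond
    100 are rescaled as D' = D * (n/100)^0.49).  The approximation was fitted
    for the p <= 0.10 region; larger values are increasingly approximate and
    are clipped to [0, 1], which is immaterial for gating at conventional
    alpha levels.  A zero-variance sample is reported as non-normal (p = 0)
    and flagged.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4 for the normality test, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        return LillieforsResult(1.0, 0.0, n, zero_variance=True)
    d = float(sps.kstest(x, "norm", args=(x.mean(), sd)).statistic)
    d_adj, n_adj = (d * (n / 100.0) ** 0.49, 100) if n > 100 else (d, n)
    logp = (-7.01256 * d_adj**2 * (n_adj + 2.78019)
            + 2.99587 * d_adj * math.sqrt(n_adj + 2.78019)
            - 0.122119 + 0.974598 / math.sqrt(n_adj) + 1.67997 / n_adj)
    p = min(max(math.exp(logp), 0.0), 1.0)
    return LillieforsResult(d, p, n)


# ---------------------------------------------------------------------------
# two-sample tests


def student_t_two_sample(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-tailed unpaired Student's t-test with pooled variance,
    df = n_x + n_y - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    df = x.size + y.size - 2
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return TTestResult(0.0, df, 1.0)
        raise ValueError("zero pooled variance with unequal means")
    res = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def welch_t_two_sample(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance t-test (available behind a flag; the
    gated protocol always uses the pooled-variance test)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test.

    For pooled sizes up to :data:`EXACT_MW_MAX_N` the p-value is exact: every
    assignment of the pooled values to the two groups is enumerated (ties are
    thereby handled exactly) and the two-tailed p is the fraction of
    assignments whose U deviates from its null mean n_x*n_y/2 at least as far
    as observed.  Larger samples use the normal approximation with tie
    correction and continuity correction.  All-tied data yield p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("need at least 1 observation per group")
    tied = bool(np.unique(np.concatenate([x, y])).size < x.size + y.size)
    u_obs = _u_statistic(x, y)
    n_x, n_y = x.size, y.size
    if n_x + n_y <= EXACT_MW_MAX_N:
        pooled = np.concatenate([x, y])
        centre = n_x * n_y / 2.0
        dev = abs(u_obs - centre)
        idx = range(n_x + n_y)
        hits = total = 0
        for comb in combinations(idx, n_x):
            sel = np.zeros(n_x + n_y, dtype=bool)
            sel[list(comb)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - centre) >= dev - 1e-12:
                hits += 1
        return MannWhitneyResult(u_obs, hits / total, "exact", tied)
    if np.ptp(np.concatenate([x, y])) == 0:
        return MannWhitneyResult(u_obs, 1.0, "asymptotic", True)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u_obs, float(res.pvalue), "asymptotic", tied)


def summary_ttest(mean1: float, sem1: float, n1: int,
                  mean2: float, sem2: float, n2: int) -> TTestResult:
    """Two-tailed t-test reconstructed from printed mean +/- SEM summaries.

    t = (mean1 - mean2) / sqrt(sem1^2 + sem2^2) on n1 + n2 - 2 degrees of
    freedom.  For balanced groups (n1 == n2) this is algebraically identical
    to the pooled-variance two-sample t-test on the underlying samples.
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    t = (mean1 - mean2) / math.hypot(sem1, sem2)
    df = n1 + n2 - 2
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t, df, p)


# ---------------------------------------------------------------------------
# gated comparison


def compare_parameter(wt: GroupSample, mut: GroupSample, alpha: float = 0.05,
                      normality_alpha: float = 0.05) -> ComparisonResult:
    """Normality-gated two-group comparison of one parameter.

    Both groups are screened with :func:`lilliefors_ks`; if both pass at
    ``normality_alpha`` the groups are compared with the pooled Student's
    t-test, otherwise with the Mann-Whitney U test.  Groups too small to
    screen (n < 4) fall back to the t-test with a warning.
    """
    if wt.parameter != mut.parameter:
        raise ValueError(
            f"parameter mismatch: {wt.parameter!r} vs {mut.parameter!r}")
    if wt.n < 4 or mut.n < 4:
        warnings.warn(
            f"{wt.parameter}: n < 4 in at least one group; normality is "
            "untestable, falling back to Student's t-test", stacklevel=2)
        normal_wt = normal_mut = True
    else:
        normal_wt = lilliefors_ks(wt.values).pvalue >= normality_alpha
        normal_mut = lilliefors_ks(mut.values).pvalue >= normality_alpha
    if normal_wt and normal_mut:
        t = student_t_two_sample(wt.values, mut.values)
        stat, p, used = t.statistic, t.pvalue, "student_t"
    else:
        mw = mann_whitney_u(wt.values, mut.values)
        stat, p, used = mw.statistic, mw.pvalue, "mann_whitney"
    return ComparisonResult(
        parameter=wt.parameter, test_used=used, statistic=stat,
        p_two_tailed=p, normal_wt=normal_wt, normal_mut=normal_mut,
        significant=bool(p < alpha), alpha=alpha, n_wt=wt.n, n_mut=mut.n)


# ---------------------------------------------------------------------------
# densitometry


_DENSITOMETRY_COLUMNS = {"blot_id", "lane", "genotype",
                         "target_intensity", "actin_intensity"}


def densitometry_percent(table: pd.DataFrame, wt_label: str = "WT",
                         alpha: float = 0.05,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize band intensities to the loading control and the WT blot mean.

    Each lane's target intensity is divided by its beta-actin intensity; each
    ratio is then expressed as a percentage of the mean WT ratio of the same
    blot (and target/region, when those columns are present), making the WT
    group mean exactly 100% by construction.  Genotypes are compared per
    target/region with the two-tailed pooled t-test on the percentages.

    Returns ``(normalized_table, comparison_table)``; the comparison table
    has one row per target/region with mean +/- SEM per genotype, t, p and
    significance stars.
    """
    missing = _DENSITOMETRY_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"densitometry table lacks columns: {sorted(missing)}")
    table = table.copy()
    bad = table[~(table["actin_intensity"] > 0)]
    if len(bad):
        raise ValueError(
            "missing or non-positive actin intensity in lane(s): "
            + ", ".join(map(str, bad["lane"].tolist())))
    group_cols = ["blot_id"] + [c for c in ("target", "region") if c in table.columns]
    table["ratio"] = table["target_intensity"] / table["actin_intensity"]

    wt_means = (table.loc[table["genotype"] == wt_label]
                .groupby(group_cols, sort=False)["ratio"].mean())
    if len(group_cols) == 1:
        denom = wt_means.reindex(table[group_cols[0]]).to_numpy()
    else:
        denom = wt_means.reindex(pd.MultiIndex.from_frame(table[group_cols])).to_numpy()
    if np.isnan(denom).any():
        missing_keys = sorted(set(map(tuple, table.loc[np.isnan(denom), group_cols]
                                      .itertuples(index=False))))
        raise ValueError(f"blot group(s) without a {wt_label} lane: {missing_keys}")
    normalized = table.copy()
    normalized["percent_of_wt"] = 100.0 * table["ratio"].to_numpy() / denom

    comp_cols = [c for c in ("target", "region") if c in table.columns]
    rows = []
    for key, grp in (normalized.groupby(comp_cols, sort=False) if comp_cols
                     else [((), normalized)]):
        key = key if isinstance(key, tuple) else (key,)
        wt_vals = grp.loc[grp["genotype"] == wt_label, "percent_of_wt"].to_numpy()
        mut_vals = grp.loc[grp["genotype"] != wt_label, "percent_of_wt"].to_numpy()
        row = dict(zip(comp_cols, key))
        row.update(
            wt_mean=wt_vals.mean(), wt_sem=sps.sem(wt_vals) if wt_vals.size > 1 else np.nan,
            n_wt=wt_vals.size, n_mut=mut_vals.size)
        if mut_vals.size >= 2 and wt_vals.size >= 2:
            res = student_t_two_sample(wt_vals, mut_vals)
            row.update(mut_mean=mut_vals.mean(), mut_sem=float(sps.sem(mut_vals)),
                       t=res.statistic, p_two_tailed=res.pvalue,
                       significance=significance_stars(res.pvalue))
        else:
            row.update(mut_mean=mut_vals.mean() if mut_vals.size else np.nan,
                       mut_sem=np.nan, t=np.nan, p_two_tailed=np.nan,
                       significance="")
        rows.append(row)
    return normalized, pd.DataFrame(rows)
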