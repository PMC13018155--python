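"""Inferential statistics for depth-zone × lifestyle niche partitioning.

Three procedures cover the study design:

* a balanced fixed-effects **two-way ANOVA** with interaction, testing
  whether a response (e.g. a taxon's relative abundance) differs by
  depth zone, by microbial lifestyle (free-living vs particle-attached
  fractions), and by their interaction;
* the **Holm–Šidák** step-down adjustment for the post-hoc multiple
  comparisons that follow a significant ANOVA;
* the two-sided **Wilcoxon rank-sum** (Mann–Whitney) test for pairwise
  group comparisons, with the exact permutation null enumerated in full
  at small sample sizes and a tie- and continuity-corrected normal
  approximation beyond.

The ANOVA requires a balanced design (equal replication per cell): with
balance the classical sums-of-squares decomposition is unambiguous,
whereas unbalanced layouts would silently depend on a SS-type choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import log
from .exceptions import DesignError, InputError


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Fixed-effects decomposition: one row per term (A, B, A:B, error)."""

    table: pd.DataFrame
    warnings: tuple = ()

    def __getitem__(self, term):
        return self.table.loc[term]


def two_way_anova(
    data: pd.DataFrame,
    response: str = "response",
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
) -> AnovaTable:
    """Balanced two-way fixed-effects ANOVA with interaction.

    ``data`` is a long-format frame. Every (A, B) cell must hold the same
    number of replicates; with a single replicate per cell the
    interaction cannot be separated from error and is omitted with a
    warning. A constant response yields zero sums of squares and missing
    F/p values (flagged), not a crash.
    """
    for col in (response, factor_a, factor_b):
        if col not in data.columns:
            raise InputError(f"data lacks column {col!r}")
    y = data[response].to_numpy(dtype=float)
    a_codes, a_levels = pd.factorize(data[factor_a], sort=True)
    b_codes, b_levels = pd.factorize(data[factor_b], sort=True)
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise DesignError("both factors need at least 2 levels")

    cell_n = np.zeros((a, b), dtype=int)
    np.add.at(cell_n, (a_codes, b_codes), 1)
    if cell_n.min() == 0 or cell_n.max() != cell_n.min():
        raise DesignError(
            "unbalanced design: replicates per cell =\n"
            + str(pd.DataFrame(cell_n, index=a_levels, columns=b_levels))
        )
    r = int(cell_n[0, 0])
    n = y.size

    cell_sum = np.zeros((a, b))
    np.add.at(cell_sum, (a_codes, b_codes), y)
    cell_mean = cell_sum / r
    grand = y.mean()
    mean_a = cell_mean.mean(axis=1)
    mean_b = cell_mean.mean(axis=0)

    ss_a = b * r * np.sum((mean_a - grand) ** 2)
    ss_b = a * r * np.sum((mean_b - grand) ** 2)
    ss_ab = r * np.sum(
        (cell_mean - mean_a[:, None] - mean_b[None, :] + grand) ** 2
    )
    ss_total = np.sum((y - grand) ** 2)
    ss_e = ss_total - ss_a - ss_b - ss_ab

    warnings = []
    terms = []
    if r >= 2:
        df = {factor_a: a - 1, factor_b: b - 1, f"{factor_a}:{factor_b}": (a - 1) * (b - 1)}
        ss = {factor_a: ss_a, factor_b: ss_b, f"{factor_a}:{factor_b}": ss_ab}
        df_e = a * b * (r - 1)
    else:
        # single replicate: interaction is the error stratum
        warnings.append("interaction_omitted_single_replicate")
        log.warning("one observation per cell: interaction term omitted")
        df = {factor_a: a - 1, factor_b: b - 1}
        ss = {factor_a: ss_a, factor_b: ss_b}
        ss_e = ss_ab + ss_e
        df_e = (a - 1) * (b - 1)

    ms_e = ss_e / df_e if df_e > 0 else np.nan
    degenerate = not np.isfinite(ms_e) or ms_e <= 0
    if degenerate:
        warnings.append("zero_error_variance")
        log.warning("zero/undefined error variance; F and p reported as missing")
    for term, ss_t in ss.items():
        ms_t = ss_t / df[term]
        f_stat = ms_t / ms_e if not degenerate else np.nan
        p = float(sps.f.sf(f_stat, df[term], df_e)) if not degenerate else np.nan
        terms.append((term, ss_t, df[term], ms_t, f_stat, p))
    terms.append(("error", ss_e, df_e, ms_e, np.nan, np.nan))

    table = pd.DataFrame(
        terms, columns=["term", "ss", "df", "ms", "F", "p"]
    ).set_index("term")
    table.attrs["ss_total"] = float(ss_total)
    table.attrs["n"] = int(n)
    return AnovaTable(table, tuple(warnings))


# ---------------------------------------------------------------------------
# Holm–Šidák
# ---------------------------------------------------------------------------

def holm_sidak(p_values) -> np.ndarray:
    """Holm–Šidák step-down adjusted p-values, in the original order.

    Sorted ascending, the i-th smallest p (1-based) becomes
    ``1 − (1 − p)^(m − i + 1)``, then a running maximum enforces
    monotonicity and values are capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise InputError("p values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    """Rank-sum test outcome: W is the midrank sum of the first group."""

    statistic: float
    p_two_sided: float
    method: str  # "exact" | "normal_approximation"
    tie_correction_applied: bool
    n_x: int
    n_y: int


def wilcoxon_rank_sum(x, y, exact_max_n: int = 20) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    The statistic is the sum of midranks of ``x`` in the pooled sample.
    When ``n + m ≤ exact_max_n`` the p-value is exact: all C(n+m, n)
    equally-likely assignments of the pooled (mid)ranks to the first
    group are enumerated, the smaller tail probability is doubled and
    capped at 1. Ties are handled naturally by enumeration over the
    midranks. Beyond the cutoff a normal approximation with tie
    correction of the variance and a 0.5 continuity correction is used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n].sum())
    nn = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if nn <= exact_max_n:
        total = comb(nn, n)
        le = ge = 0
        eps = 1e-9
        for idx in combinations(range(nn), n):
            s = ranks[list(idx)].sum()
            if s <= w + eps:
                le += 1
            if s >= w - eps:
                ge += 1
        p_one = min(le, ge) / total
        p = min(1.0, 2.0 * p_one)
        return RankSumResult(w, p, "exact", has_ties, n, m)

    mean_w = n * (nn + 1) / 2.0
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_w = n * m / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
    if var_w <= 0:
        # all observations identical: no evidence either way
        return RankSumResult(w, 1.0, "normal_approximation", has_ties, n, m)
    diff = w - mean_w
    z = (abs(diff) - 0.5) / np.sqrt(var_w)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    return RankSumResult(w, p, "normal_approximation", has_ties, n, m)


def pairwise_holm_sidak(
    data: pd.DataFrame,
    response: str = "response",
    factor: str = "factor_a",
) -> pd.DataFrame:
    """Post-hoc pairwise comparisons of one factor's levels.

    Welch two-sample t-tests between every pair of levels, with the raw
    p-values adjusted by :func:`holm_sidak`. Complements
    :func:`two_way_anova` as the multiple-comparison follow-up.
    """
    levels = sorted(data[factor].unique())
    if len(levels) < 2:
        raise DesignError(f"factor {factor!r} needs at least 2 levels")
    rows = []
    for la, lb in combinations(levels, 2):
        ya = data.loc[data[factor] == la, response].to_numpy(dtype=float)
        yb = data.loc[data[factor] == lb, response].to_numpy(dtype=float)
        t, p = sps.ttest_ind(ya, yb, equal_var=False)
        rows.append((la, lb, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["level_1", "level_2", "t", "p_raw"])
    out["p_adjusted"] = holm_sidak(out["p_raw"])
    return out
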