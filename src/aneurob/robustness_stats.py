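"""Coarse-vs-fine agreement and rupture-group statistics.

The agreement stage compares each indicator between two mesh resolutions:
Pearson correlation (on all paired cases), the mean relative difference
d = mean((coarse − fine)/fine) and a logarithmic Bland–Altman analysis
(log2 ratio against log2 geometric mean, normalized by the maximum fine
value). Pairs where either resolution yields exactly 0 are excluded from d
and the Bland–Altman points — but never from the correlation — to avoid
division by zero.

The group stage compares ruptured against unruptured cases per indicator
with a normality-gated test: Shapiro–Wilk on each group at α; if neither
group rejects normality, a two-tailed two-sample t-test, otherwise a
two-sided Mann–Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AgreementReport:
    """Per-indicator coarse-vs-fine agreement."""

    indicator: str
    pearson_r: float
    mean_relative_difference: float  # fraction
    ba_x: np.ndarray  # log2(sqrt(c·f)/normalizer)
    ba_y: np.ndarray  # log2(c/f)
    loa_low: float  # limits of agreement, log2 units
    loa_high: float
    excluded: list[int] = field(default_factory=list)
    n_pairs: int = 0


@dataclass
class GroupTestReport:
    indicator: str
    mean_ruptured: float
    sd_ruptured: float
    mean_unruptured: float
    sd_unruptured: float
    test: str  # "t" | "mann_whitney"
    p_value: float
    shapiro_p_ruptured: float
    shapiro_p_unruptured: float


def mean_relative_difference(coarse: np.ndarray, fine: np.ndarray) -> float:
    """mean((c_i − f_i)/f_i) over the pairs; fine values must be nonzero."""
    coarse = np.asarray(coarse, dtype=float)
    fine = np.asarray(fine, dtype=float)
    if coarse.shape != fine.shape:
        raise ValueError("paired arrays must have the same length")
    if coarse.size == 0:
        raise ValueError("no pairs left after exclusion")
    if np.any(fine == 0):
        raise ValueError("zero fine values; apply exclude_zero_pairs first")
    return float(np.mean((coarse - fine) / fine))


def exclude_zero_pairs(
    coarse: np.ndarray, fine: np.ndarray, case_ids: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Drop pairs where either value is exactly 0.

    Returns (coarse_kept, fine_kept, excluded_case_ids). Applied to d and
    the Bland–Altman points only; correlations keep all pairs.
    """
    coarse = np.asarray(coarse, dtype=float)
    fine = np.asarray(fine, dtype=float)
    if case_ids is None:
        case_ids = np.arange(coarse.size)
    bad = (coarse == 0) | (fine == 0)
    excluded = [int(i) for i in np.asarray(case_ids)[bad]]
    return coarse[~bad], fine[~bad], excluded


def bland_altman_log(
    coarse: np.ndarray, fine: np.ndarray, normalizer: float | None = None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Logarithmic Bland–Altman points and limits of agreement.

    y = log2(c/f); x = log2(√(c·f)/normalizer) with the normalizer
    defaulting to max(fine) — so x ≤ 0 roughly orders cases by magnitude.
    Limits of agreement are mean(y) ± 1.96 sd(y) in log2 units. The inputs
    must already have zero pairs excluded.
    """
    coarse = np.asarray(coarse, dtype=float)
    fine = np.asarray(fine, dtype=float)
    if np.any(coarse <= 0) or np.any(fine <= 0):
        raise ValueError("non-positive values retained; exclusion missed them")
    if normalizer is None:
        normalizer = float(fine.max())
    y = np.log2(coarse / fine)
    x = np.log2(np.sqrt(coarse * fine) / normalizer)
    sd = float(np.std(y, ddof=1)) if y.size > 1 else 0.0
    m = float(np.mean(y))
    return x, y, m - 1.96 * sd, m + 1.96 * sd


def agreement_report(
    coarse: np.ndarray,
    fine: np.ndarray,
    indicator: str = "",
    case_ids: np.ndarray | None = None,
) -> AgreementReport:
    """Full agreement analysis for one indicator."""
    coarse = np.asarray(coarse, dtype=float)
    fine = np.asarray(fine, dtype=float)
    r = float(stats.pearsonr(coarse, fine).statistic)
    c_k, f_k, excluded = exclude_zero_pairs(coarse, fine, case_ids)
    d = mean_relative_difference(c_k, f_k)
    x, y, lo, hi = bland_altman_log(c_k, f_k)
    return AgreementReport(indicator, r, d, x, y, lo, hi, excluded, c_k.size)


def gated_group_test(
    values: np.ndarray, ruptured: np.ndarray, alpha: float = 0.05,
    indicator: str = "", equal_var: bool = True,
) -> GroupTestReport:
    """Rupture-group comparison with Shapiro–Wilk normality gating.

    If neither group rejects normality at ``alpha``: two-tailed two-sample
    Student's t-test (Welch via ``equal_var=False``); otherwise a two-sided
    Mann–Whitney U test. Groups must have at least 3 cases each.
    """
    values = np.asarray(values, dtype=float)
    ruptured = np.asarray(ruptured, dtype=bool)
    a, b = values[ruptured], values[~ruptured]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 cases")
    sw_a = float(stats.shapiro(a).pvalue)
    sw_b = float(stats.shapiro(b).pvalue)
    if sw_a > alpha and sw_b > alpha:
        test = "t"
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    else:
        test = "mann_whitney"
        method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method=method).pvalue)
    return GroupTestReport(
        indicator, float(a.mean()), float(a.std(ddof=1)),
        float(b.mean()), float(b.std(ddof=1)), test, p, sw_a, sw_b)


def indicator_correlation_matrix(
    table: pd.DataFrame, indicators: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r across cases, with two-sided p-value flags.

    Returns (r, flags): ``flags`` holds '' (n.s.), '*' for p < 0.05 and
    '**' for p < 0.001; constant columns give NaN entries.
    """
    if indicators is None:
        indicators = [c for c in table.columns
                      if c not in ("case_id", "resolution", "ruptured")]
    if len(table) < 3:
        raise ValueError("need at least 3 cases")
    k = len(indicators)
    r = np.full((k, k), np.nan)
    flags = np.full((k, k), "", dtype=object)
    for i, a in enumerate(indicators):
        for j, b in enumerate(indicators):
            if j > i:
                continue
            x = table[a].to_numpy(dtype=float)
            y = table[b].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            flag = "**" if res.pvalue < 0.001 else "*" if res.pvalue < 0.05 else ""
            flags[i, j] = flags[j, i] = flag
    return (pd.DataFrame(r, index=indicators, columns=indicators),
            pd.DataFrame(flags, index=indicators, columns=indicators))


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample SD over mean (n − 1 denominator); mean must be nonzero."""
    values = np.asarray(values, dtype=float)
    m = values.mean()
    if m == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(values.std(ddof=1) / m)
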