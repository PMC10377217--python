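"""Nonparametric group profiling of the stratified cohort.

Implements the comparison machinery applied to the three R-based
subgroups: per-variable median and interquartile range, a tie-corrected
Kruskal-Wallis omnibus test, pairwise two-sided Mann-Whitney U tests
(exact by enumeration for small untied samples, otherwise a
tie-corrected normal approximation with continuity correction) with
Bonferroni adjustment over the three pairwise comparisons, Cohen's d as
the magnitude of the standardized mean difference, and each group's mean
"multiplication factor" (group mean divided by the grand mean).

The rank tests are written out explicitly — with `scipy` supplying only
the chi-square and normal distributions — so the exact-enumeration path
and the tie/continuity corrections are under this module's control and
can be cross-checked against library implementations in the test suite.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from lbpanomaly.errors import ValidationError

__all__ = [
    "kruskal_wallis",
    "mann_whitney_u",
    "bonferroni",
    "cohens_d",
    "median_iqr",
    "multiplication_factor",
    "build_comparison_table",
    "TABLE_VARIABLES",
]

# Profiling variable set: (label, source column, binary?).  Gender is
# compared on its female=1 coding, diagnoses on their 0/1 flags.
TABLE_VARIABLES: tuple[tuple[str, str, bool], ...] = (
    ("age", "age", False),
    ("body_mass", "body_mass", False),
    ("height", "height", False),
    ("gender", "sex_code", True),
    ("mental_illness_dx", "mental_illness_dx", True),
    ("lumbar_pathology_dx", "lumbar_pathology_dx", True),
    ("lbp_events_6wk", "lbp_events_6wk", False),
    ("dass_stress", "dass_stress", False),
    ("dass_anxiety", "dass_anxiety", False),
    ("dass_depression", "dass_depression", False),
    ("pcs_total", "pcs_total", False),
    ("odi_pct", "odi_pct", False),
)


def kruskal_wallis(values: Sequence[float],
                   group_labels: Sequence) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H test.

    Returns ``(H, df, p)`` with the chi-square approximation on k-1
    degrees of freedom.  A sample in which every value is tied gives
    H = 0, p = 1 by convention.
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if x.shape != labels.shape:
        raise ValidationError("values and labels must align")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    for g in uniq:
        if not np.any(labels == g):
            raise ValidationError(f"group {g} is empty")
    n = x.size
    ranks = rankdata(x)
    h = 12.0 / (n * (n + 1)) * sum(
        np.sum(ranks[labels == g]) ** 2 / np.sum(labels == g)
        for g in uniq) - 3.0 * (n + 1)
    _, counts = np.unique(x, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts)
    denom = 1.0 - tie_term / (n ** 3 - n)
    if denom <= 0.0:  # every value tied
        return 0.0, len(uniq) - 1, 1.0
    h /= denom
    h = max(h, 0.0)
    df = len(uniq) - 1
    return float(h), df, float(chi2.sf(h, df))


def _u_statistics(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    n1, n2 = a.size, b.size
    ranks = rankdata(np.concatenate([a, b]))
    u_a = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    return u_a, n1 * n2 - u_a


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of rank assignments.

    Counts arrangements whose ``min(U_a, U_b)`` is at most the observed
    one; since ``min <= u`` holds exactly when ``U_a`` falls in either
    tail, this is the two-sided tail probability.
    """
    n1, n2 = a.size, b.size
    total = n1 + n2
    count_le = 0
    for pos in combinations(range(total), n1):
        # untied data: ranks are 1..N, positions in sorted order
        u = sum(pos) + n1 - n1 * (n1 + 1) / 2.0  # ranks are pos+1
        u = min(u, n1 * n2 - u)
        if u <= u_obs:
            count_le += 1
    return count_le / comb(total, n1)


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   exact_threshold: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with ``U = min(U_a, U_b)``.  When both samples
    have at most ``exact_threshold`` observations and the pooled data are
    untied, the p-value comes from full enumeration of the
    ``C(n1+n2, n1)`` equally likely rank assignments; otherwise a normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    u_a, u_b = _u_statistics(a, b)
    u = min(u_a, u_b)

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if n1 <= exact_threshold and n2 <= exact_threshold and not has_ties:
        return u, _exact_p(a, b, u)

    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0.0:  # all values tied
        return u, 1.0
    mean_u = n1 * n2 / 2.0
    z = (abs(u - mean_u) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return u, float(min(1.0, 2.0 * norm.sf(z)))


def bonferroni(p_raw: float, m: int = 3) -> float:
    """Bonferroni adjustment: ``min(1, m * p)``."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValidationError(f"p={p_raw} outside [0, 1]")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return min(1.0, m * p_raw)


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Magnitude of Cohen's d with the (n-1)-weighted pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 values")
    s2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
          / (a.size + b.size - 2))
    if s2 <= 0.0:
        raise ValidationError("zero pooled SD: d is undefined")
    return float(abs(a.mean() - b.mean()) / np.sqrt(s2))


def median_iqr(values: Sequence[float]) -> tuple[float, float]:
    """Median and interquartile range via interpolated order statistics."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("empty sample")
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return float(q50), float(q75 - q25)


def multiplication_factor(group_values: Sequence[float],
                          all_values: Sequence[float]) -> float:
    """Group mean divided by the grand mean."""
    g = np.asarray(group_values, dtype=float)
    full = np.asarray(all_values, dtype=float)
    if g.size == 0 or full.size == 0:
        raise ValidationError("empty sample")
    grand = full.mean()
    if grand == 0.0:
        raise ValidationError("grand mean is zero: MF undefined")
    return float(g.mean() / grand)


def build_comparison_table(cohort: pd.DataFrame, scores: pd.DataFrame,
                           groups: pd.DataFrame
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full group-profiling grid over the twelve comparison variables.

    ``groups`` must hold ``id`` and ``group`` (1/2/3).  Returns a tidy
    comparison table (one row per variable x group pair, with medians,
    IQRs, raw and Bonferroni-adjusted Mann-Whitney p, Cohen's d and the
    omnibus Kruskal-Wallis result repeated per variable) and the mean
    multiplication-factor profile (one row per variable x group).
    """
    df = cohort.merge(scores, on="id").merge(
        groups[["id", "group"]], on="id")
    df["sex_code"] = (df["sex"] == "F").astype(int)
    present = sorted(df["group"].unique())
    for g in (1, 2, 3):
        if g not in present:
            raise ValidationError(f"group {g} is empty")

    comp_rows, mf_rows = [], []
    for label, col, binary in TABLE_VARIABLES:
        x = df[col].to_numpy(dtype=float)
        by_group = {g: x[df["group"] == g] for g in (1, 2, 3)}
        h, dfree, p_kw = kruskal_wallis(x, df["group"].to_numpy())
        for ga, gb in ((1, 2), (1, 3), (2, 3)):
            u, p_raw = mann_whitney_u(by_group[ga], by_group[gb])
            try:
                d = cohens_d(by_group[ga], by_group[gb])
            except ValidationError:
                d = float("nan")
            med_a, iqr_a = median_iqr(by_group[ga])
            med_b, iqr_b = median_iqr(by_group[gb])
            comp_rows.append({
                "variable": label, "binary": binary,
                "kw_H": h, "kw_df": dfree, "kw_p": p_kw,
                "group_a": ga, "group_b": gb,
                "median_a": med_a, "iqr_a": iqr_a,
                "median_b": med_b, "iqr_b": iqr_b,
                "U": u, "p_raw": p_raw,
                "p_adj": bonferroni(p_raw, 3), "d": d,
            })
        grand_ok = x.mean() != 0.0
        for g in (1, 2, 3):
            mf_rows.append({
                "variable": label, "group": g,
                "mf": multiplication_factor(by_group[g], x) if grand_ok
                else float("nan"),
                "group_mean": float(by_group[g].mean()),
                "grand_mean": float(x.mean()),
            })
    return pd.DataFrame(comp_rows), pd.DataFrame(mf_rows)
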