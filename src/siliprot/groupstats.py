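"""Statistical comparison of feature distributions between protein groups.

The central test is the Brunner-Munzel rank test for stochastic equality of
two samples under heteroscedasticity, H0: P(X < Y) = P(X > Y).  It is
accompanied by the Wilcoxon-Mann-Whitney cross-check, per-group normality
screening with the robust Jarque-Bera test (median-based spread), the
Brown-Forsythe equality-of-variance test, and Benjamini-Hochberg FDR
adjustment across the feature battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    """Outcome of one two-sample (or one-sample) test."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None
    estimate: float | None = None
    degenerate: bool = False


def midranks(values) -> np.ndarray:
    """Ranks with ties replaced by their average rank (midranks)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    return stats.rankdata(values, method="average")


def brunner_munzel(x, y) -> TestResult:
    """Brunner-Munzel test for P(X < Y) = P(X > Y).

    Returns the studentized statistic W, Satterthwaite degrees of freedom,
    a two-sided p-value from the t distribution, and the relative effect
    estimate p-hat = P(X < Y) + 0.5 P(X = Y).  If both within-group rank
    variances vanish the result is flagged degenerate and the limiting
    values are reported: complete separation (p-hat 0 or 1) gives W = +-inf
    and p = 0, fully tied samples give W = 0 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 values")
    n = n1 + n2
    pooled = midranks(np.concatenate([x, y]))
    rx, ry = pooled[:n1], pooled[n1:]
    rx_int, ry_int = midranks(x), midranks(y)
    rx_mean, ry_mean = rx.mean(), ry.mean()

    p_hat = (ry_mean - (n2 + 1) / 2.0) / n1

    s1_sq = np.sum((rx - rx_int - rx_mean + (n1 + 1) / 2.0) ** 2) / (n1 - 1)
    s2_sq = np.sum((ry - ry_int - ry_mean + (n2 + 1) / 2.0) ** 2) / (n2 - 1)
    v1, v2 = n1 * s1_sq, n2 * s2_sq

    if v1 + v2 == 0:
        if p_hat in (0.0, 1.0):  # complete separation: limit of W -> +-inf
            stat, p = np.copysign(np.inf, p_hat - 0.5), 0.0
        else:  # all values tied: no evidence either way
            stat, p = 0.0, 1.0
        return TestResult(
            statistic=float(stat), p_value=p, df=np.nan,
            estimate=float(p_hat), method="brunner-munzel", degenerate=True,
        )

    w = n1 * n2 * (ry_mean - rx_mean) / (n * np.sqrt(v1 + v2))
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(w), df)
    return TestResult(
        statistic=float(w), p_value=float(p), df=float(df),
        estimate=float(p_hat), method="brunner-munzel",
    )


def mann_whitney(x, y) -> TestResult:
    """Two-sided Wilcoxon-Mann-Whitney test, normal approximation with tie
    correction (no continuity correction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.ptp(np.concatenate([x, y])) == 0:
        # all values identical: U at its null mean, no evidence either way
        return TestResult(
            statistic=len(x) * len(y) / 2.0, p_value=1.0,
            method="mann-whitney", degenerate=True,
        )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), method="mann-whitney"
    )


def robust_jarque_bera(x) -> TestResult:
    """Robust Jarque-Bera normality test.

    Classical JB moments but with the spread estimated robustly as the
    average absolute deviation from the sample median (scaled by
    sqrt(pi/2)); the statistic is compared to chi-square(2).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 values")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    j = np.sqrt(np.pi / 2.0) * np.mean(np.abs(x - np.median(x)))
    m = x.mean()
    m3 = np.mean((x - m) ** 3)
    m4 = np.mean((x - m) ** 4)
    stat = n * ((m3 / j**3) ** 2 / 6.0 + (m4 / j**4 - 3.0) ** 2 / 64.0)
    p = stats.chi2.sf(stat, 2)
    return TestResult(statistic=float(stat), p_value=float(p), df=2.0,
                      method="robust-jarque-bera")


def brown_forsythe(x, y) -> TestResult:
    """Brown-Forsythe equality-of-variance test (ANOVA on absolute
    deviations from the group medians)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    zx = np.abs(x - np.median(x))
    zy = np.abs(y - np.median(y))
    if np.all(zx == 0) and np.all(zy == 0):
        raise ValueError("all deviations zero")
    stat, p = stats.levene(x, y, center="median")
    return TestResult(statistic=float(stat), p_value=float(p),
                      df=float(len(x) + len(y) - 2), method="brown-forsythe")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    NaN entries (tests that could not be run) are passed through untouched
    and do not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p[~np.isnan(p)] < 0) | (p[~np.isnan(p)] > 1)):
        raise ValueError("p-values must be in [0, 1]")
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF as (sorted unique values, cumulative fractions).

    Right-continuous step function; the last fraction is exactly 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    xs, counts = np.unique(values, return_counts=True)
    fracs = np.cumsum(counts) / values.size
    return xs, fracs


def compare_groups(
    features: pd.DataFrame,
    labels,
    group_a: str = "adsorbed",
    group_b: str = "non_adsorbed",
    center: str = "mean",
) -> pd.DataFrame:
    """Compare every feature between two protein groups.

    Parameters
    ----------
    features:
        Proteins x features matrix (index = protein id).
    labels:
        Mapping or Series protein id -> group label; proteins with other
        labels (intermediate, unmatched) are ignored.
    center:
        Summary used to call the direction of the difference
        (``"mean"`` or ``"median"``).

    Returns
    -------
    DataFrame with one row per feature, sorted by ascending Brunner-Munzel
    p-value: group sizes, direction (``more``/``less`` in group A), the BM
    statistic/relative effect/p, the BH-adjusted p, the Mann-Whitney
    cross-check p, per-group robust Jarque-Bera normality p-values and the
    Brown-Forsythe homoscedasticity p-value.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    ids_a = [i for i in features.index if labels.get(i) == group_a]
    ids_b = [i for i in features.index if labels.get(i) == group_b]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(f"need >= 2 proteins per group (got {len(ids_a)}/{len(ids_b)})")
    summary = np.mean if center == "mean" else np.median

    rows = []
    for feat in features.columns:
        a = features.loc[ids_a, feat].dropna().to_numpy(float)
        b = features.loc[ids_b, feat].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            continue
        bm = brunner_munzel(a, b)
        try:
            mwu_p = mann_whitney(a, b).p_value
        except ValueError:
            mwu_p = np.nan

        def _norm_p(v):
            try:
                return robust_jarque_bera(v).p_value
            except ValueError:
                return np.nan

        try:
            bf_p = brown_forsythe(a, b).p_value
        except ValueError:
            bf_p = np.nan
        rows.append({
            "feature": feat,
            "n_a": len(a),
            "n_b": len(b),
            "direction": "more" if summary(a) > summary(b) else "less",
            "bm_statistic": bm.statistic,
            "bm_estimate": bm.estimate,
            "p_value": bm.p_value,
            "p_mwu": mwu_p,
            "normality_p_a": _norm_p(a),
            "normality_p_b": _norm_p(b),
            "homoscedasticity_p": bf_p,
            "degenerate": bm.degenerate,
        })
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values("p_value", kind="mergesort", na_position="last")
    return table.reset_index(drop=True)
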