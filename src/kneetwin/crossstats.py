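"""Cross-sectional feature testing: normality screening, two-sided rank-sum
tests per PC-mode feature, Benjamini-Hochberg adjustment, and percentile
bootstrap confidence intervals.

The rank-sum stage is run unpaired across all features of the matched
cohorts; normality screens (Shapiro-Wilk, Anderson-Darling at the 5% level)
guide the choice of non-parametric tests but do not gate them.  Adjusted
p-values use the standard step-up false-discovery-rate estimator; the
sharper Hochberg family-wise procedure is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "normality_screen",
    "rank_sum_test",
    "bh_adjust",
    "hochberg_adjust",
    "bootstrap_ci",
    "cross_sectional_tests",
    "significance_tier",
]


@dataclass
class TestResult:
    feature: str
    statistic: float
    p_raw: float
    p_adjusted: float
    tier: str
    ci95: tuple[float, float]
    ci99: tuple[float, float]
    n_case: int
    n_control: int


def significance_tier(p: float) -> str:
    """Asterisk convention: * p<0.05, ** p<0.01, *** p<0.001, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def normality_screen(values: np.ndarray, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk and Anderson-Darling screen of one feature sample.

    Constant samples are flagged non-normal with sentinel statistics.
    Returns W, p, the A^2 statistic, the smallest exceeded significance
    level (15 meaning none exceeded), and a combined ``normal`` flag at
    ``alpha``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("normality screen needs at least 3 observations")
    if np.ptp(x) == 0:
        return {
            "shapiro_w": np.nan, "shapiro_p": 0.0,
            "anderson_stat": np.inf, "anderson_sig_level": 1.0,
            "normal": False,
        }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = stats.shapiro(x)
        ad = stats.anderson(x, dist="norm")
    exceeded = ad.statistic > ad.critical_values
    sig = float(ad.significance_level[exceeded][-1]) if exceeded.any() else 15.0
    ad_reject = sig <= 100 * alpha
    return {
        "shapiro_w": float(w),
        "shapiro_p": float(p),
        "anderson_stat": float(ad.statistic),
        "anderson_sig_level": sig,
        "normal": bool(p >= alpha and not ad_reject),
    }


def rank_sum_test(case, control, exact_threshold: int = 25):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both groups have at most
    ``exact_threshold`` observations and there are no ties, otherwise the
    tie-corrected normal approximation.  The returned statistic is the
    rank-sum W of the case group.  If every value across both groups is
    tied, p = 1 is returned with a flag.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be nonempty")
    all_tied = np.ptp(np.concatenate([case, control])) == 0
    if all_tied:
        w = case.size * (case.size + control.size + 1) / 2.0
        return w, 1.0, True
    small = case.size <= exact_threshold and control.size <= exact_threshold
    method = "exact" if small else "asymptotic"
    try:
        res = stats.mannwhitneyu(case, control, alternative="two-sided", method=method)
    except ValueError:  # exact method refuses ties
        res = stats.mannwhitneyu(
            case, control, alternative="two-sided", method="asymptotic"
        )
    w = res.statistic + case.size * (case.size + 1) / 2.0  # U -> rank-sum W
    return float(w), float(res.pvalue), False


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order.

    With p-values sorted ascending, the adjusted value at rank i is
    ``min over j >= i of min(1, (m/j) * P(j))`` — the smallest false
    discovery rate at which the i-th test would still be declared
    significant.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def hochberg_adjust(pvals) -> np.ndarray:
    """Hochberg's sharpened step-up family-wise adjustment (the alternative
    convention some report alongside BH): adjusted(i) = min over j >= i of
    min(1, (m - j + 1) * P(j))."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * (m - np.arange(m))
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def bootstrap_ci(
    statistic,
    data,
    n_boot: int = 1000,
    levels: tuple[float, ...] = (95.0, 99.0),
    seed: int = 0,
) -> dict[float, tuple[float, float]]:
    """Percentile bootstrap intervals for ``statistic(data)``.

    ``data`` may be one array or a tuple of arrays resampled
    independently (e.g. the two groups of a median difference).
    Deterministic given ``seed``.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; intervals will be noisy")
    groups = data if isinstance(data, tuple) else (data,)
    groups = tuple(np.asarray(g, dtype=float) for g in groups)
    if any(g.size == 0 for g in groups):
        raise ValueError("data must be nonempty")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        resampled = tuple(g[rng.integers(0, g.size, g.size)] for g in groups)
        reps[b] = statistic(*resampled)
    out = {}
    for lvl in levels:
        half = (100.0 - lvl) / 2.0
        out[lvl] = (
            float(np.percentile(reps, half)),
            float(np.percentile(reps, 100.0 - half)),
        )
    return out


def median_difference(case, control) -> float:
    return float(np.median(case) - np.median(control))


def cross_sectional_tests(
    table: pd.DataFrame,
    feature_columns: list[str],
    outcome_col: str = "outcome",
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    adjustment: str = "bh",
) -> pd.DataFrame:
    """Rank-sum test every feature, adjust across the family, bootstrap CIs.

    One row per feature: rank-sum W, raw and adjusted p, significance tier
    on the adjusted p, and percentile-bootstrap 95%/99% CIs of the
    case-control median difference.
    """
    case = table[table[outcome_col] == 1]
    ctrl = table[table[outcome_col] == 0]
    adjust = {"bh": bh_adjust, "hochberg": hochberg_adjust}[adjustment]
    rows = []
    rng = np.random.default_rng(seed)
    for f in feature_columns:
        a = case[f].to_numpy(dtype=float)
        b = ctrl[f].to_numpy(dtype=float)
        w, p, _ = rank_sum_test(a, b)
        cis = bootstrap_ci(
            median_difference, (a, b), n_boot=n_boot, seed=int(rng.integers(2**31 - 1))
        )
        rows.append(
            {"feature": f, "statistic": w, "p_raw": p,
             "ci95_lo": cis[95.0][0], "ci95_hi": cis[95.0][1],
             "ci99_lo": cis[99.0][0], "ci99_hi": cis[99.0][1],
             "n_case": a.size, "n_control": b.size}
        )
    res = pd.DataFrame(rows).set_index("feature")
    res["p_adjusted"] = adjust(res["p_raw"].to_numpy())
    res["tier"] = [significance_tier(p) for p in res["p_adjusted"]]
    return res
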