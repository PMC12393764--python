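"""Group summaries and the nonparametric test battery used on isotope cohorts.

Thin, explicit wrappers over scipy/statsmodels: Spearman rank correlation
(exact p for small tie-free samples), Wilcoxon–Mann–Whitney with Holm
step-down adjustment over a declared comparison family, Shapiro–Wilk
normality and Fisher's exact test. Each wrapper records which p-value
regime (exact vs approximation) was used.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio
from statsmodels.stats.multitest import multipletests

ISOTOPE_COLUMNS = ("d13C", "d15N", "d34S")


def summarize(samples: pd.DataFrame, grouping: list[str],
              isotopes: tuple[str, ...] = ISOTOPE_COLUMNS) -> pd.DataFrame:
    """Per-group descriptive statistics for each isotope.

    One output row per (group, isotope): n, mean, median, min, max, sd
    (sample sd, absent for n = 1). Values are never rounded here; rounding
    is presentation's business. Empty groups are omitted.
    """
    for key in grouping:
        if key not in samples.columns:
            raise KeyError(f"grouping column {key!r} not in table")
    rows = []
    for keys, grp in samples.groupby(grouping, dropna=False, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for iso in isotopes:
            v = grp[iso].dropna().to_numpy(dtype=float)
            if v.size == 0:
                continue
            rows.append({
                **dict(zip(grouping, keys)),
                "isotope": iso,
                "n": int(v.size),
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "min": float(np.min(v)),
                "max": float(np.max(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else np.nan,
            })
    return pd.DataFrame(rows)


def _spearman_exact_p(rho_obs: float, xr: np.ndarray, yr: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of rank permutations."""
    n = len(xr)
    perms = np.array(list(permutations(range(n))))
    xs = (xr - xr.mean()) / xr.std()
    ys = (yr - yr.mean()) / yr.std()
    rhos = (ys[perms] * xs).mean(axis=1)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y, exact_max_n: int = 8) -> tuple[float, float, str]:
    """Spearman rho with two-sided p; returns (rho, p, method).

    Absent pairs are dropped listwise. For n ≤ ``exact_max_n`` with no ties
    the p-value is exact (permutation enumeration); otherwise the
    t-approximation. The method string records which was used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("spearman needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    rho, p_approx = stats.spearmanr(x, y)
    no_ties = (len(np.unique(x)) == x.size) and (len(np.unique(y)) == y.size)
    if x.size <= exact_max_n and no_ties:
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        return float(rho), float(_spearman_exact_p(rho, xr, yr)), "exact"
    return float(rho), float(p_approx), "t-approximation"


def mann_whitney(x, y, exact_max_n: int = 8) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U; exact when both groups ≤ exact_max_n and
    tie-free, else the tie-corrected normal approximation (no continuity
    correction, so identical groups give p = 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group in Mann-Whitney comparison")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    if x.size <= exact_max_n and y.size <= exact_max_n and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue), "normal approximation"


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values for one declared family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def mwu_holm(comparisons: dict[str, tuple]) -> pd.DataFrame:
    """Mann-Whitney U over a declared family with Holm adjustment.

    ``comparisons`` maps a label to an (x, y) pair of value vectors; the
    dict *is* the adjustment family. Output rows keep input order.
    """
    labels = list(comparisons)
    rows = []
    for label in labels:
        x, y = comparisons[label]
        u, p, method = mann_whitney(x, y)
        rows.append({"comparison": label, "U": u, "p_raw": p, "method": method})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def shapiro(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p; n restricted to [3, 5000]."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if not (3 <= v.size <= 5000):
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {v.size}")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> tuple[float, float]:
    """Conditional-MLE odds ratio and two-sided exact p for a 2x2 table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        as_int = t.astype(int)
        if np.any(t < 0) or not np.array_equal(as_int, t):
            raise ValueError("counts must be non-negative integers")
        t = as_int
    _, p = stats.fisher_exact(t, alternative="two-sided")
    or_cond = odds_ratio(t, kind="conditional").statistic
    return float(or_cond), float(p)
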