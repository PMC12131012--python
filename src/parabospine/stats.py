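"""Inferential battery: decision gates, repeated-measures tests, post hocs.

Implements the analysis battery used for the gravity-condition comparisons:

* a Shapiro–Wilk normality gate (with 3×IQR extreme-outlier screen) that
  routes each outcome to the parametric (repeated-measures ANOVA + paired
  t-tests) or nonparametric (Friedman + Wilcoxon signed-rank) path;
* one-way repeated-measures ANOVA with the Greenhouse–Geisser sphericity
  correction, plus a trimmed-means (robust) variant for the order-effect
  screens;
* Bonferroni-corrected paired t-tests, Friedman tests (exact permutation
  null for small cohorts, χ² otherwise), Wilcoxon signed-rank post hocs and
  Spearman rank associations — every Bonferroni family size is an explicit
  argument, never inferred;
* post-hoc power of the paired t-test from the noncentral t distribution.

All operations are pure functions over in-memory arrays and return
:class:`~parabospine.core.StatTestResult` objects.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .core import PowerSpec, StatTestResult, bonferroni

__all__ = [
    "GateResult",
    "shapiro_gate",
    "rm_anova_gg",
    "rm_anova_trimmed",
    "paired_t_bonferroni",
    "friedman_bonferroni",
    "wilcoxon_posthoc",
    "spearman_assoc",
    "paired_t_power",
    "StatTestResult",
    "PowerSpec",
]


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GateResult:
    """Routing decision from the normality / extreme-outlier screen."""

    verdicts: dict[str, str]  # cell -> "normal" | "non-normal" | "untestable"
    extreme_outliers: dict[str, int]  # cell -> count beyond 3*IQR
    route: str  # "parametric" | "nonparametric"
    alpha: float

    @property
    def parametric(self) -> bool:
        return self.route == "parametric"


def _extreme_outlier_count(x: np.ndarray, k: float = 3.0) -> int:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return int(np.sum((x < q1 - k * iqr) | (x > q3 + k * iqr)))


def shapiro_gate(cells: dict[str, np.ndarray], alpha: float = 0.05) -> GateResult:
    """Shapiro–Wilk screen of every cell plus a 3×IQR extreme-outlier check.

    The parametric path is taken only when every cell is testable, none
    rejects normality at ``alpha`` and no cell contains extreme outliers;
    otherwise the nonparametric path (Friedman / Wilcoxon) is indicated.
    Cells with fewer than 3 values, or with zero variance, are untestable
    and force the nonparametric route.
    """
    verdicts: dict[str, str] = {}
    outliers: dict[str, int] = {}
    for name, values in cells.items():
        x = np.asarray(values, dtype=float)
        x = x[~np.isnan(x)]
        if x.size < 3 or x.size > 5000 or np.ptp(x) == 0:
            verdicts[name] = "untestable"
            outliers[name] = 0
            continue
        _, p = sst.shapiro(x)
        verdicts[name] = "normal" if p >= alpha else "non-normal"
        outliers[name] = _extreme_outlier_count(x)
    parametric = all(v == "normal" for v in verdicts.values()) and not any(
        outliers.values()
    )
    return GateResult(
        verdicts=verdicts,
        extreme_outliers=outliers,
        route="parametric" if parametric else "nonparametric",
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse–Geisser sample epsilon from the condition covariance.

    Computed from the eigenvalues of the double-centered sample covariance
    of the k conditions; bounded in [1/(k-1), 1].  For k = 2 sphericity is
    trivial and epsilon is exactly 1.
    """
    k = data.shape[1]
    if k == 2:
        return 1.0
    s = np.cov(data, rowvar=False)
    c = np.eye(k) - np.full((k, k), 1.0 / k)
    sdc = c @ s @ c
    lam = np.linalg.eigvalsh(sdc)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * float(np.sum(lam**2))
    if denom <= 0:
        return 1.0
    eps = float(np.sum(lam)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(data: np.ndarray, alpha: float = 0.05) -> StatTestResult:
    """One-way repeated-measures ANOVA with Greenhouse–Geisser correction.

    ``data`` is a complete participant × condition matrix (apply listwise
    deletion first).  Both F degrees of freedom are multiplied by the
    sample GG epsilon.  A matrix with no between-condition variance returns
    the degenerate F = 0, p = 1.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be a participant x condition matrix, k >= 2")
    if np.any(np.isnan(data)):
        raise ValueError("matrix must be complete; apply listwise deletion first")
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 complete participants")

    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    resid = data - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = float(np.sum(resid**2))

    eps = _gg_epsilon(data)
    df1, df2 = (k - 1) * eps, (k - 1) * (n - 1) * eps
    if ss_err <= 1e-300:
        if ss_cond <= 1e-300:
            return StatTestResult(
                "rm_anova_gg", 0.0, "F", (df1, df2), 1.0, 1.0,
                alpha=alpha, epsilon_gg=eps, n=n, detail="degenerate: no variance",
            )
        f_stat, p = math.inf, 0.0
    else:
        f_stat = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        p = float(sst.f.sf(f_stat, df1, df2))
    return StatTestResult(
        name="rm_anova_gg",
        statistic=float(f_stat),
        stat_label="F",
        df=(df1, df2),
        p_raw=p,
        p_corrected=p,
        alpha=alpha,
        epsilon_gg=eps,
        n=n,
    )


def _winsorize_columns(data: np.ndarray, g: int) -> np.ndarray:
    out = data.copy()
    if g == 0:
        return out
    srt = np.sort(data, axis=0)
    lo, hi = srt[g], srt[-g - 1]
    return np.clip(out, lo[None, :], hi[None, :])


def rm_anova_trimmed(
    data: np.ndarray, trim: float = 0.2, alpha: float = 0.05
) -> StatTestResult:
    """Robust one-way repeated-measures test on trimmed means.

    Condition effects are assessed on 20%-trimmed (by default) condition
    means, with the error term built from column-Winsorized residuals and
    degrees of freedom adjusted by a GG-type epsilon computed on the
    Winsorized data.  With ``trim = 0`` this reduces exactly to
    :func:`rm_anova_gg`.  Used for the parabola-order screens where heavy
    tails and outliers are expected.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be a participant x condition matrix, k >= 2")
    if np.any(np.isnan(data)):
        raise ValueError("matrix must be complete; apply listwise deletion first")
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    n, k = data.shape
    g = int(math.floor(trim * n))
    h = n - 2 * g
    if h < 3:
        raise ValueError("too few participants after trimming")

    srt = np.sort(data, axis=0)
    tmeans = srt[g : n - g].mean(axis=0)
    qc = h * float(np.sum((tmeans - tmeans.mean()) ** 2))

    y = _winsorize_columns(data, g)
    resid = y - y.mean(axis=0)[None, :] - y.mean(axis=1)[:, None] + y.mean()
    qe = float(np.sum(resid**2))

    eps = _gg_epsilon(y)
    df1, df2 = (k - 1) * eps, (h - 1) * (k - 1) * eps
    if qe <= 1e-300:
        if qc <= 1e-300:
            return StatTestResult(
                "rm_anova_trimmed", 0.0, "F", (df1, df2), 1.0, 1.0,
                alpha=alpha, epsilon_gg=eps, n=n, detail="degenerate: no variance",
            )
        f_stat, p = math.inf, 0.0
    else:
        f_stat = (qc / (k - 1)) / (qe / ((h - 1) * (k - 1)))
        p = float(sst.f.sf(f_stat, df1, df2))
    return StatTestResult(
        name="rm_anova_trimmed",
        statistic=float(f_stat),
        stat_label="F",
        df=(df1, df2),
        p_raw=p,
        p_corrected=p,
        alpha=alpha,
        epsilon_gg=eps,
        n=n,
        detail=f"trim={trim}",
    )


# ---------------------------------------------------------------------------
# pairwise t-tests
# ---------------------------------------------------------------------------


def paired_t_bonferroni(
    data: dict[str, np.ndarray],
    pairs: list[tuple[str, str]],
    family_size: int | None = None,
    alpha: float = 0.05,
) -> list[StatTestResult]:
    """Two-sided paired t-tests with Bonferroni correction over the family.

    ``family_size`` defaults to the number of pairs (3 for the three gravity
    conditions).  Zero-variance differences yield the degenerate t = 0,
    p = 1 result rather than an error.
    """
    m = family_size if family_size is not None else len(pairs)
    results = []
    for a, b in pairs:
        x = np.asarray(data[a], dtype=float)
        y = np.asarray(data[b], dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"pair ({a}, {b}): unequal lengths")
        d = x - y
        n = d.size
        if n < 2:
            raise ValueError("need at least 2 pairs")
        if np.ptp(d) == 0 and d[0] == 0:
            t_stat, p = 0.0, 1.0
            detail = "degenerate: zero differences"
        elif np.ptp(d) == 0:
            t_stat, p = math.copysign(math.inf, d[0]), 0.0
            detail = "degenerate: constant nonzero differences"
        else:
            t_stat, p = sst.ttest_rel(x, y)
            detail = ""
        results.append(
            StatTestResult(
                name=f"paired_t[{a} vs {b}]",
                statistic=float(t_stat),
                stat_label="t",
                df=(float(n - 1),),
                p_raw=float(p),
                p_corrected=bonferroni(float(p), m),
                correction="bonferroni",
                family_size=m,
                alpha=alpha,
                n=n,
                detail=detail,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from within-row mid-ranks."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    c = n * k * (k + 1) ** 2 / 4.0
    a1 = float(np.sum(ranks**2))
    # sum of squared deviations of column rank sums from their null mean
    dev = float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2))
    denom = a1 - c
    if denom <= 0:  # all rows fully tied
        return 0.0
    return (k - 1) * dev / denom


def _friedman_exact_p(ranks: np.ndarray) -> float:
    """Exact permutation p-value for the Friedman statistic.

    Under the null every within-row arrangement of the observed (mid-)rank
    vector is equally likely; the tie-corrected statistic is a monotone
    function of the sum of squared column rank sums, so the distribution is
    accumulated by dynamic programming over column-sum states (counts are
    exact integers; rank sums are tracked in half-units).
    """
    n, k = ranks.shape
    # half-unit integer ranks keep states hashable and exact
    r2 = np.round(ranks * 2).astype(int)
    states: dict[tuple[int, ...], int] = {tuple([0] * k): 1}
    for i in range(n):
        perms = list(itertools.permutations(r2[i]))
        nxt: dict[tuple[int, ...], int] = {}
        for state, cnt in states.items():
            for perm in perms:
                key = tuple(s + p for s, p in zip(state, perm))
                nxt[key] = nxt.get(key, 0) + cnt
        states = nxt
    # observed criterion on the same half-unit scale
    obs_ss = float(np.sum((np.round(ranks.sum(axis=0) * 2)) ** 2))
    total = sum(states.values())
    extreme = sum(
        cnt
        for sums, cnt in states.items()
        if float(sum(s**2 for s in sums)) >= obs_ss - 1e-9
    )
    return extreme / total


def friedman_bonferroni(
    data: np.ndarray,
    family_size: int = 1,
    name: str = "friedman",
    alpha: float = 0.05,
    exact_n_max: int = 8,
) -> StatTestResult:
    """Friedman test over a complete participant × condition block.

    Ties are handled by mid-ranks with the standard tie correction of the
    chi-square statistic.  The p-value comes from exhaustive enumeration of
    the within-row permutation null whenever that is cheap — always for
    ``n <= exact_n_max``, and for three-condition blocks up to n = 25 (the
    dynamic program over rank-sum states stays tiny there); otherwise from
    the chi-square approximation with k − 1 degrees of freedom, which is
    noticeably conservative at cohort sizes.  The Bonferroni
    ``family_size`` spans the battery the test belongs to (the four erector
    spinae sites in the site comparisons).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("data must be a participant x condition matrix, k >= 2")
    if np.any(np.isnan(data)):
        raise ValueError("matrix must be complete; apply listwise deletion first")
    n, k = data.shape
    ranks = np.apply_along_axis(sst.rankdata, 1, data)
    stat = _friedman_statistic(ranks)
    if n <= exact_n_max or (k == 3 and n <= 25):
        p = _friedman_exact_p(ranks)
        detail = "exact permutation null"
    else:
        p = float(sst.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
        detail = "chi-square approximation"
    return StatTestResult(
        name=name,
        statistic=float(stat),
        stat_label="chi2",
        df=(float(k - 1),),
        p_raw=p,
        p_corrected=bonferroni(p, family_size),
        correction="bonferroni" if family_size > 1 else "none",
        family_size=family_size,
        alpha=alpha,
        n=n,
        detail=detail,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def wilcoxon_posthoc(
    data: dict[str, np.ndarray],
    pairs: list[tuple[str, str]],
    family_size: int | None = None,
    alpha: float = 0.05,
) -> list[StatTestResult]:
    """Two-sided Wilcoxon signed-rank tests with Bonferroni correction.

    Zero differences are dropped (classic convention); W is the sum of the
    positive-difference ranks.  The p-value is exact for n <= 25 without
    ties in the absolute differences and a normal approximation with
    continuity correction otherwise.  All differences zero is degenerate
    (W = 0, p = 1).
    """
    m = family_size if family_size is not None else len(pairs)
    results = []
    for a, b in pairs:
        d = np.asarray(data[a], dtype=float) - np.asarray(data[b], dtype=float)
        d = d[d != 0.0]
        n = d.size
        if n == 0:
            results.append(
                StatTestResult(
                    name=f"wilcoxon[{a} vs {b}]", statistic=0.0, stat_label="W",
                    df=(), p_raw=1.0, p_corrected=1.0, correction="bonferroni",
                    family_size=m, alpha=alpha, n=0, detail="degenerate: all zeros",
                )
            )
            continue
        ranks = sst.rankdata(np.abs(d))
        w_pos = float(ranks[d > 0].sum())
        has_ties = np.unique(np.abs(d)).size < n
        if n <= 25 and not has_ties:
            method = "exact"
        else:
            method = "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sst.wilcoxon(
                d, zero_method="wilcox", alternative="two-sided",
                correction=(method == "approx"), method=method,
            )
        results.append(
            StatTestResult(
                name=f"wilcoxon[{a} vs {b}]",
                statistic=w_pos,
                stat_label="W",
                df=(),
                p_raw=float(res.pvalue),
                p_corrected=bonferroni(float(res.pvalue), m),
                correction="bonferroni" if m > 1 else "none",
                family_size=m,
                alpha=alpha,
                n=n,
                detail=method,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Spearman association
# ---------------------------------------------------------------------------


def spearman_assoc(
    x: np.ndarray,
    y: np.ndarray,
    family_size: int = 1,
    name: str = "spearman",
    alpha: float = 0.05,
) -> StatTestResult:
    """Spearman rank correlation over paired complete cases.

    Mid-ranks resolve ties.  ``family_size`` carries the Bonferroni family
    (4 for the erector spinae sites; 1 for the multifidus site, which is
    tested alone and uncorrected).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 complete pairs for a rank correlation")
    rho, p = sst.spearmanr(x, y)
    return StatTestResult(
        name=name,
        statistic=float(rho),
        stat_label="rho",
        df=(float(x.size - 2),),
        p_raw=float(p),
        p_corrected=bonferroni(float(p), family_size),
        correction="bonferroni" if family_size > 1 else "none",
        family_size=family_size,
        alpha=alpha,
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


def paired_t_power(spec: PowerSpec) -> float:
    """Achieved power of a paired t-test from the noncentral t distribution.

    With paired effect size d and n pairs the noncentrality parameter is
    ``d * sqrt(n)`` and the null critical value comes from the central t
    with n − 1 degrees of freedom.  At d = 0 the power equals alpha.
    """
    df = spec.n_pairs - 1
    ncp = spec.effect_size_d * math.sqrt(spec.n_pairs)
    if spec.tails == 2:
        tcrit = sst.t.ppf(1.0 - spec.alpha / 2.0, df)
        power = sst.nct.sf(tcrit, df, ncp) + sst.nct.cdf(-tcrit, df, ncp)
    else:
        tcrit = sst.t.ppf(1.0 - spec.alpha, df)
        power = sst.nct.sf(tcrit, df, ncp)
    return float(power)
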