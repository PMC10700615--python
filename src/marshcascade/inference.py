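"""Treatment-comparison statistics.

One-way ANOVA with Tukey HSD and a compact letter display, pairwise
rank-sum (Wilcoxon) tests with Bonferroni adjustment, pairwise proportion
tests for the tethering outcomes, first-week plant-loss slopes, AICc
selection between linear and quadratic fits, and Spearman correlations
among functions.

Mixed-model (GLMM) estimation is deliberately out of scope: repeated
measures are summarized by per-month tests and the effect-size
meta-regression in :mod:`marshcascade.effects`; callers needing a full
mixed model can export the tidy tables to an external backend.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TreatmentComparison",
    "RegressionFit",
    "anova_tukey",
    "wilcoxon_pairwise",
    "pairwise_proportions",
    "first_week_loss_rate",
    "fit_and_select",
    "spearman_matrix",
    "compact_letter_display",
]


@dataclass
class TreatmentComparison:
    """Omnibus + pairwise test results with a compact letter display."""

    method: str
    statistic: float
    df: tuple[float, float] | None
    p: float
    pairwise: pd.DataFrame  # columns: group1, group2, p_raw, p_adj, reject
    letters: dict[str, str]
    alpha: float = 0.05
    notes: str = ""


@dataclass
class RegressionFit:
    """A selected polynomial fit with small-sample AIC."""

    form: str  # "linear" or "quadratic"
    coef: np.ndarray  # ascending powers
    aicc: float
    r2: float
    n: int
    candidates: dict[str, float] = field(default_factory=dict)  # form -> AICc


# ---------------------------------------------------------------------------
# Compact letter display (insert-and-absorb)
# ---------------------------------------------------------------------------

def compact_letter_display(groups: list[str],
                           means: dict[str, float],
                           significant_pairs: set[frozenset]) -> dict[str, str]:
    """Assign letters so that two groups share a letter exactly when their
    difference is *not* significant.

    Insert-and-absorb: start from one letter covering everyone; for every
    significant pair split each letter containing both; drop letters that
    became subsets of others. Letters are ordered by descending group mean.
    """
    columns: list[set] = [set(groups)]
    for pair in significant_pairs:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb duplicates / subsets
        columns = [c for c in columns
                   if c and not any(c < d for d in columns if d is not c)]
        pruned = []
        for c in columns:
            if c not in pruned:
                pruned.append(c)
        columns = pruned
    # order letters by the best (largest) mean they contain
    columns.sort(key=lambda c: -max(means[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assigned: dict[str, str] = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in sorted(col, key=lambda g: -means[g]):
            assigned[g] += letter
    return {g: "".join(sorted(s)) for g, s in assigned.items()}


def _pairwise_frame(pairs, p_raw, p_adj, alpha) -> pd.DataFrame:
    return pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "p_raw": p_raw,
        "p_adj": p_adj,
        "reject": [p <= alpha for p in p_adj],
    })


# ---------------------------------------------------------------------------
# Omnibus + post-hoc tests
# ---------------------------------------------------------------------------

def anova_tukey(values_by_group: dict[str, np.ndarray],
                alpha: float = 0.05,
                posthoc: bool = True) -> TreatmentComparison:
    """One-way ANOVA followed by Tukey HSD on all pairs, with letters.

    ``posthoc=False`` skips the studentized-range computations and returns
    the omnibus F-test only (useful in large simulations)."""
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("need at least two observations per group")
    n_total = sum(a.size for a in arrays)
    df1, df2 = len(groups) - 1, n_total - len(groups)
    if all(np.ptp(a) == 0 for a in arrays):
        if len({float(a[0]) for a in arrays}) == 1:
            # identical constant groups: no evidence of any difference
            pairs = list(itertools.combinations(groups, 2))
            pw = _pairwise_frame(pairs, [1.0] * len(pairs), [1.0] * len(pairs), alpha)
            means = {g: float(np.mean(a)) for g, a in zip(groups, arrays)}
            return TreatmentComparison("anova_tukey", 0.0, (df1, df2), 1.0,
                                       pw, compact_letter_display(groups, means, set()),
                                       alpha, notes="zero variance everywhere")
        raise ValueError("zero within-group variance everywhere; F undefined")
    fstat, pval = stats.f_oneway(*arrays)
    means = {g: float(np.mean(a)) for g, a in zip(groups, arrays)}
    if not posthoc:
        pw = _pairwise_frame([], [], [], alpha)
        return TreatmentComparison("anova", float(fstat), (df1, df2),
                                   float(pval), pw,
                                   compact_letter_display(groups, means, set()),
                                   alpha, notes="omnibus only")

    flat = np.concatenate(arrays)
    labels = np.concatenate([[g] * a.size for g, a in zip(groups, arrays)])
    tukey = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    pairs = list(itertools.combinations(list(tukey.groupsunique), 2))
    p_adj = [float(p) for p in tukey.pvalues]
    pw = _pairwise_frame(pairs, p_adj, p_adj, alpha)

    sig = {frozenset(p) for p, r in zip(pairs, pw["reject"]) if r}
    letters = compact_letter_display(groups, means, sig)
    return TreatmentComparison("anova_tukey", float(fstat), (df1, df2),
                               float(pval), pw, letters, alpha)


def wilcoxon_pairwise(values_by_group: dict[str, np.ndarray],
                      alpha: float = 0.05) -> TreatmentComparison:
    """Pairwise two-sided rank-sum (Mann-Whitney/Wilcoxon) tests with
    Bonferroni adjustment and letters. Independent plots, so the rank-sum
    (not signed-rank) variant applies; exact null distribution for small
    tie-free samples, normal approximation with tie correction otherwise."""
    groups = list(values_by_group)
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    pairs = list(itertools.combinations(groups, 2))
    p_raw, stats_w = [], []
    for a, b in pairs:
        xa, xb = arrays[a], arrays[b]
        if np.ptp(np.concatenate([xa, xb])) == 0:
            stats_w.append(float(xa.size * xb.size / 2))
            p_raw.append(1.0)
            continue
        method = "exact" if (min(xa.size, xb.size) < 8 and
                             np.unique(np.concatenate([xa, xb])).size
                             == xa.size + xb.size) else "asymptotic"
        w, p = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                  method=method)
        stats_w.append(float(w))
        p_raw.append(float(p))
    p_adj = [min(1.0, p * len(pairs)) for p in p_raw]
    pw = _pairwise_frame(pairs, p_raw, p_adj, alpha)
    # Kruskal-Wallis as the omnibus companion statistic
    if all(np.ptp(v) == 0 for v in arrays.values()) and \
            len({float(v[0]) for v in arrays.values()}) == 1:
        h, p_omni = 0.0, 1.0
    else:
        h, p_omni = stats.kruskal(*arrays.values())
    means = {g: float(np.mean(v)) for g, v in arrays.items()}
    sig = {frozenset(p) for p, r in zip(pairs, pw["reject"]) if r}
    letters = compact_letter_display(groups, means, sig)
    return TreatmentComparison("wilcoxon_bonferroni", float(h),
                               (len(groups) - 1, float("nan")), float(p_omni),
                               pw, letters, alpha)


def pairwise_proportions(eaten_by_group: dict[str, int],
                         total_by_group: dict[str, int],
                         alpha: float = 0.05) -> TreatmentComparison:
    """Pairwise two-sided proportion tests (chi-square with continuity
    correction) with Bonferroni adjustment, for e.g. tethering outcomes."""
    groups = list(eaten_by_group)
    pairs = list(itertools.combinations(groups, 2))
    p_raw, chis = [], []
    for a, b in pairs:
        table = np.array([
            [eaten_by_group[a], total_by_group[a] - eaten_by_group[a]],
            [eaten_by_group[b], total_by_group[b] - eaten_by_group[b]],
        ])
        if np.any(table.sum(axis=1) <= 0):
            raise ValueError("each group needs a positive total")
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            chis.append(0.0)
            p_raw.append(1.0)
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        chis.append(float(chi2))
        p_raw.append(float(p))
    p_adj = [min(1.0, p * len(pairs)) for p in p_raw]
    pw = _pairwise_frame(pairs, p_raw, p_adj, alpha)
    props = {g: eaten_by_group[g] / total_by_group[g] for g in groups}
    sig = {frozenset(p) for p, r in zip(pairs, pw["reject"]) if r}
    letters = compact_letter_display(groups, props, sig)
    # omnibus: overall chi-square across all groups
    table = np.array([[eaten_by_group[g], total_by_group[g] - eaten_by_group[g]]
                      for g in groups])
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        chi2, p_omni, dof = 0.0, 1.0, len(groups) - 1
    else:
        chi2, p_omni, dof, _ = stats.chi2_contingency(table, correction=False)
    return TreatmentComparison("pairwise_proportions", float(chi2),
                               (float(dof), float("nan")), float(p_omni),
                               pw, letters, alpha)


# ---------------------------------------------------------------------------
# Plant-loss slopes, model selection, correlations
# ---------------------------------------------------------------------------

def first_week_loss_rate(counts: pd.DataFrame,
                         max_day: float = 7.0) -> pd.DataFrame:
    """Per-plot OLS slope (plants day^-1) of plant counts over the first
    week after planting.

    ``counts`` is a long table with columns ``plot_id``, ``treatment``,
    ``day``, ``count``. Returns one row per plot with its slope; feed the
    result to :func:`anova_tukey` grouped by treatment.
    """
    required = {"plot_id", "treatment", "day", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise KeyError(f"plant-count table lacks columns {sorted(missing)}")
    rows = []
    for (plot, treatment), sub in counts.groupby(["plot_id", "treatment"]):
        sub = sub[sub["day"] <= max_day]
        if len(sub) < 2:
            raise ValueError(f"plot {plot}: fewer than 2 observations in "
                             "the first week")
        x = sub["day"].to_numpy(dtype=float)
        y = sub["count"].to_numpy(dtype=float)
        xc = x - x.mean()
        slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
        rows.append({"plot_id": plot, "treatment": treatment, "slope": slope})
    return pd.DataFrame(rows)


def _aicc_ols(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float, float]:
    n = y.size
    coef = np.polynomial.polynomial.polyfit(x, y, degree)
    resid = y - np.polynomial.polynomial.polyval(x, coef)
    rss = float(np.dot(resid, resid))
    k = degree + 2  # mean parameters + error variance
    if rss <= 0:
        loglik = math.inf
        aic = -math.inf
    else:
        loglik = -n / 2 * (math.log(2 * math.pi * rss / n) + 1)
        aic = 2 * k - 2 * loglik
    if n - k - 1 <= 0:
        raise ValueError("too few points for AICc at this model order")
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return coef, aicc, r2


def fit_and_select(x, y) -> RegressionFit:
    """Fit linear and quadratic OLS and return the lower-AICc form,
    AICc = AIC + 2k(k+1)/(n-k-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    fits = {}
    for form, degree in (("linear", 1), ("quadratic", 2)):
        coef, aicc, r2 = _aicc_ols(x, y, degree)
        fits[form] = (coef, aicc, r2)
    best = min(fits, key=lambda f: fits[f][1])
    coef, aicc, r2 = fits[best]
    return RegressionFit(form=best, coef=coef, aicc=aicc, r2=r2, n=x.size,
                         candidates={f: v[1] for f, v in fits.items()})


def spearman_matrix(matrix: pd.DataFrame,
                    columns: list[str] | None = None) -> pd.DataFrame:
    """Spearman rank-correlation matrix among function columns."""
    if columns is None:
        columns = [c for c in matrix.columns
                   if pd.api.types.is_numeric_dtype(matrix[c])]
    sub = matrix[columns]
    rho = stats.spearmanr(sub.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return pd.DataFrame(rho, index=columns, columns=columns)
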