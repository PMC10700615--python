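"""Trophic-cascade effect sizes.

Log response ratios (LRR) with delta-method sampling variances,
DerSimonian-Laird random-effects pooling, monthly shorebird-exclusion
effects on crab abundance, inverse-variance meta-regression against bird
abundance, tethering predation intensity, and the historical back-projection
of crab density to the pre-collapse shorebird population.

For two arms with means X_P (control / predator present) and X_E
(exclusion), sample sizes N and standard deviations S:

    LRR = ln(X_P) - ln(X_E)
    Var = S_E^2 / (N_E X_E^2) + S_P^2 / (N_P X_P^2)

Negative LRR under this orientation means the excluded consumer suppresses
the response (e.g. crabs suppress plant biomass). The monthly
exclusion-effect on crabs uses the reverse orientation (exclusion in the
numerator), kept explicit in the effect metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSize",
    "PooledEffect",
    "ModeratorFit",
    "BackProjectionInputs",
    "predation_intensity",
    "intensity_wilcoxon",
    "lrr_effect",
    "pooled_random_effects",
    "exclusion_effect_on_crabs",
    "moderator_regression",
    "back_project_crabs",
]


@dataclass
class EffectSize:
    """A log response ratio with its sampling variance and provenance."""

    lrr: float
    var: float
    group: str = ""
    n_p: int = 0
    n_e: int = 0
    mean_p: float = float("nan")
    mean_e: float = float("nan")
    sd_p: float = float("nan")
    sd_e: float = float("nan")
    orientation: str = "control/exclusion"
    moderators: dict[str, float] = field(default_factory=dict)


@dataclass
class PooledEffect:
    """DerSimonian-Laird random-effects pooled estimate."""

    lrr: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q_stat: float
    k: int

    @property
    def significant(self) -> bool:
        """Significant when the 95% CI does not cross zero."""
        return self.ci_low > 0 or self.ci_high < 0


@dataclass
class ModeratorFit:
    """Inverse-variance meta-regression slope with Wald inference."""

    slope: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    intercept: float
    tau2: float
    k: int


@dataclass
class BackProjectionInputs:
    """Inputs for projecting crab density back to the historical shorebird
    population: present-day control/exclusion burrow densities, the
    proportional footprint change p between arms, and the shorebird counts
    in the reference and present years."""

    d_control: float
    d_exclusion: float
    p: float
    n_hist: float
    n_now: float

    def validate(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")
        if self.n_hist <= 0 or self.n_now <= 0:
            raise ValueError("shorebird counts must be positive")


# ---------------------------------------------------------------------------
# Tethering predation intensity
# ---------------------------------------------------------------------------

def predation_intensity(n_eaten: float, n_total: float) -> float:
    """Percent of tethered crabs eaten: M_p * 100 / M."""
    if n_total <= 0:
        raise ValueError("total number of tethered crabs must be positive")
    if not 0 <= n_eaten <= n_total:
        raise ValueError("eaten count must lie in [0, total]")
    return n_eaten * 100.0 / n_total


def intensity_wilcoxon(intensities) -> tuple[float, float]:
    """One-sample two-sided Wilcoxon signed-rank test of site-level
    predation intensities against zero. All-zero samples carry no evidence
    and return (0, 1)."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("no intensities supplied")
    if np.all(x == 0):
        return 0.0, 1.0
    stat, p = stats.wilcoxon(x, alternative="two-sided")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Log response ratios and pooling
# ---------------------------------------------------------------------------

def lrr_effect(x_p: float, s_p: float, n_p: int,
               x_e: float, s_e: float, n_e: int,
               group: str = "",
               orientation: str = "control/exclusion") -> EffectSize:
    """LRR = ln(X_P) - ln(X_E) with its delta-method variance."""
    if x_p <= 0 or x_e <= 0:
        raise ValueError("LRR requires positive group means")
    if s_p < 0 or s_e < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_p < 1 or n_e < 1:
        raise ValueError("sample sizes must be at least 1")
    lrr = math.log(x_p) - math.log(x_e)
    var = s_e**2 / (n_e * x_e**2) + s_p**2 / (n_p * x_p**2)
    return EffectSize(lrr=lrr, var=var, group=group, n_p=n_p, n_e=n_e,
                      mean_p=x_p, mean_e=x_e, sd_p=s_p, sd_e=s_e,
                      orientation=orientation)


def pooled_random_effects(effects: list[EffectSize]) -> PooledEffect:
    """DerSimonian-Laird random-effects pooling, weighted by the inverse of
    (sampling variance + tau^2)."""
    if not effects:
        raise ValueError("no effects to pool")
    y = np.array([e.lrr for e in effects])
    v = np.array([e.var for e in effects])
    k = y.size
    if k == 1:
        half = 1.959963984540054 * math.sqrt(v[0])
        return PooledEffect(lrr=float(y[0]), se=float(math.sqrt(v[0])),
                            ci_low=float(y[0] - half), ci_high=float(y[0] + half),
                            tau2=0.0, q_stat=0.0, k=1)
    if np.any(v <= 0):
        raise ValueError("pooling requires positive sampling variances")
    w = 1.0 / v
    y_fixed = np.sum(w * y) / np.sum(w)
    q_stat = float(np.sum(w * (y - y_fixed) ** 2))
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q_stat - (k - 1)) / c)
    w_re = 1.0 / (v + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    se = float(math.sqrt(1.0 / np.sum(w_re)))
    half = 1.959963984540054 * se
    return PooledEffect(lrr=mu, se=se, ci_low=mu - half, ci_high=mu + half,
                        tau2=float(tau2), q_stat=q_stat, k=k)


# ---------------------------------------------------------------------------
# Monthly exclusion effect on crab abundance
# ---------------------------------------------------------------------------

def exclusion_effect_on_crabs(burrows: pd.DataFrame,
                              exclusion: str = "planting_exclusion",
                              control: str = "planting_control",
                              shift: float = 1.0) -> list[EffectSize]:
    """Per-calendar-month LRR of crab abundance, exclusion over control.

    ``burrows`` is a long table with columns ``plot_id``, ``treatment``,
    ``year``, ``month``, ``burrows`` (monthly mean burrow density per plot).
    Counts are shifted by ``shift`` (x + 1 by default) to avoid
    non-positive means. Orientation is exclusion/control: positive values
    mean shorebird exclusion *increased* crabs.
    """
    required = {"plot_id", "treatment", "year", "month", "burrows"}
    missing = required - set(burrows.columns)
    if missing:
        raise KeyError(f"burrow table lacks columns {sorted(missing)}")
    out: list[EffectSize] = []
    for (year, month), sub in burrows.groupby(["year", "month"], sort=True):
        xe = sub.loc[sub["treatment"] == exclusion, "burrows"] + shift
        xc = sub.loc[sub["treatment"] == control, "burrows"] + shift
        if xe.empty or xc.empty:
            continue
        eff = lrr_effect(float(xe.mean()), float(xe.std(ddof=1)), len(xe),
                         float(xc.mean()), float(xc.std(ddof=1)), len(xc),
                         group=f"{int(year):04d}-{int(month):02d}",
                         orientation="exclusion/control")
        out.append(eff)
    if not out:
        raise ValueError("no months with both exclusion and control plots")
    return out


def moderator_regression(effects: list[EffectSize], moderator) -> ModeratorFit:
    """Meta-regression of effect sizes on a moderator.

    Weighted least squares with weights 1/(var + tau^2), where the residual
    between-month heterogeneity tau^2 is estimated by the method of moments
    from the first-stage inverse-variance fit. When every sampling variance
    is zero the fit reduces to ordinary least squares.
    """
    if len(effects) < 3:
        raise ValueError("meta-regression needs at least 3 effects")
    y = np.array([e.lrr for e in effects])
    v = np.array([e.var for e in effects])
    x = np.asarray(moderator, dtype=float)
    if x.size != y.size:
        raise ValueError("moderator length must match number of effects")
    if np.ptp(x) == 0:
        # degenerate moderator: no slope is identifiable; report 0 with
        # infinite uncertainty rather than a singular solve
        pooled = pooled_random_effects(effects)
        return ModeratorFit(slope=0.0, se=math.inf, ci_low=-math.inf,
                            ci_high=math.inf, p=1.0, intercept=pooled.lrr,
                            tau2=pooled.tau2, k=y.size)
    X = np.column_stack([np.ones_like(x), x])
    k, p = y.size, 2

    w1 = np.ones_like(v) if np.all(v == 0) else 1.0 / np.where(v > 0, v, np.min(v[v > 0]) * 1e-8)
    tau2 = _mm_residual_tau2(y, v, X, w1, k, p)
    w = 1.0 / (v + tau2) if np.any(v + tau2 > 0) else np.ones_like(v)
    xtwx = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    cov = np.linalg.inv(xtwx)
    se = math.sqrt(cov[1, 1])
    z = beta[1] / se if se > 0 else np.inf * np.sign(beta[1])
    pval = 2 * stats.norm.sf(abs(z))
    half = 1.959963984540054 * se
    return ModeratorFit(slope=float(beta[1]), se=float(se),
                        ci_low=float(beta[1] - half),
                        ci_high=float(beta[1] + half),
                        p=float(pval), intercept=float(beta[0]),
                        tau2=float(tau2), k=k)


def _mm_residual_tau2(y, v, X, w, k, p) -> float:
    """Method-of-moments residual heterogeneity for weighted meta-regression."""
    W = np.diag(w)
    xtwx_inv = np.linalg.inv(X.T @ W @ X)
    H = X @ xtwx_inv @ X.T @ W
    resid = y - H @ y
    qe = float(np.sum(w * resid**2))
    P = W - W @ X @ xtwx_inv @ X.T @ W
    trace_p = float(np.trace(P))
    if trace_p <= 0:
        return 0.0
    return max(0.0, (qe - (k - p)) / trace_p)


# ---------------------------------------------------------------------------
# Historical back-projection
# ---------------------------------------------------------------------------

def back_project_crabs(inputs: BackProjectionInputs) -> float:
    """Crab burrow density expected under the historical shorebird
    population:

        D_hist = D_C + [(D_C - D_E) / (p * N_now)] * (N_hist - N_now)

    assuming suppression proportional to shorebird abundance. A negative
    result indicates potential elimination of crab grazers at historical
    predator abundance.
    """
    inputs.validate()
    slope = (inputs.d_control - inputs.d_exclusion) / (inputs.p * inputs.n_now)
    return inputs.d_control + slope * (inputs.n_hist - inputs.n_now)
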