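"""Association models linking demography to climate-change vulnerability.

Three model families, matching the statistical layer of the analysis:

* ordinary least squares for continuous population parameters
  (e.g. mean stem length ~ mean CCVI), reported with the overall
  regression F on (1, n-2) df, R², and a Shapiro-Wilk check of the
  residuals;
* a binomial GLM (logit link) on aggregated young/adult counts for
  proportions (count weighting — equivalent to weighting each
  population's proportion by its census size), reported with the Wald Z
  of the slope and a McFadden-style pseudo-R² computed from deviances
  (1 - residual deviance / null deviance, i.e. the log-likelihood ratio
  referenced to the saturated model);
* an MM-type robust linear regression (S-estimate initialization,
  bisquare M-refinement at 95% Gaussian efficiency) for plant-level
  relations where gross outliers are expected.

Slopes carry 95% confidence intervals so that slopes of different
scenarios can be compared by interval overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

# bisquare tuning: 95% Gaussian efficiency for the M-step, 50% breakdown
# (consistency constant) for the S-scale
TUKEY_C_EFFICIENT = 4.685
TUKEY_C_SCALE = 1.54764


@dataclass
class RegressionResult:
    """Fitted association model in census-table form."""

    family: str                       # linear | binomial | robust_linear
    slope: float
    intercept: float
    statistic_name: str               # "F" or "Z"
    statistic: float
    p_value: float
    fit_measure_name: str             # "R2" or "McFadden R2"
    fit_measure: float
    n: int
    slope_ci: tuple[float, float]
    shapiro_w: float | None = None
    shapiro_p: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.slope_ci
        if not (lo <= self.slope <= hi) and np.isfinite(self.slope):
            raise ValueError("confidence interval must contain the point estimate")


def shapiro_wilk(residuals: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and two-sided p for the normality null (3 <= n <= 5000)."""
    x = np.asarray(residuals, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.std(x) == 0:
        raise ValueError("zero-variance residuals; Shapiro-Wilk undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with overall F-test and residual normality check."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)[1]
    resid = model.resid
    try:
        w, p_sw = shapiro_wilk(resid)
    except ValueError:
        w, p_sw = float("nan"), float("nan")
    return RegressionResult(
        family="linear",
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        statistic_name="F",
        statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        fit_measure_name="R2",
        fit_measure=float(model.rsquared),
        n=n,
        slope_ci=(float(ci[0]), float(ci[1])),
        shapiro_w=w,
        shapiro_p=p_sw,
    )


def binomial_fit(
    successes: Sequence[int],
    totals: Sequence[int],
    x: Sequence[float],
    weighted: bool = True,
) -> RegressionResult:
    """Logit-link binomial GLM of a proportion on x.

    ``weighted=True`` (default) fits the aggregated (successes,
    failures) counts, so large populations carry proportionally more
    information; ``weighted=False`` fits the raw proportions as if each
    population were a single Bernoulli-scale observation (offered for
    comparison, but proportions from censuses of very different sizes are
    not equally precise).

    The pseudo-R² is 1 - residual deviance / null deviance: McFadden's
    likelihood-ratio measure with both likelihoods referenced to the
    saturated model, the natural form for grouped binomial data.
    """
    successes = np.asarray(successes, dtype=float)
    totals = np.asarray(totals, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 populations")
    if np.any(successes < 0) or np.any(successes > totals):
        raise ValueError("need 0 <= successes <= totals")
    if successes.sum() == 0 or (totals - successes).sum() == 0:
        raise ValueError("degenerate likelihood: all-success or all-failure data")
    X = sm.add_constant(x)
    if weighted:
        endog = np.column_stack([successes, totals - successes])
        model = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        null = sm.GLM(endog, np.ones((n, 1)), family=sm.families.Binomial()).fit()
    else:
        prop = successes / totals
        model = sm.GLM(prop, X, family=sm.families.Binomial()).fit()
        null = sm.GLM(prop, np.ones((n, 1)), family=sm.families.Binomial()).fit()
    mcfadden = 1.0 - model.deviance / null.deviance
    ci = model.conf_int(alpha=0.05)[1]
    return RegressionResult(
        family="binomial",
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        statistic_name="Z",
        statistic=float(model.tvalues[1]),
        p_value=float(model.pvalues[1]),
        fit_measure_name="McFadden R2",
        fit_measure=float(mcfadden),
        n=n,
        slope_ci=(float(ci[0]), float(ci[1])),
    )


# ---------------------------------------------------------------------------
# MM-type robust regression
# ---------------------------------------------------------------------------


def _bisquare_rho(u: np.ndarray, c: float) -> np.ndarray:
    """Tukey bisquare rho, normalized so rho(inf) = 1."""
    v = np.clip(u / c, -1, 1)
    return 1.0 - (1.0 - v**2) ** 3


def _bisquare_weight(u: np.ndarray, c: float) -> np.ndarray:
    w = np.zeros_like(u)
    inside = np.abs(u) < c
    w[inside] = (1.0 - (u[inside] / c) ** 2) ** 2
    return w


def _m_scale(resid: np.ndarray, c: float = TUKEY_C_SCALE, b: float = 0.5) -> float:
    """M-estimate of scale: mean rho(r/s) = b, solved by fixed point."""
    s = np.median(np.abs(resid)) / 0.6745
    if s == 0:
        s = np.mean(np.abs(resid)) or 1e-12
    for _ in range(100):
        m = np.mean(_bisquare_rho(resid / s, c))
        s_new = s * np.sqrt(m / b)
        if abs(s_new - s) < 1e-12 * s:
            return s_new
        s = s_new
    return s


def robust_linear_fit(
    x: Sequence[float],
    y: Sequence[float],
    n_subsets: int = 500,
    max_iter: int = 100,
    tol: float = 1e-10,
    seed: int = 0,
) -> RegressionResult:
    """MM-type robust simple regression (S-init, bisquare M-refinement).

    The S-estimate is found by elemental-set resampling: lines through
    random point pairs, scored by the 50%-breakdown bisquare M-scale of
    their residuals.  The best candidate's scale is held fixed while the
    coefficients are refined by IRLS with the 95%-efficiency bisquare
    (c = 4.685).  The slope test is a robust Wald test reported as
    F = (slope/se)² on (1, n-2) df, with the standard M-estimator
    asymptotic covariance; the robust R² is a bisquare-weighted R².
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations for a robust fit")
    rng = np.random.default_rng(seed)
    A = np.column_stack([np.ones(n), x])

    # --- S-estimate by elemental sets ---
    best_beta, best_scale = None, np.inf
    for _ in range(n_subsets):
        i, j = rng.choice(n, size=2, replace=False)
        if x[i] == x[j]:
            continue
        slope = (y[j] - y[i]) / (x[j] - x[i])
        beta = np.array([y[i] - slope * x[i], slope])
        s = _m_scale(y - A @ beta)
        if s < best_scale:
            best_beta, best_scale = beta, s
    if best_beta is None:
        raise ValueError("x has (near) zero variance; robust fit undefined")

    # --- M-refinement with fixed scale ---
    beta = best_beta
    scale = best_scale if best_scale > 0 else 1e-12
    converged = False
    for _ in range(max_iter):
        r = (y - A @ beta) / scale
        w = _bisquare_weight(r, TUKEY_C_EFFICIENT)
        if w.sum() == 0:
            break
        WA = A * w[:, None]
        try:
            beta_new = np.linalg.solve(A.T @ WA, WA.T @ y)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new

    # --- robust Wald inference ---
    r = (y - A @ beta) / scale
    psi = _bisquare_weight(r, TUKEY_C_EFFICIENT) * r          # psi(u) = u w(u)
    c = TUKEY_C_EFFICIENT
    inside = np.abs(r) < c
    psi_prime = np.zeros_like(r)
    u = r[inside]
    psi_prime[inside] = (1 - (u / c) ** 2) * (1 - 5 * (u / c) ** 2)
    kappa = np.mean(psi**2) / max(np.mean(psi_prime) ** 2, 1e-12)
    cov = scale**2 * kappa * np.linalg.inv(A.T @ A) * n / max(n - 2, 1)
    se_slope = float(np.sqrt(cov[1, 1]))
    f_stat = (beta[1] / se_slope) ** 2 if se_slope > 0 else np.inf
    p = float(stats.f.sf(f_stat, 1, n - 2))
    t_crit = stats.t.ppf(0.975, n - 2)
    ci = (float(beta[1] - t_crit * se_slope), float(beta[1] + t_crit * se_slope))

    w_final = _bisquare_weight(r, TUKEY_C_EFFICIENT)
    ybar_w = np.average(y, weights=w_final) if w_final.sum() > 0 else y.mean()
    resid = y - A @ beta
    denom = np.sum(w_final * (y - ybar_w) ** 2)
    r2 = 1.0 - np.sum(w_final * resid**2) / denom if denom > 0 else float("nan")

    return RegressionResult(
        family="robust_linear",
        slope=float(beta[1]),
        intercept=float(beta[0]),
        statistic_name="F",
        statistic=float(f_stat),
        p_value=p,
        fit_measure_name="R2",
        fit_measure=float(r2),
        n=n,
        slope_ci=ci,
        converged=converged,
    )


@dataclass
class SlopeComparison:
    """Verdict of a 95%-CI comparison between two fitted slopes."""

    disjoint: bool
    order: str  # "a<b", "a>b", or "overlap"


def slope_ci_compare(a: RegressionResult, b: RegressionResult) -> SlopeComparison:
    """Compare two slopes by 95% confidence-interval overlap.

    Intervals are closed: touching endpoints count as overlapping.
    """
    lo_a, hi_a = a.slope_ci
    lo_b, hi_b = b.slope_ci
    for v in (lo_a, hi_a, lo_b, hi_b):
        if not np.isfinite(v):
            raise ValueError("both results must carry finite confidence intervals")
    if hi_a < lo_b:
        return SlopeComparison(disjoint=True, order="a<b")
    if hi_b < lo_a:
        return SlopeComparison(disjoint=True, order="a>b")
    return SlopeComparison(disjoint=False, order="overlap")
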