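"""Two-sample MR estimators and report transformations.

Implements the Wald ratio, the inverse-variance-weighted (IVW) estimator
with multiplicative random effects, the weighted-median estimator with a
parametric bootstrap SE, and MR-Egger regression, plus the odds-ratio /
confidence-interval / p-value transformations used in reports, a joint
significance rule (IVW p below alpha and all three methods agreeing in
sign), and Bonferroni adjustment.

Conventions
-----------
* IVW is weighted regression of SNP-outcome effects on SNP-exposure effects
  through the origin with weights 1/se_out^2.  The reported SE is the
  fixed-effect SE inflated by max(1, sigma_hat) where sigma_hat^2 is the
  weighted residual mean square on n-1 df — random effects never tighten
  below the fixed-effect model.
* MR-Egger adds an intercept (the average directional pleiotropy), orients
  SNPs to nonnegative exposure effects first, and tests both coefficients
  against t with n-2 df.
* Confidence intervals are normal (z) based on all methods; only the
  MR-Egger p-values use the t distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gwas import HarmonizedSet

__all__ = [
    "MREstimate",
    "MethodPanel",
    "bonferroni_adjust",
    "estimate_from_summary",
    "ivw",
    "mr_egger",
    "significance_rule",
    "to_odds_ratio",
    "wald_ratio",
    "weighted_median",
]


@dataclass
class MREstimate:
    """One causal-effect estimate (log-odds scale for binary outcomes)."""

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    ci_level: float = 0.95

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("se must be positive")

    @property
    def _z(self) -> float:
        return stats.norm.ppf(1.0 - (1.0 - self.ci_level) / 2.0)

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - self._z * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + self._z * self.se)


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float,
               se_out: float) -> MREstimate:
    """Single-SNP causal estimate: beta_out/beta_exp with first-order SE."""
    if beta_exp == 0:
        raise ValueError("undefined ratio: beta_exp is zero")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate("wald", 1, beta, se, _normal_p(beta, se))


def _arrays(h: HarmonizedSet):
    r = h.rows
    return (r["beta_exp"].to_numpy(float), r["se_exp"].to_numpy(float),
            r["beta_out"].to_numpy(float), r["se_out"].to_numpy(float))


def ivw(h: HarmonizedSet) -> MREstimate:
    """Inverse-variance-weighted estimate (multiplicative random effects).

    With a single instrument this reduces to the Wald ratio.
    """
    bx, sx, by, sy = _arrays(h)
    n = len(bx)
    if n == 0:
        raise ValueError("empty harmonized set")
    if n == 1:
        return wald_ratio(bx[0], sx[0], by[0], sy[0])
    if np.all(bx == 0):
        raise ValueError("no instrument signal: all exposure betas are zero")
    w = 1.0 / sy**2
    s_xx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / s_xx
    se_fixed = s_xx ** -0.5
    resid = by - beta * bx
    sigma2 = float(np.sum(w * resid**2)) / (n - 1)
    se = se_fixed * max(1.0, math.sqrt(sigma2))
    return MREstimate("ivw", n, beta, se, _normal_p(beta, se))


def ivw_fixed_beta(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    """Fixed-effect IVW point estimate on raw arrays (internal helper)."""
    w = 1.0 / sy**2
    return float(np.sum(w * bx * by) / np.sum(w * bx * bx))


def _interp_weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b, kind="stable")
    b, w = b[order], w[order]
    p = w / w.sum()
    s = np.cumsum(p) - p / 2.0
    return float(np.interp(0.5, s, b))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median estimator over per-SNP Wald ratios.

    Ratios are weighted by beta_exp^2/se_out^2 (the inverse first-order
    variance of the ratio); the estimate interpolates the weighted CDF of
    sorted ratios at 0.5, so it is consistent when at least half the weight
    comes from valid instruments.  The SE comes from a seeded parametric
    bootstrap resampling the per-SNP effects from their normal sampling
    distributions.
    """
    bx, sx, by, sy = _arrays(h)
    usable = bx != 0
    if not usable.all():
        warnings.warn("excluding SNP(s) with zero exposure beta from weighted median")
        bx, sx, by, sy = bx[usable], sx[usable], by[usable], sy[usable]
    n = len(bx)
    if n < 3:
        raise ValueError("weighted median requires >= 3 usable instruments")
    ratios = by / bx
    w = bx**2 / sy**2
    beta = _interp_weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_boot, n))
    by_s = rng.normal(by, sy, size=(n_boot, n))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _interp_weighted_median(by_s[i] / bx_s[i],
                                           bx_s[i]**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", n, beta, se, _normal_p(beta, se))


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, df_resid: int):
    """Weighted least squares via normal equations.

    Returns (coef, se_unscaled, sigma_hat) where sigma_hat^2 is the weighted
    residual mean square on ``df_resid`` degrees of freedom.
    """
    XtW = X.T * w
    xtwx = XtW @ X
    coef = np.linalg.solve(xtwx, XtW @ y)
    cov_unscaled = np.linalg.inv(xtwx)
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / df_resid if df_resid > 0 else 0.0
    return coef, np.sqrt(np.diag(cov_unscaled)), math.sqrt(sigma2)


def mr_egger(h: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression; returns (slope, intercept) estimates.

    The slope is a pleiotropy-adjusted causal estimate; the intercept
    estimates the average directional pleiotropic effect and its test is the
    Egger intercept test.  Both p-values are two-sided t with n-2 df.
    """
    bx, sx, by, sy = _arrays(h)
    n = len(bx)
    if n < 3:
        raise ValueError("MR-Egger underdetermined: need >= 3 instruments")
    flip = bx < 0
    bx = np.where(flip, -bx, bx)
    by = np.where(flip, -by, by)
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), bx])
    coef, se_u, sigma = _wls(X, by, w, n - 2)
    scale = max(1.0, sigma)
    df = n - 2

    def t_p(b, s):
        return float(2.0 * stats.t.sf(abs(b) / s, df)) if s > 0 else 1.0

    intercept = MREstimate("mr_egger_intercept", n, float(coef[0]),
                           float(se_u[0] * scale), t_p(coef[0], se_u[0] * scale))
    slope = MREstimate("mr_egger_slope", n, float(coef[1]),
                       float(se_u[1] * scale), t_p(coef[1], se_u[1] * scale))
    return slope, intercept


def estimate_from_summary(method: str, n_snp: int, beta: float, se: float,
                          ci_level: float = 0.95) -> MREstimate:
    """Rebuild an estimate from a reported (beta, SE, N-SNP) triple.

    Applies the method's inference convention — t with n_snp-2 df for
    MR-Egger coefficients, standard normal otherwise — so published
    per-method summary rows can be turned back into OR / CI / p columns.
    """
    if method in ("mr_egger", "mr_egger_slope", "mr_egger_intercept"):
        pval = float(2.0 * stats.t.sf(abs(beta) / se, n_snp - 2))
    else:
        pval = _normal_p(beta, se)
    return MREstimate(method, n_snp, beta, se, pval, ci_level)


def to_odds_ratio(beta: float, se: float, ci_level: float = 0.95):
    """Report transformation: (OR, CI low, CI high, normal two-sided p)."""
    if se <= 0:
        raise ValueError("se must be positive")
    if not (0.0 < ci_level < 1.0):
        raise ValueError("ci_level must be in (0, 1)")
    z = stats.norm.ppf(1.0 - (1.0 - ci_level) / 2.0)
    return (math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se),
            _normal_p(beta, se))


@dataclass
class MethodPanel:
    """All estimates for one exposure-outcome pair plus the verdict."""

    exposure_name: str
    outcome_name: str
    estimates: dict = field(default_factory=dict)  # method -> MREstimate
    significant: bool | None = None
    bonferroni_p: float | None = None

    def __getitem__(self, method: str) -> MREstimate:
        return self.estimates[method]


def significance_rule(panel: MethodPanel, alpha: float = 0.05) -> bool:
    """IVW p below alpha AND all three methods agreeing in effect direction.

    A zero beta in any method counts as a direction mismatch.
    """
    try:
        est_ivw = panel["ivw"]
        est_wm = panel["weighted_median"]
        est_egger = panel["mr_egger_slope"]
    except KeyError as exc:
        raise ValueError(f"panel missing method {exc}") from exc
    signs = {np.sign(est.beta) for est in (est_ivw, est_wm, est_egger)}
    return est_ivw.pval < alpha and len(signs) == 1 and 0.0 not in signs


def bonferroni_adjust(pvals, m: int):
    """Multiply p-values by the number of comparisons, capped at 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    arr = np.minimum(1.0, np.asarray(pvals, dtype=float) * m)
    return arr
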