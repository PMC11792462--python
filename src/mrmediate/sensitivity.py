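"""Sensitivity battery: heterogeneity, pleiotropy, outliers, influence.

Mirrors the standard two-sample MR diagnostics: Cochran's Q over per-SNP
Wald ratios, the MR-Egger intercept test for directional pleiotropy,
MR-PRESSO (residual sum of squares with a simulated null) for pleiotropic
outliers, and leave-one-out IVW for influential instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, ivw, mr_egger
from .gwas import HarmonizedSet

__all__ = [
    "HeterogeneityResult",
    "LooResult",
    "PressoResult",
    "SensitivityReport",
    "cochran_q",
    "egger_intercept_test",
    "exclude_multitrait_snps",
    "leave_one_out",
    "mr_presso",
    "run_sensitivity",
]


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    pval: float
    per_snp: pd.Series  # per-SNP contribution to Q

    @property
    def heterogeneous(self) -> bool:
        return self.pval < 0.05


def cochran_q(h: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q over per-SNP ratios with inverse-variance ratio weights.

    Weights are beta_exp^2/se_out^2, so the weighted mean is the fixed-effect
    IVW estimate and Q is chi-square with n-1 df under homogeneity.
    """
    r = h.rows
    n = len(r)
    if n < 2:
        raise ValueError("Cochran's Q requires >= 2 instruments")
    bx = r["beta_exp"].to_numpy(float)
    by = r["beta_out"].to_numpy(float)
    sy = r["se_out"].to_numpy(float)
    if np.any(bx == 0):
        raise ValueError("zero exposure beta: ratio undefined")
    b = by / bx
    w = bx**2 / sy**2
    b_fixed = float(np.sum(w * b) / np.sum(w))
    contrib = w * (b - b_fixed) ** 2
    q = float(np.sum(contrib))
    pval = float(stats.chi2.sf(q, n - 1))
    return HeterogeneityResult(q, n - 1, max(pval, np.finfo(float).tiny),
                               pd.Series(contrib, index=r["snp_id"].to_numpy()))


def egger_intercept_test(h: HarmonizedSet) -> MREstimate:
    """MR-Egger intercept estimate; p > 0.05 means no detected horizontal
    pleiotropy.  Shares the code path of the Egger fit exactly."""
    return mr_egger(h)[1]


@dataclass
class PressoResult:
    rss_observed: float
    global_pval: float
    per_snp_pvals: dict  # snp_id -> Bonferroni-adjusted outlier p
    outliers: set
    corrected_estimate: MREstimate | None = None


def _loo_fixed_betas(bx, by, w):
    """Leave-one-out fixed-effect IVW estimates, vectorized.

    Works on 1-D arrays or 2-D (n_sim, n_snp) matrices; ``w`` is 1-D.
    """
    s1 = np.sum(w * bx * by, axis=-1, keepdims=True)
    s2 = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (s1 - w * bx * by) / (s2 - w * bx * bx)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> PressoResult:
    """MR-PRESSO global and outlier tests.

    The observed statistic is the weighted residual sum of squares where
    each SNP's prediction uses the fixed-effect IVW slope fitted without
    that SNP.  The null distribution comes from ``n_sim`` parametric
    simulations drawing per-SNP effects from their sampling distributions
    around the leave-one-out fit; empirical p-values use add-one smoothing.
    Per-SNP outlier p-values are Bonferroni-adjusted by the number of
    instruments; when outliers are found the IVW estimate is recomputed
    without them.
    """
    r = h.rows
    n = len(r)
    if n < 4:
        raise ValueError("too few instruments for PRESSO (need >= 4)")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    bx = r["beta_exp"].to_numpy(float)
    sx = r["se_exp"].to_numpy(float)
    by = r["beta_out"].to_numpy(float)
    sy = r["se_out"].to_numpy(float)
    w = 1.0 / sy**2

    b_loo = _loo_fixed_betas(bx, by, w).reshape(-1)
    obs_sq = w * (by - b_loo * bx) ** 2
    rss_obs = float(np.sum(obs_sq))

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, n))
    by_s = rng.normal(b_loo * bx, sy, size=(n_sim, n))
    b_loo_s = _loo_fixed_betas(bx_s, by_s, w)
    sim_sq = w * (by_s - b_loo_s * bx_s) ** 2
    rss_sim = sim_sq.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    raw = (1 + np.sum(sim_sq >= obs_sq, axis=0)) / (n_sim + 1)
    adj = np.minimum(1.0, raw * n)
    snp_ids = r["snp_id"].to_numpy()
    per_snp = dict(zip(snp_ids, adj))
    outliers = {s for s, p in per_snp.items() if p < outlier_alpha}

    corrected = None
    if outliers:
        keep = h.subset(set(snp_ids) - outliers)
        if keep.n_snp >= 1:
            corrected = ivw(keep)
    return PressoResult(rss_obs, global_p, per_snp, outliers, corrected)


@dataclass
class LooResult:
    rows: pd.DataFrame  # snp_id, beta_without, se_without, pval_without
    flagged: set
    full_estimate: MREstimate | None = None


def leave_one_out(h: HarmonizedSet, alpha: float = 0.05) -> LooResult:
    """IVW re-estimated with each SNP removed in turn.

    A SNP is flagged as influential if removing it loses IVW significance at
    ``alpha`` or flips the sign of the estimate relative to the all-SNP fit.
    """
    n = h.n_snp
    if n < 3:
        raise ValueError("leave-one-out requires >= 3 instruments")
    full = ivw(h)
    records = []
    flagged = set()
    for snp in h.rows["snp_id"]:
        est = ivw(h.drop(snp))
        records.append((snp, est.beta, est.se, est.pval))
        if est.pval >= alpha or np.sign(est.beta) != np.sign(full.beta):
            flagged.add(snp)
    rows = pd.DataFrame(records, columns=["snp_id", "beta_without",
                                          "se_without", "pval_without"])
    return LooResult(rows, flagged, full)


def exclude_multitrait_snps(h: HarmonizedSet, other_traits,
                            p_threshold: float = 1e-5):
    """Drop instruments associated with any other trait at ``p_threshold``.

    Guards the exclusion restriction when several exposures are analysed
    jointly (for example a microbe and a metabolite): an instrument for one
    trait that is also genome-wide associated with another acts through
    more than one pathway and is removed.  Returns the filtered set and the
    list of removed rsIDs.
    """
    removed = set()
    for table in other_traits:
        pmap = dict(zip(table.df["snp_id"], table.df["pval"]))
        for snp in h.rows["snp_id"]:
            if pmap.get(snp, 1.0) < p_threshold:
                removed.add(snp)
    kept = h.subset(set(h.rows["snp_id"]) - removed)
    return kept, sorted(removed)


@dataclass
class SensitivityReport:
    """The full battery for one exposure-outcome pair (fields None when the
    instrument count is below a method's minimum)."""

    heterogeneity: HeterogeneityResult | None = None
    egger_intercept: MREstimate | None = None
    presso: PressoResult | None = None
    loo: LooResult | None = None
    notes: list = field(default_factory=list)


def run_sensitivity(h: HarmonizedSet, seed: int = 0,
                    n_sim: int = 1000, alpha: float = 0.05) -> SensitivityReport:
    """Run every diagnostic the instrument count permits."""
    rep = SensitivityReport()
    n = h.n_snp
    if n >= 2:
        rep.heterogeneity = cochran_q(h)
    else:
        rep.notes.append("heterogeneity skipped: <2 instruments")
    if n >= 3:
        rep.egger_intercept = egger_intercept_test(h)
        rep.loo = leave_one_out(h, alpha=alpha)
    else:
        rep.notes.append("Egger intercept / leave-one-out skipped: <3 instruments")
    if n >= 4:
        rep.presso = mr_presso(h, n_sim=n_sim, seed=seed)
    else:
        rep.notes.append("MR-PRESSO skipped: <4 instruments")
    return rep
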