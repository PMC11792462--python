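"""Mediation of an exposure-outcome effect through one mediator.

Two complementary strategies:

* Two-step (network) MR: estimate the exposure->mediator effect (alpha) and
  the mediator->outcome effect (beta2) by univariable MR; the indirect
  effect is alpha*beta2 and the mediated proportion is indirect/total.
* Multivariable MR (MVMR): regress SNP-outcome effects jointly on the SNP
  effects for exposure and mediator; the exposure coefficient is the direct
  effect beta1, so the indirect effect is total - beta1.

A mediator whose indirect effect shares the total effect's direction is a
mediator proper; one whose indirect effect opposes it is a suppressor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import MREstimate, ivw, _wls, _normal_p
from .gwas import GwasTable, LdInfo, clump, harmonize
from .iv import IvSet, SelectionConfig, select_ivs

__all__ = [
    "MediationResult",
    "MvmrFit",
    "classify_effect",
    "mediation_summary",
    "mvmr_fit",
    "two_step_effects",
]


def classify_effect(indirect: float, total: float) -> str:
    """'mediation' if indirect and total agree in (nonzero) sign,
    'suppression' if they oppose, 'none' if the indirect effect is zero."""
    if indirect == 0 or total == 0:
        return "none"
    return "mediation" if np.sign(indirect) == np.sign(total) else "suppression"


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    alpha: float = float("nan")          # exposure -> mediator
    beta2: float = float("nan")          # mediator -> outcome
    total: float = float("nan")          # exposure -> outcome (beta)
    indirect_two_step: float = float("nan")   # alpha * beta2
    indirect_se: float = float("nan")
    indirect_pval: float = float("nan")
    direct_mvmr: float = float("nan")    # beta1
    indirect_mvmr: float = float("nan")  # beta - beta1
    proportion_two_step: float = float("nan")
    proportion_mvmr: float = float("nan")
    proportion_se: float = float("nan")
    proportion_pval: float = float("nan")
    label: str = "none"
    skipped: bool = False
    reason: str = ""
    details: dict = field(default_factory=dict)


def two_step_effects(alpha: MREstimate, beta2: MREstimate,
                     total: MREstimate,
                     exposure: str = "exposure", mediator: str = "mediator",
                     outcome: str = "outcome") -> MediationResult:
    """Combine the three univariable estimates into a two-step result.

    The indirect-effect SE uses the delta method for a product,
    sqrt(alpha^2 se_beta2^2 + beta2^2 se_alpha^2); the mediated-proportion
    SE treats the total effect as fixed.
    """
    if total.beta == 0:
        raise ValueError("total effect is zero: mediated proportion undefined")
    indirect = alpha.beta * beta2.beta
    ind_se = math.sqrt(alpha.beta**2 * beta2.se**2 + beta2.beta**2 * alpha.se**2)
    ind_p = _normal_p(indirect, ind_se) if ind_se > 0 else 1.0
    prop = indirect / total.beta
    prop_se = ind_se / abs(total.beta)
    prop_p = _normal_p(prop, prop_se) if prop_se > 0 else 1.0
    return MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        alpha=alpha.beta, beta2=beta2.beta, total=total.beta,
        indirect_two_step=indirect, indirect_se=ind_se, indirect_pval=ind_p,
        proportion_two_step=prop, proportion_se=prop_se, proportion_pval=prop_p,
        label=classify_effect(indirect, total.beta),
    )


@dataclass
class MvmrFit:
    """Joint (exposure + mediator) instrument regression on the outcome."""

    coefficients: dict  # name -> MREstimate (method 'mvmr_direct')
    n_snp: int

    def __getitem__(self, name: str) -> MREstimate:
        return self.coefficients[name]


def mvmr_fit(bx_matrix: np.ndarray, beta_out: np.ndarray,
             se_out: np.ndarray, names) -> MvmrFit:
    """Weighted multivariable regression of outcome effects on exposure
    effect columns, no intercept, weights 1/se_out^2.

    SEs are inflated by max(1, sigma_hat) with sigma_hat^2 on n-2 df;
    p-values are normal two-sided.
    """
    X = np.asarray(bx_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    n, k = X.shape
    names = list(names)
    if len(names) != k:
        raise ValueError("one name per exposure column required")
    if n < k + 1:
        raise ValueError("need more instruments than exposures")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("collinear instruments: design matrix rank deficient")
    w = 1.0 / sy**2
    coef, se_u, sigma = _wls(X, y, w, n - 2)
    scale = max(1.0, sigma)
    coefficients = {
        name: MREstimate("mvmr_direct", n, float(b), float(s * scale),
                         _normal_p(float(b), float(s * scale)))
        for name, b, s in zip(names, coef, se_u)
    }
    return MvmrFit(coefficients, n)


def _estimate(h) -> MREstimate:
    return ivw(h)  # delegates to Wald when a single instrument remains


def mediation_summary(exposure: GwasTable, mediator: GwasTable,
                      outcome: GwasTable, ld: LdInfo,
                      cfg: SelectionConfig,
                      multitrait_removal: bool = True) -> MediationResult:
    """Full mediation analysis for one exposure-mediator-outcome triple.

    Runs three univariable MRs (exposure->mediator, mediator->outcome,
    exposure->outcome) with the same instrument-selection rules, then an
    MVMR on the union of the exposure's and mediator's instruments,
    re-clumped at the same threshold.  By default the mediator's
    instruments additionally drop SNPs associated with the exposure
    (multi-trait removal): an exposure-associated SNP used to instrument
    the mediator carries the exposure's direct effect and biases the
    mediator->outcome step.  Any stage with no surviving instruments
    yields a structured skip.
    """
    from dataclasses import replace

    from .sensitivity import exclude_multitrait_snps

    names = (exposure.trait_name, mediator.trait_name, outcome.trait_name)

    # step 1 targets a trait hypothesised to be *downstream* of the exposure,
    # so the no-association-with-outcome criterion does not apply there
    step1_cfg = replace(cfg, outcome_p_threshold=None)
    stages = {}
    for key, (exp_t, out_t, stage_cfg) in {
        "exposure_mediator": (exposure, mediator, step1_cfg),
        "mediator_outcome": (mediator, outcome, cfg),
        "exposure_outcome": (exposure, outcome, cfg),
    }.items():
        ivs, h = select_ivs(exp_t, out_t, ld, stage_cfg)
        if key == "mediator_outcome" and multitrait_removal and not ivs.no_iv:
            h, removed = exclude_multitrait_snps(
                h, [exposure], cfg.exposure_p_threshold)
            ivs = IvSet(ivs.exposure_name, tuple(h.rows["snp_id"]),
                        ivs.selection_log
                        + [("multitrait_removal", len(removed), h.n_snp)])
        if ivs.no_iv:
            return MediationResult(*names, skipped=True,
                                   reason=f"no instruments for {key}")
        stages[key] = (ivs, h)

    alpha = _estimate(stages["exposure_mediator"][1])
    beta2 = _estimate(stages["mediator_outcome"][1])
    total = _estimate(stages["exposure_outcome"][1])
    if total.beta == 0:
        return MediationResult(*names, skipped=True, reason="zero total effect")
    result = two_step_effects(alpha, beta2, total, *names)

    # MVMR on the de-duplicated, re-clumped union of instruments
    union = sorted(set(stages["exposure_outcome"][0].snp_ids)
                   | set(stages["mediator_outcome"][0].snp_ids))
    pool_rows = []
    med_p = dict(zip(mediator.df["snp_id"], mediator.df["pval"]))
    for rec in exposure.df[exposure.df["snp_id"].isin(union)].itertuples(index=False):
        pool_rows.append((rec.snp_id, rec.chrom, rec.pos, rec.effect_allele,
                          rec.other_allele, rec.eaf, rec.beta, rec.se,
                          min(rec.pval, med_p.get(rec.snp_id, 1.0)), rec.n))
    pool = GwasTable(exposure.trait_name, exposure.trait_type,
                     pd.DataFrame(pool_rows, columns=exposure.df.columns.tolist()))
    pool = clump(pool, ld, cfg.clump_r2, cfg.clump_window_kb)

    h_eo = harmonize(pool, outcome, cfg.palindrome_freq_window, cfg.harmonize_action)
    h_em = harmonize(pool, mediator, cfg.palindrome_freq_window, cfg.harmonize_action)
    joint = h_eo.rows.merge(
        h_em.rows[["snp_id", "beta_out", "se_out"]].rename(
            columns={"beta_out": "beta_med", "se_out": "se_med"}),
        on="snp_id")
    if len(joint) < 3:
        result.details["mvmr"] = "skipped: <3 joint instruments"
        return result

    fit = mvmr_fit(joint[["beta_exp", "beta_med"]].to_numpy(),
                   joint["beta_out"].to_numpy(), joint["se_out"].to_numpy(),
                   names=[exposure.trait_name, mediator.trait_name])
    beta1 = fit[exposure.trait_name]
    result.direct_mvmr = beta1.beta
    result.indirect_mvmr = total.beta - beta1.beta
    result.proportion_mvmr = result.indirect_mvmr / total.beta
    result.details["mvmr_n_snp"] = fit.n_snp
    result.details["mvmr_mediator_coef"] = fit[mediator.trait_name].beta
    return result
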