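"""Calibration and recovery experiments on synthetic data.

Desk-scale simulation studies that characterise the estimators under known
truth: type-I error and coverage of IVW, MR-PRESSO outlier power and
global-test size, MR-Egger intercept power under directional pleiotropy,
and recovery of mediated proportions by two-step MR and MVMR.  Each
function is fully seeded and returns plain numbers, so the analysis
drivers, the test suite, and the acceptance script all share one
implementation of the experimental protocol.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .estimators import ivw, mr_egger
from .gwas import HarmonizedSet, harmonize
from .iv import SelectionConfig
from .mediation import mediation_summary
from .sensitivity import mr_presso
from .simulate import SimConfig, simulate_mediation_dataset, simulate_summary_dataset

__all__ = [
    "egger_intercept_power",
    "ivw_recovery",
    "ivw_type1_error",
    "mediation_recovery",
    "presso_null_size",
    "presso_outlier_power",
]


def _rep_seeds(seed: int, n: int, stream: int) -> np.ndarray:
    """Deterministic per-replicate seeds derived from one root seed."""
    return np.random.SeedSequence([int(seed), stream]).generate_state(n) % (2**31)


def ivw_type1_error(n_rep: int = 1000, n_snp: int = 30, alpha: float = 0.05,
                    seed: int = 0) -> float:
    """Rejection rate of the IVW test under a true null, no pleiotropy."""
    rejections = 0
    for s in _rep_seeds(seed, n_rep, stream=1):
        ds = simulate_summary_dataset(SimConfig(n_snp=n_snp, causal_total=0.0,
                                                seed=int(s)))
        rejections += ivw(harmonize(ds.exposure, ds.outcome)).pval < alpha
    return rejections / n_rep


def ivw_recovery(n_rep: int = 500, true_beta: float = 0.3, n_snp: int = 30,
                 n_exposure: int = 20_000, seed: int = 0):
    """(mean estimate, bias, CI coverage) for IVW at a true causal effect."""
    estimates, covered = [], 0
    target_or = math.exp(true_beta)
    for s in _rep_seeds(seed, n_rep, stream=2):
        ds = simulate_summary_dataset(SimConfig(
            n_snp=n_snp, causal_total=true_beta, n_exposure=n_exposure,
            seed=int(s)))
        est = ivw(harmonize(ds.exposure, ds.outcome))
        estimates.append(est.beta)
        covered += est.ci_low <= target_or <= est.ci_high
    mean_est = float(np.mean(estimates))
    return mean_est, mean_est - true_beta, covered / n_rep


def _shift_outlier(h: HarmonizedSet, index: int, n_se: float) -> HarmonizedSet:
    rows = h.rows.copy()
    rows.loc[rows.index[index], "beta_out"] += n_se * rows.loc[rows.index[index],
                                                              "se_out"]
    return HarmonizedSet(h.exposure_name, h.outcome_name, rows)


def presso_outlier_power(n_rep: int = 100, n_snp: int = 20,
                         shift_se: float = 10.0, seed: int = 0) -> float:
    """Fraction of replicates in which a planted outlier (outcome effect
    shifted by ``shift_se`` SEs) is flagged by MR-PRESSO."""
    hits = 0
    for i, s in enumerate(_rep_seeds(seed, n_rep, stream=3)):
        ds = simulate_summary_dataset(SimConfig(n_snp=n_snp, causal_total=0.3,
                                                seed=int(s)))
        h = harmonize(ds.exposure, ds.outcome)
        idx = i % h.n_snp
        planted = _shift_outlier(h, idx, shift_se)
        res = mr_presso(planted, n_sim=1000, seed=int(s) % (2**31))
        hits += planted.rows.loc[planted.rows.index[idx], "snp_id"] in res.outliers
    return hits / n_rep


def presso_null_size(n_rep: int = 100, n_snp: int = 20, alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Global-test rejection rate under homogeneous null data."""
    rejections = 0
    for s in _rep_seeds(seed, n_rep, stream=4):
        ds = simulate_summary_dataset(SimConfig(n_snp=n_snp, causal_total=0.0,
                                                seed=int(s)))
        h = harmonize(ds.exposure, ds.outcome)
        rejections += mr_presso(h, n_sim=1000,
                                seed=int(s) % (2**31)).global_pval < alpha
    return rejections / n_rep


def egger_intercept_power(n_rep: int = 200, n_snp: int = 30,
                          pleiotropy_mean: float = 0.1, seed: int = 0) -> float:
    """Rejection rate of the Egger intercept test under directional
    pleiotropy affecting every instrument."""
    rejections = 0
    for s in _rep_seeds(seed, n_rep, stream=5):
        ds = simulate_summary_dataset(SimConfig(
            n_snp=n_snp, causal_total=0.0, pleiotropy_frac=1.0,
            pleiotropy_mean=pleiotropy_mean, pleiotropy_sd=0.05, seed=int(s)))
        rejections += mr_egger(harmonize(ds.exposure,
                                         ds.outcome))[1].pval < 0.05
    return rejections / n_rep


#: study conditions for the mediation recovery experiment: a powered
#: (common-disease) outcome so the per-replicate total effect, the
#: denominator of the mediated proportion, is identified
MEDIATION_RECOVERY_CONFIG = SimConfig(
    n_snp=40, causal_alpha=0.4, causal_beta2=0.5, causal_direct=0.3,
    causal_total=None, case_fraction=0.2)

MEDIATION_SELECTION = SelectionConfig(outcome_p_threshold=None)


def mediation_recovery(n_rep: int = 200, base_cfg: SimConfig | None = None,
                       seed: int = 0):
    """(mean two-step proportion, mean MVMR proportion, truth) over
    replicates of the standard mediation scenario."""
    base_cfg = base_cfg or MEDIATION_RECOVERY_CONFIG
    props2, propm = [], []
    truth = None
    for s in _rep_seeds(seed, n_rep, stream=6):
        ds = simulate_mediation_dataset(replace(base_cfg, seed=int(s)))
        truth = ds.truth["proportion"]
        res = mediation_summary(ds.exposure, ds.mediator, ds.outcome, ds.ld,
                                MEDIATION_SELECTION)
        if res.skipped:
            continue
        props2.append(res.proportion_two_step)
        propm.append(res.proportion_mvmr)
    return float(np.mean(props2)), float(np.nanmean(propm)), truth
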