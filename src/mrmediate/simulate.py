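"""Synthetic GWAS summary statistics with known causal structure.

Generates exposure / mediator / outcome summary-statistic triples directly
at the summary level (no individual genotypes): per-SNP effects are drawn
from the causal model and observed betas add normal sampling noise with the
analytic SE implied by allele frequency and sample size.  The outcome is a
rare binary trait whose SE uses the logistic-score approximation
1/sqrt(2*MAF*(1-MAF)*n*cf*(1-cf)); with a few hundred cases among ~250k
subjects this yields the very large outcome SEs characteristic of
rare-disease GWAS and stresses the estimators realistically.

Causal model (per SNP j, effect sizes on the exposure-increasing allele):

* exposure effect  gamma_j ~ N(0, gamma_sd^2)          (exposure SNPs)
* mediator direct  mu_j    ~ N(0, mediator_gamma_sd^2) (mediator SNPs)
* mediator effect  alpha*gamma_j + mu_j + eta_j
* outcome effect   beta*gamma_j + beta2*mu_j + delta_j, beta = beta1 + alpha*beta2

eta/delta are horizontal-pleiotropy terms drawn for a random
``pleiotropy_frac`` of SNPs from N(pleiotropy_mean, pleiotropy_sd^2) and
sign-aligned with gamma, so "directional" means directional relative to the
exposure-increasing allele (the orientation MR-Egger fits on).  Exposure-
and mediator-specific SNP roles are disjoint so that multivariable MR is
identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gwas import COLUMNS, GwasTable, LdInfo

__all__ = ["SimConfig", "SimDataset", "simulate_batch",
           "simulate_mediation_dataset", "simulate_summary_dataset"]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults mirror the cohorts the pipeline targets: a microbiome-scale
    exposure GWAS (n ~ 18k, standardized units), a metabolite-scale mediator
    GWAS (n ~ 8k), and a rare binary outcome (261 cases in 247,540 subjects,
    log-odds scale).  ``gamma_sd = 0.15`` puts selected-instrument F
    statistics broadly in the 10-150 range seen for microbiome taxa.
    """

    n_snp: int = 30
    n_exposure: int = 18_340
    n_outcome: int = 247_540
    n_mediator: int = 8_299
    maf_range: tuple = (0.1, 0.5)
    gamma_sd: float = 0.15
    mediator_gamma_sd: float = 0.15
    causal_total: float | None = 0.0      # beta (exposure -> outcome)
    causal_alpha: float | None = None     # alpha (exposure -> mediator)
    causal_beta2: float | None = None     # beta2 (mediator -> outcome)
    causal_direct: float | None = None    # beta1 (direct exposure -> outcome)
    mediator_snp_frac: float = 0.0        # fraction of SNPs acting on mediator only
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    case_fraction: float = 261 / 247_540
    ld_blocks: int = 0
    ld_block_size: int = 3
    ld_within_r2: float = 0.95
    palindromic_frac: float = 0.0
    swap_frac: float = 0.0
    snp_offset: int = 0   # rsID numbering offset (disjoint panels in batches)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        if not (0.0 < self.case_fraction < 0.5):
            raise ValueError("case_fraction must be in (0, 0.5)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")


@dataclass
class SimDataset:
    exposure: GwasTable
    outcome: GwasTable
    ld: LdInfo
    mediator: GwasTable | None = None
    truth: dict = field(default_factory=dict)


def _se_quantitative(maf, n):
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _se_binary(maf, n, cf):
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * cf * (1.0 - cf))


def _pvals(beta, se):
    from scipy.stats import norm
    return np.maximum(2.0 * norm.sf(np.abs(beta) / se), np.finfo(float).tiny)


def _pleiotropy(rng, n, frac, mean, sd, sign):
    """Sign-aligned pleiotropic effects for a random subset of SNPs."""
    delta = np.zeros(n)
    if frac > 0:
        hit = rng.random(n) < frac
        delta[hit] = rng.normal(mean, sd, size=hit.sum()) * sign[hit]
    return delta


def _alleles(rng, n, palindromic_frac):
    bases = np.array(list("ACGT"))
    ea = bases[rng.integers(0, 4, size=n)]
    oa = np.empty(n, dtype=object)
    pal = rng.random(n) < palindromic_frac
    for j in range(n):
        if pal[j]:
            oa[j] = _COMP[ea[j]]
        else:
            choices = [b for b in "ACGT" if b != ea[j] and b != _COMP[ea[j]]]
            oa[j] = choices[rng.integers(0, len(choices))]
    return ea.astype(object), oa


def _positions(rng, cfg):
    """Chromosome/position layout: independent SNPs far apart, or LD blocks
    of adjacent SNPs on the same chromosome within the clump window."""
    n = cfg.n_snp
    chrom = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    ld = LdInfo()
    block = -np.ones(n, dtype=np.int64)
    if cfg.ld_blocks > 0:
        block[: cfg.ld_blocks * cfg.ld_block_size] = \
            np.arange(cfg.ld_blocks * cfg.ld_block_size)[:n] // cfg.ld_block_size
    next_free = 0
    for j in range(n):
        if block[j] >= 0:  # blocked SNPs sit close together, inside the window
            b = int(block[j])
            chrom[j] = str(1 + (b % 22))
            pos[j] = 1_000_000 + (b // 22) * 60_000_000 \
                + (j % cfg.ld_block_size) * 50_000
        else:  # independent SNPs spaced far beyond any clump window
            chrom[j] = str(1 + (next_free % 22))
            pos[j] = 30_000_000 + (next_free // 22) * 60_000_000
            next_free += 1
    return chrom, pos, block, ld


def _table(name, ttype, snp_ids, chrom, pos, ea, oa, eaf, beta, se, n):
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pval": _pvals(beta, se),
        "n": np.full(len(snp_ids), n, dtype=np.int64),
    })[COLUMNS]
    return GwasTable(name, ttype, df)


def _maybe_swap(rng, df, frac):
    """Swap effect/other allele labels for a fraction of rows (beta negated,
    EAF complemented) so harmonization has real work to do."""
    if frac <= 0:
        return df
    swap = rng.random(len(df)) < frac
    df = df.copy()
    ea = df["effect_allele"].to_numpy(object).copy()
    oa = df["other_allele"].to_numpy(object).copy()
    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    df["effect_allele"], df["other_allele"] = ea, oa
    df.loc[swap, "beta"] = -df.loc[swap, "beta"]
    df.loc[swap, "eaf"] = 1.0 - df.loc[swap, "eaf"]
    return df


def simulate_summary_dataset(cfg: SimConfig) -> SimDataset:
    """Draw one synthetic exposure/(mediator)/outcome summary-stat triple.

    A single root seed governs everything; each table uses its own derived
    substream so adding or dropping the mediator does not perturb the other
    draws.  Identical configs give byte-identical tables.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_panel, rng_exp, rng_med, rng_out, rng_all = \
        [np.random.default_rng(s) for s in ss.spawn(5)]
    n = cfg.n_snp

    # causal parameters; beta = beta1 + alpha*beta2 when the chain is specified
    alpha = cfg.causal_alpha
    beta2 = cfg.causal_beta2
    beta1 = cfg.causal_direct
    if alpha is not None and beta2 is not None and beta1 is not None:
        beta = beta1 + alpha * beta2
        if cfg.causal_total is not None and not np.isclose(cfg.causal_total, beta):
            raise ValueError("causal_total inconsistent with beta1 + alpha*beta2")
    else:
        beta = cfg.causal_total if cfg.causal_total is not None else 0.0
        alpha = alpha if alpha is not None else 0.0
        beta2 = beta2 if beta2 is not None else 0.0

    maf = rng_panel.uniform(*cfg.maf_range, size=n)
    mediator_snp = rng_panel.random(n) < cfg.mediator_snp_frac
    gamma = np.where(~mediator_snp, rng_panel.normal(0.0, cfg.gamma_sd, n), 0.0)
    mu = np.where(mediator_snp, rng_panel.normal(0.0, cfg.mediator_gamma_sd, n), 0.0)
    sign = np.where(gamma + mu >= 0, 1.0, -1.0)
    snp_ids = np.array([f"rs{100000 + cfg.snp_offset + j}" for j in range(n)],
                       dtype=object)
    chrom, pos, block, ld = _positions(rng_panel, cfg)
    if cfg.ld_blocks > 0:
        for a in range(n):
            for b in range(a + 1, n):
                if block[a] == block[b]:
                    ld.set_r2(snp_ids[a], snp_ids[b], cfg.ld_within_r2)
    ea, oa = _alleles(rng_panel, n, cfg.palindromic_frac)
    eaf = np.where(rng_panel.random(n) < 0.5, maf, 1.0 - maf)

    se_exp = _se_quantitative(maf, cfg.n_exposure)
    beta_exp = gamma + rng_exp.normal(0.0, se_exp)
    exposure = _table("exposure", "quantitative", snp_ids, chrom, pos,
                      ea, oa, eaf, beta_exp, se_exp, cfg.n_exposure)

    eta = _pleiotropy(rng_med, n, cfg.pleiotropy_frac,
                      cfg.pleiotropy_mean, cfg.pleiotropy_sd, sign)
    se_med = _se_quantitative(maf, cfg.n_mediator)
    beta_med = alpha * gamma + mu + eta + rng_med.normal(0.0, se_med)
    mediator_df = _maybe_swap(
        rng_med, _table("mediator", "quantitative", snp_ids, chrom, pos,
                        ea, oa, eaf, beta_med, se_med, cfg.n_mediator).df,
        cfg.swap_frac)
    mediator = GwasTable("mediator", "quantitative", mediator_df)

    delta = _pleiotropy(rng_out, n, cfg.pleiotropy_frac,
                        cfg.pleiotropy_mean, cfg.pleiotropy_sd, sign)
    se_out = _se_binary(maf, cfg.n_outcome, cfg.case_fraction)
    if cfg.case_fraction * cfg.n_outcome < 10:
        import warnings
        warnings.warn("effectively unidentified outcome SEs: <10 expected cases")
    beta_out = beta * gamma + beta2 * mu + delta + rng_out.normal(0.0, se_out)
    outcome_df = _maybe_swap(
        rng_out, _table("outcome", "binary", snp_ids, chrom, pos,
                        ea, oa, eaf, beta_out, se_out, cfg.n_outcome).df,
        cfg.swap_frac)
    outcome = GwasTable("outcome", "binary", outcome_df)

    truth = {
        "beta": beta, "alpha": alpha, "beta2": beta2,
        "beta1": beta1 if beta1 is not None else beta - alpha * beta2,
        "gamma": gamma, "mu": mu, "mediator_snp": mediator_snp,
        "eta": eta, "delta": delta, "maf": maf,
        "config": asdict(cfg),
    }
    return SimDataset(exposure, outcome, ld, mediator=mediator, truth=truth)


def simulate_mediation_dataset(cfg: SimConfig) -> SimDataset:
    """Mediation variant: the full causal chain must be specified and the
    total effect beta = beta1 + alpha*beta2 is enforced; the truth records
    the implied mediated proportion alpha*beta2/beta."""
    if cfg.causal_alpha is None or cfg.causal_beta2 is None or cfg.causal_direct is None:
        raise ValueError("mediation dataset requires causal_alpha, causal_beta2, causal_direct")
    beta = cfg.causal_direct + cfg.causal_alpha * cfg.causal_beta2
    if beta == 0 and (cfg.causal_alpha * cfg.causal_beta2) != 0:
        raise ValueError("undefined proportion: total effect is zero")
    from dataclasses import replace
    cfg = replace(cfg, causal_total=beta,
                  mediator_snp_frac=cfg.mediator_snp_frac or 0.5)
    ds = simulate_summary_dataset(cfg)
    ds.truth["proportion"] = cfg.causal_alpha * cfg.causal_beta2 / beta
    return ds


def simulate_batch(n_exposures: int, causal_betas: dict | None = None,
                   base_cfg: SimConfig | None = None, seed: int = 0):
    """A batch of exposures with disjoint SNP panels sharing one outcome.

    Emulates a many-taxa screen against a single disease GWAS: exposure i
    owns its own instrument panel (disjoint rsIDs) and the outcome table is
    the union of the per-panel outcome rows, so each exposure's causal
    effect (``causal_betas[i]``, default 0) acts only through its own SNPs.
    Returns (exposures, outcome, ld).
    """
    from dataclasses import replace

    causal_betas = causal_betas or {}
    base_cfg = base_cfg or SimConfig()
    exposures, outcome_dfs = [], []
    ld = LdInfo()
    for i in range(n_exposures):
        cfg = replace(base_cfg,
                      causal_total=float(causal_betas.get(i, 0.0)),
                      causal_alpha=None, causal_beta2=None, causal_direct=None,
                      snp_offset=base_cfg.snp_offset + i * 10 * base_cfg.n_snp,
                      seed=(seed + 7919 * i) % (2**31))
        ds = simulate_summary_dataset(cfg)
        ds.exposure.trait_name = f"exposure_{i:02d}"
        exposures.append(ds.exposure)
        outcome_dfs.append(ds.outcome.df)
        ld.pairs.update(ds.ld.pairs)
    outcome = GwasTable("outcome", "binary",
                        pd.concat(outcome_dfs, ignore_index=True))
    return exposures, outcome, ld
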