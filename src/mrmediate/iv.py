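"""Instrument selection: p-value screen, clumping, outcome filter, strength.

Instruments for one exposure pass four criteria in order: (1) association
with the exposure at p below a loose genome-wide threshold (default 1e-5,
the convention for microbiome GWAS with modest sample sizes), (2) LD
clumping so retained SNPs are approximately independent, (3) no association
with the outcome (p above the same threshold), and (4) instrument strength
F > 10.  Known confounder-associated SNPs are removed last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gwas import GwasTable, HarmonizedSet, LdInfo, clump, harmonize

__all__ = [
    "FStatResult",
    "IvSet",
    "SelectionConfig",
    "exclude_confounder_snps",
    "f_statistic",
    "select_ivs",
]


@dataclass
class SelectionConfig:
    """Thresholds for the four instrument-selection criteria."""

    exposure_p_threshold: float = 1e-5
    outcome_p_threshold: float | None = 1e-5  # None disables the filter
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_threshold: float = 10.0
    confounder_snps: frozenset = frozenset()
    palindrome_freq_window: float = 0.08
    harmonize_action: str = "infer"

    def __post_init__(self):
        if not (0 < self.exposure_p_threshold < 1):
            raise ValueError("exposure_p_threshold must be in (0, 1)")
        for name in ("clump_r2", "clump_window_kb", "f_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.outcome_p_threshold is not None and self.outcome_p_threshold <= 0:
            raise ValueError("outcome_p_threshold must be positive or None")
        self.confounder_snps = frozenset(self.confounder_snps)


@dataclass
class FStatResult:
    """Per-SNP instrument strength.

    R2 = 2*MAF*(1-MAF)*beta^2 is the variance in the (standardized) exposure
    explained by the SNP; F = (R2/(1-R2)) * ((n-k-1)/k) with k instruments
    (k=1 per SNP).  Retained iff F strictly exceeds the threshold.
    """

    snp_id: str
    r2: float
    f: float
    retained: bool


def f_statistic(beta: float, eaf: float, n: int, k: int = 1,
                f_threshold: float = 10.0, snp_id: str = "") -> FStatResult:
    if not (0.0 <= eaf <= 1.0):
        raise ValueError("eaf must be in [0, 1]")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    maf = min(eaf, 1.0 - eaf)
    r2 = 2.0 * maf * (1.0 - maf) * beta * beta
    if maf == 0.0:
        return FStatResult(snp_id, 0.0, 0.0, False)
    if r2 >= 1.0:
        raise ValueError("variance explained not below 1")
    f = (r2 / (1.0 - r2)) * ((n - k - 1) / k)
    return FStatResult(snp_id, r2, f, f > f_threshold)


@dataclass
class IvSet:
    """Selected instruments for one exposure plus a per-criterion audit log.

    ``selection_log`` is a list of (step, n_removed, n_remaining) tuples; the
    removals sum to input size minus output size.
    """

    exposure_name: str
    snp_ids: tuple
    selection_log: list = field(default_factory=list)
    removed_confounders: tuple = ()

    @property
    def no_iv(self) -> bool:
        return len(self.snp_ids) == 0

    def __len__(self) -> int:
        return len(self.snp_ids)


def exclude_confounder_snps(ivs: IvSet, confounders) -> IvSet:
    """Remove instruments known to associate with outcome risk factors.

    Stands in for a PhenoScanner-style lookup: the caller supplies the rsIDs
    flagged as confounder-associated and they are dropped with a log entry.
    """
    confounders = set(confounders)
    removed = tuple(s for s in ivs.snp_ids if s in confounders)
    kept = tuple(s for s in ivs.snp_ids if s not in confounders)
    log = list(ivs.selection_log)
    log.append(("confounder_exclusion", len(removed), len(kept)))
    return IvSet(ivs.exposure_name, kept, log,
                 removed_confounders=ivs.removed_confounders + removed)


def select_ivs(exposure: GwasTable, outcome: GwasTable, ld: LdInfo,
               cfg: SelectionConfig) -> tuple[IvSet, HarmonizedSet]:
    """Apply the four selection criteria plus confounder exclusion.

    Order: exposure p-screen -> clump -> harmonize with outcome -> outcome
    p-filter -> F-filter -> confounder removal.  Returns the instrument set
    with its per-step log and the matching harmonized rows.  Zero survivors
    at any step yield a structured no-IV result rather than an error.
    """
    if len(exposure) == 0:
        raise ValueError("exposure table is empty")
    log: list = []
    n0 = len(exposure)

    sig = exposure.df[exposure.df["pval"] < cfg.exposure_p_threshold]
    step1 = GwasTable(exposure.trait_name, exposure.trait_type,
                      sig.reset_index(drop=True))
    log.append(("exposure_p_filter", n0 - len(step1), len(step1)))

    def _empty(h=None):
        if h is None:
            h = HarmonizedSet(exposure.trait_name, outcome.trait_name,
                              _empty_rows(), no_overlap=True)
        return IvSet(exposure.trait_name, (), log), h

    if len(step1) == 0:
        return _empty()

    step2 = clump(step1, ld, cfg.clump_r2, cfg.clump_window_kb)
    log.append(("ld_clump", len(step1) - len(step2), len(step2)))

    h = harmonize(step2, outcome, cfg.palindrome_freq_window, cfg.harmonize_action)
    log.append(("harmonize", len(step2) - h.n_snp, h.n_snp))
    if h.n_snp == 0:
        return _empty(h)

    if cfg.outcome_p_threshold is not None:
        keep = h.rows[h.rows["pval_out"] > cfg.outcome_p_threshold]
    else:
        keep = h.rows
    log.append(("outcome_p_filter", h.n_snp - len(keep), len(keep)))
    h = HarmonizedSet(h.exposure_name, h.outcome_name, keep.reset_index(drop=True),
                      h.n_dropped_palindromic, h.n_dropped_incompatible)
    if h.n_snp == 0:
        return _empty(h)

    n_map = dict(zip(exposure.df["snp_id"], exposure.df["n"]))
    strong = [
        rec.snp_id for rec in h.rows.itertuples(index=False)
        if f_statistic(rec.beta_exp, rec.eaf_exp, int(n_map[rec.snp_id]),
                       k=1, f_threshold=cfg.f_threshold).retained
    ]
    log.append(("f_statistic_filter", h.n_snp - len(strong), len(strong)))
    h = h.subset(strong)
    ivs = IvSet(exposure.trait_name, tuple(h.rows["snp_id"]), log)
    if ivs.no_iv:
        return ivs, h

    ivs = exclude_confounder_snps(ivs, cfg.confounder_snps)
    h = h.subset(ivs.snp_ids)
    return ivs, h


def _empty_rows():
    from .gwas import _HARMONIZED_COLUMNS
    import pandas as pd
    return pd.DataFrame(columns=_HARMONIZED_COLUMNS)
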