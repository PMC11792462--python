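"""Pipeline orchestration: forward MR batches, reverse MR, and reports.

``run_univariable`` runs the full per-exposure chain (instrument selection,
estimation with the Wald path for single-instrument exposures, sensitivity
battery, joint significance rule, Bonferroni across the family of
exposures).  ``run_reverse`` is the same machinery with disease and taxa
roles swapped.  ``render_report`` writes deterministic TSV + JSON output
mirroring the conventional results-table layout (exposure, method, N SNP,
beta, SE, p, OR, 95% CI).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .estimators import (MethodPanel, bonferroni_adjust, ivw, mr_egger,
                         significance_rule, weighted_median)
from .gwas import GwasTable, HarmonizedSet, LdInfo, read_gwas_table, read_ld
from .iv import IvSet, SelectionConfig, select_ivs
from .mediation import MediationResult
from .sensitivity import SensitivityReport, run_sensitivity

logger = logging.getLogger("mrmediate")

__all__ = ["ExposureResult", "RunConfig", "render_report", "run_reverse",
           "run_univariable"]


@dataclass
class RunConfig:
    """File-level configuration for a pipeline run (CLI / YAML surface)."""

    exposure_paths: list
    outcome_path: str
    ld_path: str | None = None
    mediator_paths: list = field(default_factory=list)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    alpha: float = 0.05
    bonferroni_m: int | None = None   # default: number of exposures tested
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sel = SelectionConfig(**raw.pop("selection", {}))
        return cls(selection=sel, **raw)

    def load(self):
        exposures = [read_gwas_table(p, Path(p).stem, "quantitative")
                     for p in self.exposure_paths]
        outcome = read_gwas_table(self.outcome_path, Path(self.outcome_path).stem,
                                  "binary")
        ld = read_ld(self.ld_path) if self.ld_path else LdInfo()
        return exposures, outcome, ld


@dataclass
class ExposureResult:
    """Everything computed for one exposure in a batch."""

    exposure_name: str
    panel: MethodPanel | None = None
    iv_set: IvSet | None = None
    harmonized: HarmonizedSet | None = None
    sensitivity: SensitivityReport | None = None
    skipped: bool = False
    reason: str = ""


def _estimate_panel(h: HarmonizedSet, exposure_name: str, outcome_name: str,
                    seed: int, alpha: float) -> MethodPanel:
    panel = MethodPanel(exposure_name, outcome_name)
    n = h.n_snp
    if n == 1:
        est = ivw(h)  # single instrument: Wald ratio, method recorded 'wald'
        panel.estimates[est.method] = est
        panel.significant = est.pval < alpha
        return panel
    panel.estimates["ivw"] = ivw(h)
    if n >= 3:
        panel.estimates["weighted_median"] = weighted_median(h, seed=seed)
        slope, intercept = mr_egger(h)
        panel.estimates["mr_egger_slope"] = slope
        panel.estimates["mr_egger_intercept"] = intercept
        panel.significant = significance_rule(panel, alpha)
    else:
        panel.significant = panel.estimates["ivw"].pval < alpha
    return panel


def run_univariable(exposures, outcome: GwasTable, ld: LdInfo,
                    cfg: SelectionConfig | None = None, alpha: float = 0.05,
                    bonferroni_m: int | None = None, seed: int = 0,
                    label: str = "forward") -> list[ExposureResult]:
    """Run the full univariable MR chain for a batch of exposures.

    The Bonferroni family size defaults to the number of exposures
    attempted, counting the ones skipped for lack of instruments.
    """
    exposures = list(exposures)
    if not exposures:
        raise ValueError("empty exposure list")
    cfg = cfg or SelectionConfig()
    results: list[ExposureResult] = []
    for i, exposure in enumerate(exposures):
        name = exposure.trait_name
        sub_seed = (seed + 1009 * i) % (2**31)
        ivs, h = select_ivs(exposure, outcome, ld, cfg)
        if ivs.no_iv:
            logger.info("%s: skipped (no instruments); log=%s", name, ivs.selection_log)
            results.append(ExposureResult(name, iv_set=ivs, skipped=True,
                                          reason="no instruments survived selection"))
            continue
        panel = _estimate_panel(h, name, outcome.trait_name, sub_seed, alpha)
        sens = run_sensitivity(h, seed=sub_seed, alpha=alpha) if h.n_snp >= 2 else None
        for step, removed, remaining in ivs.selection_log:
            logger.info("%s [%s]: %s removed %d, %d remain", name, label,
                        step, removed, remaining)
        results.append(ExposureResult(name, panel=panel, iv_set=ivs,
                                      harmonized=h, sensitivity=sens))
    m = bonferroni_m if bonferroni_m is not None else len(exposures)
    for res in results:
        if res.panel is not None:
            key = "ivw" if "ivw" in res.panel.estimates else "wald"
            res.panel.bonferroni_p = float(
                bonferroni_adjust([res.panel.estimates[key].pval], m)[0])
    return results


def run_reverse(disease: GwasTable, taxa, ld: LdInfo,
                cfg: SelectionConfig | None = None, alpha: float = 0.05,
                bonferroni_m: int | None = None, seed: int = 0) -> list[ExposureResult]:
    """Reverse MR: the disease is the exposure, each taxon the outcome.

    Instrument selection reuses the same thresholds as the forward run.
    """
    taxa = list(taxa)
    if not taxa:
        raise ValueError("empty outcome list for reverse MR")
    cfg = cfg or SelectionConfig()
    results = []
    for i, taxon in enumerate(taxa):
        sub_seed = (seed + 7919 * (i + 1)) % (2**31)
        ivs, h = select_ivs(disease, taxon, ld, cfg)
        name = f"{disease.trait_name}->{taxon.trait_name}"
        if ivs.no_iv:
            results.append(ExposureResult(name, iv_set=ivs, skipped=True,
                                          reason="no instruments survived selection"))
            continue
        panel = _estimate_panel(h, disease.trait_name, taxon.trait_name,
                                sub_seed, alpha)
        sens = run_sensitivity(h, seed=sub_seed, alpha=alpha) if h.n_snp >= 2 else None
        results.append(ExposureResult(name, panel=panel, iv_set=ivs,
                                      harmonized=h, sensitivity=sens))
    m = bonferroni_m if bonferroni_m is not None else len(taxa)
    for res in results:
        if res.panel is not None:
            key = "ivw" if "ivw" in res.panel.estimates else "wald"
            res.panel.bonferroni_p = float(
                bonferroni_adjust([res.panel.estimates[key].pval], m)[0])
    return results


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

_METHOD_LABEL = {"ivw": "IVW", "weighted_median": "Weighted median",
                 "mr_egger_slope": "MR Egger", "wald": "Wald"}


def _fmt_p(p: float) -> str:
    return f"{p:.2E}"


def _fmt_row(exposure: str, method: str, est) -> str:
    ci = f"{est.ci_low:.3f}-{est.ci_high:.3f}"
    return "\t".join([exposure, _METHOD_LABEL.get(method, method), str(est.n_snp),
                      f"{est.beta:.3f}", f"{est.se:.3f}", _fmt_p(est.pval),
                      f"{est.or_:.3f}", ci])


def _estimate_dict(est) -> dict:
    return {"method": est.method, "n_snp": est.n_snp, "beta": est.beta,
            "se": est.se, "pval": est.pval, "or": est.or_,
            "ci_low": est.ci_low, "ci_high": est.ci_high}


_MAIN_HEADER = "exposure\tmethod\tn_snp\tbeta\tse\tpval\tor\tci_95\n"
_MAIN_METHODS = ("ivw", "weighted_median", "mr_egger_slope", "wald")


def render_report(results: list[ExposureResult], out_dir,
                  mediation: list[MediationResult] | None = None,
                  label: str = "forward") -> dict:
    """Write main/sensitivity/mediation TSVs plus a machine-readable JSON.

    Output is deterministic for identical inputs (no timestamps, stable
    ordering), so identical seeds give byte-identical report directories.
    """
    if not results:
        raise ValueError("at least one exposure result required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    main_lines = [_MAIN_HEADER]
    all_lines = [_MAIN_HEADER]
    for res in results:
        if res.panel is None:
            continue
        for method in _MAIN_METHODS:
            if method in res.panel.estimates:
                row = _fmt_row(res.exposure_name, method,
                               res.panel.estimates[method]) + "\n"
                all_lines.append(row)
                if res.panel.significant:
                    main_lines.append(row)
    (out / f"{label}_significant.tsv").write_text("".join(main_lines))
    (out / f"{label}_all_results.tsv").write_text("".join(all_lines))

    sens_lines = ["exposure\tstatistic\tvalue\n"]
    for res in results:
        s = res.sensitivity
        if s is None:
            continue
        name = res.exposure_name
        if s.heterogeneity:
            sens_lines += [f"{name}\tcochran_q\t{s.heterogeneity.q:.6g}\n",
                           f"{name}\tcochran_q_df\t{s.heterogeneity.df}\n",
                           f"{name}\tcochran_q_p\t{_fmt_p(s.heterogeneity.pval)}\n"]
        if s.egger_intercept:
            sens_lines += [f"{name}\tegger_intercept\t{s.egger_intercept.beta:.6g}\n",
                           f"{name}\tegger_intercept_p\t{_fmt_p(s.egger_intercept.pval)}\n"]
        if s.presso:
            sens_lines += [f"{name}\tpresso_global_p\t{_fmt_p(s.presso.global_pval)}\n",
                           f"{name}\tpresso_outliers\t"
                           f"{','.join(sorted(s.presso.outliers)) or 'none'}\n"]
        if s.loo:
            sens_lines.append(
                f"{name}\tloo_flagged\t{','.join(sorted(s.loo.flagged)) or 'none'}\n")
    (out / f"{label}_sensitivity.tsv").write_text("".join(sens_lines))

    if mediation:
        med_header = ("exposure\tmediator\talpha\tbeta2\ttotal\tindirect_two_step\t"
                      "direct_mvmr\tproportion_two_step\tproportion_mvmr\t"
                      "proportion_pval\tlabel\n")
        med_lines = [med_header]
        for m in mediation:
            med_lines.append("\t".join([
                m.exposure, m.mediator, f"{m.alpha:.6g}", f"{m.beta2:.6g}",
                f"{m.total:.6g}", f"{m.indirect_two_step:.6g}",
                f"{m.direct_mvmr:.6g}", f"{m.proportion_two_step:.6g}",
                f"{m.proportion_mvmr:.6g}", _fmt_p(m.proportion_pval), m.label,
            ]) + "\n")
        (out / f"{label}_mediation.tsv").write_text("".join(med_lines))
    else:
        logger.info("no mediation results; mediation file omitted")

    payload = {"label": label, "exposures": []}
    for res in results:
        entry = {"exposure": res.exposure_name, "skipped": res.skipped,
                 "reason": res.reason}
        if res.iv_set is not None:
            entry["n_iv"] = len(res.iv_set)
            entry["selection_log"] = [list(t) for t in res.iv_set.selection_log]
        if res.panel is not None:
            entry["significant"] = res.panel.significant
            entry["bonferroni_p"] = res.panel.bonferroni_p
            entry["estimates"] = {m: _estimate_dict(e)
                                  for m, e in sorted(res.panel.estimates.items())}
        payload["exposures"].append(entry)
    if mediation:
        payload["mediation"] = [
            {k: (v if not isinstance(v, float) or np.isfinite(v) else None)
             for k, v in vars(m).items() if k != "details"}
            for m in mediation
        ]
    (out / f"{label}_report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload
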