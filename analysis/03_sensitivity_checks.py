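#!/usr/bin/env python
"""Sensitivity battery for the significant exposure from the forward screen.

Cochran's Q (heterogeneity), MR-Egger intercept (directional pleiotropy),
MR-PRESSO (outliers), and leave-one-out influence, written to
results/sensitivity.tsv.
"""

from pathlib import Path

from mrmediate.gwas import read_gwas_table, read_ld
from mrmediate.iv import SelectionConfig
from mrmediate.sensitivity import run_sensitivity
from mrmediate.iv import select_ivs

DATA = Path("results/data")
SEED = 20240


def main():
    exposure = read_gwas_table(DATA / "exposure_00.tsv", "exposure_00",
                               "quantitative")
    outcome = read_gwas_table(DATA / "outcome.tsv", "vaginitis-like", "binary")
    ld = read_ld(DATA / "ld.tsv")
    ivs, h = select_ivs(exposure, outcome, ld, SelectionConfig())
    rep = run_sensitivity(h, seed=SEED)

    lines = ["statistic\tvalue\n"]
    het = rep.heterogeneity
    lines.append(f"cochran_q\t{het.q:.4f}\n")
    lines.append(f"cochran_q_df\t{het.df}\n")
    lines.append(f"cochran_q_p\t{het.pval:.4g}\n")
    egg = rep.egger_intercept
    lines.append(f"egger_intercept\t{egg.beta:.4f}\n")
    lines.append(f"egger_intercept_p\t{egg.pval:.4g}\n")
    lines.append(f"presso_global_p\t{rep.presso.global_pval:.4g}\n")
    lines.append(f"presso_outliers\t{','.join(sorted(rep.presso.outliers)) or 'none'}\n")
    lines.append(f"loo_flagged\t{','.join(sorted(rep.loo.flagged)) or 'none'}\n")
    Path("results/sensitivity.tsv").write_text("".join(lines))

    print(f"{len(ivs)} instruments; Q={het.q:.2f} (p={het.pval:.3f}); "
          f"Egger intercept p={egg.pval:.3f}; PRESSO global p="
          f"{rep.presso.global_pval:.3f}, outliers: "
          f"{sorted(rep.presso.outliers) or 'none'}; "
          f"leave-one-out flags: {sorted(rep.loo.flagged) or 'none'}")


if __name__ == "__main__":
    main()
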