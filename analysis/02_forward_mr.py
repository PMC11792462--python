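#!/usr/bin/env python
"""Forward MR screen: every exposure against the rare binary outcome.

Runs the full chain per exposure (p < 1e-5 screen, LD clumping at
r2 < 0.001 within 10,000 kb, harmonization, outcome-association filter,
F > 10, confounder exclusion; IVW + weighted median + MR-Egger; joint
significance rule; Bonferroni across the screen) and writes the
conventional results tables under results/forward/.
"""

from pathlib import Path

from mrmediate.gwas import read_gwas_table, read_ld
from mrmediate.iv import SelectionConfig
from mrmediate.pipeline import render_report, run_univariable

DATA = Path("results/data")
SEED = 20240


def main():
    exposures = [read_gwas_table(p, p.stem, "quantitative")
                 for p in sorted(DATA.glob("exposure_*.tsv"))]
    outcome = read_gwas_table(DATA / "outcome.tsv", "vaginitis-like", "binary")
    ld = read_ld(DATA / "ld.tsv")

    results = run_univariable(exposures, outcome, ld, SelectionConfig(),
                              seed=SEED)
    render_report(results, "results/forward")

    for res in results:
        if res.skipped:
            print(f"{res.exposure_name}: skipped ({res.reason})")
            continue
        key = "ivw" if "ivw" in res.panel.estimates else "wald"
        est = res.panel.estimates[key]
        flag = "SIGNIFICANT" if res.panel.significant else "ns"
        print(f"{res.exposure_name}: {len(res.iv_set)} IVs, {key} OR "
              f"{est.or_:.3f} (p {est.pval:.2E}, Bonferroni "
              f"{res.panel.bonferroni_p:.2E}) {flag}")


if __name__ == "__main__":
    main()
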