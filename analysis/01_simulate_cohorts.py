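#!/usr/bin/env python
"""Generate the synthetic study: a taxa-like exposure screen and a
mediation triple.

Emulates the data layout of a gut-microbiota -> vaginitis MR study: ten
exposure GWAS (standardized units, n = 18,340) screened against one rare
binary outcome GWAS (261 cases / 247,540 subjects, log-odds scale), with
one protective exposure planted (beta = -2.5, the size of the strongest
reported genus effect), plus an exposure/metabolite-mediator/outcome triple
with a known mediated proportion of 0.4.  Tables are written as TSV under
results/data/ for the downstream steps.
"""

from pathlib import Path

import yaml

from mrmediate.gwas import write_gwas_table, write_ld
from mrmediate.simulate import (SimConfig, simulate_batch,
                                simulate_mediation_dataset)

SEED = 20240
OUT = Path("results/data")


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    exposures, outcome, ld = simulate_batch(
        10, {0: -2.5}, SimConfig(n_snp=15, swap_frac=0.3,
                                 palindromic_frac=0.1), seed=SEED)
    for exp in exposures:
        write_gwas_table(exp, OUT / f"{exp.trait_name}.tsv")
    write_gwas_table(outcome, OUT / "outcome.tsv")
    write_ld(ld, OUT / "ld.tsv")
    print(f"screen: {len(exposures)} exposures x 15 SNPs; planted protective "
          f"effect beta=-2.5 on {exposures[0].trait_name}")

    med = simulate_mediation_dataset(SimConfig(
        n_snp=40, causal_alpha=0.4, causal_beta2=0.5, causal_direct=0.3,
        causal_total=None, case_fraction=0.2, seed=SEED + 1))
    write_gwas_table(med.exposure, OUT / "med_exposure.tsv")
    write_gwas_table(med.mediator, OUT / "med_mediator.tsv")
    write_gwas_table(med.outcome, OUT / "med_outcome.tsv")
    write_ld(med.ld, OUT / "med_ld.tsv")
    truth = {k: float(v) for k, v in med.truth.items()
             if k in ("beta", "alpha", "beta2", "beta1", "proportion")}
    (OUT / "med_truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    print(f"mediation triple: truth {truth}")


if __name__ == "__main__":
    main()
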