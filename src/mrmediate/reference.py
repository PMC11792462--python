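"""Published reference estimates used as worked-example inputs.

These are the reported per-method summary estimates from a published
two-sample MR screen of 196 gut-microbiota taxa against vaginitis (a rare
binary outcome, 261 cases / 247,279 controls): the four genera that reached
joint significance, with the per-method (beta, SE, number of instruments)
triples on the log-odds scale, plus the inputs of its metabolite mediation
follow-up.  The report layer turns such triples into odds ratios,
confidence intervals, and p-values; these rows exercise exactly that
transformation (the betas themselves require the source GWAS data and are
not recomputed here).
"""

from __future__ import annotations

#: (exposure, method, n_snp, beta, se)
REFERENCE_ESTIMATES = [
    ("Candidatus Soleaferrea", "ivw", 9, 0.788, 0.355),
    ("Candidatus Soleaferrea", "weighted_median", 9, 0.855, 0.495),
    ("Candidatus Soleaferrea", "mr_egger", 9, 5.629, 3.846),
    ("Dialister", "ivw", 11, 0.964, 0.441),
    ("Dialister", "weighted_median", 11, 0.74, 0.587),
    ("Dialister", "mr_egger", 11, 0.492, 1.789),
    ("Lachnospiraceae UCG-008", "ivw", 11, -0.887, 0.327),
    ("Lachnospiraceae UCG-008", "weighted_median", 11, -0.953, 0.429),
    ("Lachnospiraceae UCG-008", "mr_egger", 11, -1.225, 1.68),
    ("Ruminiclostridium 5", "ivw", 10, -2.521, 0.581),
    ("Ruminiclostridium 5", "weighted_median", 10, -2.228, 0.802),
    ("Ruminiclostridium 5", "mr_egger", 10, -7.182, 2.315),
]

#: number of taxa tested, i.e. the Bonferroni family size for the screen
N_TAXA_TESTED = 196

#: two SNPs flagged as confounder-associated (type 2 diabetes and
#: parathyroid problems) and excluded from the instrument sets
CONFOUNDER_SNPS = frozenset({"rs6494306", "rs10458299"})

#: mediation worked-example inputs:
#: (exposure, mediator, alpha, alpha_se, mediator->outcome OR and 95% CI,
#:  total beta, total se)
MEDIATION_INPUTS = [
    ("Lachnospiraceae UCG-008", "arachidonate/pyruvate ratio",
     0.12, 0.057, 0.622, (0.391, 0.989), -0.887, 0.327),
    ("Lachnospiraceae UCG-008", "palmitate/myristate ratio",
     -0.183, 0.057, 1.924, (1.08, 3.425), -0.887, 0.327),
]
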