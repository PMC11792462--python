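"""Shared fixtures: direct builders for harmonized sets and GWAS tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrmediate.gwas import COLUMNS, GwasTable, HarmonizedSet

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def build_harmonized(bx, sx, by, sy, exposure="exposure", outcome="outcome",
                     pval_out=0.5):
    """HarmonizedSet straight from effect arrays (bypasses allele logic)."""
    bx, sx, by, sy = map(lambda a: np.asarray(a, dtype=float), (bx, sx, by, sy))
    n = len(bx)
    rows = pd.DataFrame({
        "snp_id": [f"rs{j:04d}" for j in range(n)],
        "effect_allele": "A", "other_allele": "G",
        "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy,
        "eaf_exp": 0.3, "eaf_out": 0.3,
        "pval_exp": 1e-8, "pval_out": pval_out,
    })
    return HarmonizedSet(exposure, outcome, rows)


def build_table(records, trait_name="trait", trait_type="quantitative"):
    """GwasTable from a list of dicts; unspecified fields get benign values."""
    defaults = {"chrom": "1", "pos": 1_000_000, "effect_allele": "A",
                "other_allele": "G", "eaf": 0.3, "beta": 0.1, "se": 0.05,
                "pval": 1e-6, "n": 18_340}
    rows = []
    for i, rec in enumerate(records):
        row = dict(defaults)
        row.setdefault("snp_id", f"rs{i:04d}")
        row.update(rec)
        rows.append(row)
    df = pd.DataFrame(rows)[COLUMNS]
    return GwasTable(trait_name, trait_type, df)


@pytest.fixture
def harmonized_builder():
    return build_harmonized


@pytest.fixture
def table_builder():
    return build_table
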