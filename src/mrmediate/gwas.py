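"""GWAS summary-statistics tables, allele harmonization, and LD clumping.

The central container is :class:`GwasTable`, a thin wrapper around a pandas
DataFrame holding one row per variant with the ten canonical summary-statistic
fields (rsID, chromosome, position, effect/other allele, effect-allele
frequency, beta, SE, p, N).  Two-sample MR needs per-SNP effect pairs on a
common effect allele, which :func:`harmonize` produces, and approximately
independent instruments, which :func:`clump` produces from a user-supplied
pairwise r-squared table (:class:`LdInfo`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GwasFormatError",
    "GwasTable",
    "HarmonizedSet",
    "LdInfo",
    "clump",
    "harmonize",
    "read_gwas_table",
    "read_ld",
    "write_gwas_table",
]

#: canonical internal column names, in file order
COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: default header aliases used in TSV files (overridable per call)
DEFAULT_ALIASES = {
    "SNP": "snp_id", "CHR": "chrom", "POS": "pos", "EA": "effect_allele",
    "OA": "other_allele", "EAF": "eaf", "BETA": "beta", "SE": "se",
    "P": "pval", "N": "n",
}

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GwasFormatError(ValueError):
    """Raised for malformed summary-statistics input."""


@dataclass
class GwasTable:
    """Summary statistics for one trait.

    ``trait_type`` is ``"quantitative"`` (beta in trait units / SD) or
    ``"binary"`` (beta on the log-odds scale).  ``rejections`` lists
    ``(snp_id, reason)`` pairs for input rows that violated field invariants
    and were excluded at read time.
    """

    trait_name: str
    trait_type: str
    df: pd.DataFrame
    rejections: list = field(default_factory=list)
    n_missing_ld: int = 0  # set by clump()

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        dup = self.df["snp_id"].duplicated()
        if dup.any():
            first = self.df.loc[dup, "snp_id"].iloc[0]
            raise GwasFormatError(f"duplicate snp_id: {first!r}")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, snp_ids) -> "GwasTable":
        keep = self.df[self.df["snp_id"].isin(set(snp_ids))].reset_index(drop=True)
        return GwasTable(self.trait_name, self.trait_type, keep)


def _validate_rows(df: pd.DataFrame):
    """Split rows into (valid, list of (snp_id, reason))."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    flag(~ea.isin(_VALID_ALLELES) | ~oa.isin(_VALID_ALLELES), "invalid allele")
    flag(ea == oa, "identical alleles")
    flag(~(df["se"] > 0), "nonpositive se")
    flag((df["eaf"] < 0) | (df["eaf"] > 1) | df["eaf"].isna(), "eaf out of range")
    flag(~(df["pval"] > 0) | (df["pval"] > 1), "pval out of range")
    flag(~(df["n"] > 0), "nonpositive n")

    bad = reasons != ""
    rejected = list(zip(df.loc[bad, "snp_id"], reasons[bad]))
    valid = df.loc[~bad].copy()
    valid["effect_allele"] = ea[~bad]
    valid["other_allele"] = oa[~bad]
    return valid.reset_index(drop=True), rejected


def read_gwas_table(path, trait_name: str, trait_type: str,
                    aliases: dict | None = None) -> GwasTable:
    """Read a tab-separated summary-statistics table.

    The header must name (possibly via ``aliases``) all ten canonical
    columns.  Rows violating field invariants are excluded and recorded in
    ``GwasTable.rejections`` with a reason; structural problems (missing
    column, duplicate rsID, empty file) raise :class:`GwasFormatError`.
    """
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update(aliases)
    try:
        raw = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    except pd.errors.EmptyDataError:
        raise GwasFormatError(f"empty summary-statistics file: {path}")
    raw = raw.rename(columns=lambda c: alias_map.get(c, c))
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise GwasFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if len(raw) == 0:
        raise GwasFormatError(f"no data rows in {path}")
    df = raw[COLUMNS].copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64").astype("int64")
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    valid, rejected = _validate_rows(df)
    return GwasTable(trait_name, trait_type, valid, rejections=rejected)


def write_gwas_table(table: GwasTable, path) -> None:
    """Write a table in the canonical TSV layout (inverse of read)."""
    out = table.df[COLUMNS].copy()
    out.columns = list(DEFAULT_ALIASES)  # SNP, CHR, POS, ...
    with io.StringIO() as buf:
        out.to_csv(buf, sep="\t", index=False, float_format="%.12g")
        text = buf.getvalue()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


# ---------------------------------------------------------------------------
# LD information
# ---------------------------------------------------------------------------

@dataclass
class LdInfo:
    """Pairwise LD (r-squared) lookup.  Absent pairs default to r2 = 0."""

    pairs: dict = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str):
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 out of [0,1]: {r2}")
        self.pairs[self._key(a, b)] = float(r2)

    def get(self, a: str, b: str):
        """r2 for a pair, or None if the pair is not recorded."""
        if a == b:
            return 1.0
        return self.pairs.get(self._key(a, b))

    def r2(self, a: str, b: str) -> float:
        val = self.get(a, b)
        return 0.0 if val is None else val


def read_ld(path) -> LdInfo:
    """Read a three-column TSV (SNP_A, SNP_B, R2)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in df.columns:
            raise GwasFormatError(f"LD file missing column {col}")
    ld = LdInfo()
    for a, b, r2 in zip(df["SNP_A"].astype(str), df["SNP_B"].astype(str), df["R2"]):
        ld.set_r2(a, b, float(r2))
    return ld


def write_ld(ld: LdInfo, path) -> None:
    rows = sorted((a, b, r2) for (a, b), r2 in ld.pairs.items())
    df = pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedSet:
    """Allele-aligned per-SNP effect pairs ready for MR.

    ``rows`` has one line per SNP kept in both tables, sorted by rsID, with
    outcome effects re-signed onto the exposure's effect allele.  Exposure
    and outcome p-values ride along for downstream instrument filters.
    """

    exposure_name: str
    outcome_name: str
    rows: pd.DataFrame
    n_dropped_palindromic: int = 0
    n_dropped_incompatible: int = 0
    no_overlap: bool = False

    @property
    def n_snp(self) -> int:
        return len(self.rows)

    def subset(self, snp_ids) -> "HarmonizedSet":
        keep = self.rows[self.rows["snp_id"].isin(set(snp_ids))].reset_index(drop=True)
        return HarmonizedSet(self.exposure_name, self.outcome_name, keep,
                             self.n_dropped_palindromic, self.n_dropped_incompatible)

    def drop(self, snp_id: str) -> "HarmonizedSet":
        keep = self.rows[self.rows["snp_id"] != snp_id].reset_index(drop=True)
        return HarmonizedSet(self.exposure_name, self.outcome_name, keep,
                             self.n_dropped_palindromic, self.n_dropped_incompatible)


_HARMONIZED_COLUMNS = [
    "snp_id", "effect_allele", "other_allele", "beta_exp", "se_exp",
    "beta_out", "se_out", "eaf_exp", "eaf_out", "pval_exp", "pval_out",
]


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def harmonize(exposure: GwasTable, outcome: GwasTable,
              palindrome_freq_window: float = 0.08,
              action: str = "infer") -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect allele.

    Matching is by rsID.  Outcome records whose alleles are swapped (or
    strand-flipped, or both) relative to the exposure have their beta negated
    and EAF complemented as needed.  Palindromic SNPs (A/T or C/G) cannot be
    strand-resolved from alleles; those with either EAF within
    ``palindrome_freq_window`` of 0.5 are dropped.  Outside that window,
    ``action="infer"`` aligns them by matching minor-allele status while
    ``action="drop_palindromic"`` drops them all.
    """
    if not (0.0 <= palindrome_freq_window < 0.5):
        raise ValueError("palindrome_freq_window must be in [0, 0.5)")
    if action not in ("infer", "drop_palindromic"):
        raise ValueError(f"unknown harmonization action {action!r}")
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("harmonize requires nonempty tables")

    merged = exposure.df.merge(outcome.df, on="snp_id", suffixes=("_x", "_y"))
    if len(merged) == 0:
        return HarmonizedSet(exposure.trait_name, outcome.trait_name,
                             pd.DataFrame(columns=_HARMONIZED_COLUMNS),
                             no_overlap=True)

    out_rows = []
    n_pal = n_inc = 0
    for rec in merged.itertuples(index=False):
        ea_x, oa_x = rec.effect_allele_x, rec.other_allele_x
        ea_y, oa_y = rec.effect_allele_y, rec.other_allele_y
        beta_y, eaf_y = rec.beta_y, rec.eaf_y
        palindromic = _is_palindromic(ea_x, oa_x)

        if palindromic:
            # swap and strand flip are indistinguishable: allele strings must
            # match directly or swapped, orientation decided by frequency
            if (ea_y, oa_y) == (ea_x, oa_x):
                flip = False
            elif (ea_y, oa_y) == (oa_x, ea_x):
                flip = True
            else:
                n_inc += 1
                continue
            ambiguous = (abs(rec.eaf_x - 0.5) <= palindrome_freq_window
                         or abs(eaf_y - 0.5) <= palindrome_freq_window)
            if ambiguous or action == "drop_palindromic":
                n_pal += 1
                continue
            if flip:
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            # strand check: minor-allele status must agree after alignment
            if (rec.eaf_x - 0.5) * (eaf_y - 0.5) < 0:
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
        else:
            if (ea_y, oa_y) == (ea_x, oa_x):
                pass
            elif (ea_y, oa_y) == (oa_x, ea_x):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            elif (ea_y, oa_y) == (_COMPLEMENT[ea_x], _COMPLEMENT[oa_x]):
                pass  # other strand, same orientation
            elif (ea_y, oa_y) == (_COMPLEMENT[oa_x], _COMPLEMENT[ea_x]):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            else:
                n_inc += 1
                continue

        out_rows.append((rec.snp_id, ea_x, oa_x, rec.beta_x, rec.se_x,
                         beta_y, rec.se_y, rec.eaf_x, eaf_y,
                         rec.pval_x, rec.pval_y))

    rows = pd.DataFrame(out_rows, columns=_HARMONIZED_COLUMNS)
    rows = rows.sort_values("snp_id", kind="mergesort").reset_index(drop=True)
    return HarmonizedSet(exposure.trait_name, outcome.trait_name, rows,
                         n_dropped_palindromic=n_pal,
                         n_dropped_incompatible=n_inc,
                         no_overlap=len(rows) == 0)


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def clump(table: GwasTable, ld: LdInfo, r2_threshold: float = 0.001,
          window_kb: float = 10_000.0) -> GwasTable:
    """Greedy p-value-sorted LD clumping.

    Records are visited in (pval, chrom, pos, snp_id) order; a record is
    retained iff its r2 with every already-retained record on the same
    chromosome within ``window_kb`` kilobases is below ``r2_threshold``.
    Pairs absent from ``ld`` count as r2 = 0 and are tallied in the returned
    table's ``n_missing_ld``.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    window_bp = window_kb * 1000.0

    order = table.df.sort_values(
        ["pval", "chrom", "pos", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    retained_idx: list[int] = []
    missing = 0
    for i, rec in enumerate(order.itertuples(index=False)):
        ok = True
        for j in retained_idx:
            kept = order.iloc[j]
            if kept["chrom"] != rec.chrom:
                continue
            if abs(float(kept["pos"]) - float(rec.pos)) > window_bp:
                continue
            r2 = ld.get(kept["snp_id"], rec.snp_id)
            if r2 is None:
                missing += 1
                r2 = 0.0
            if r2 >= r2_threshold:
                ok = False
                break
        if ok:
            retained_idx.append(i)
    result = GwasTable(table.trait_name, table.trait_type,
                       order.iloc[retained_idx].reset_index(drop=True))
    result.n_missing_ld = missing
    return result
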