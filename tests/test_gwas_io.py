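"""GWAS table I/O, allele harmonization, and LD clumping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mrmediate.gwas import (GwasFormatError, GwasTable, LdInfo, clump,
                            harmonize, read_gwas_table, read_ld,
                            write_gwas_table)
from mrmediate.gwas import write_ld
from mrmediate.simulate import SimConfig, simulate_summary_dataset

from conftest import build_table

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


def _write(tmp_path, body, name="stats.tsv"):
    path = tmp_path / name
    path.write_text(HEADER + body)
    return path


class TestReadWrite:
    def test_well_formed_read(self, tmp_path):
        path = _write(tmp_path,
                      "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.05\t1e-6\t18340\n"
                      "rs2\t2\t200\tC\tT\t0.2\t-0.2\t0.04\t1e-7\t18340\n"
                      "rs3\t3\t300\tG\tA\t0.4\t0.05\t0.03\t0.5\t18340\n")
        t = read_gwas_table(path, "taxon", "quantitative")
        assert len(t) == 3 and t.rejections == []
        assert t.df.loc[1, "beta"] == -0.2

    def test_invalid_rows_counted_not_dropped_silently(self, tmp_path):
        path = _write(tmp_path,
                      "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.05\t1e-6\t18340\n"
                      "rs2\t2\t200\tC\tT\t0.2\t-0.2\t0\t1e-7\t18340\n"
                      "rs3\t3\t300\tG\tA\t0.4\t0.05\t0.03\t0.5\t18340\n")
        t = read_gwas_table(path, "taxon", "quantitative")
        assert len(t) == 2
        assert t.rejections == [("rs2", "nonpositive se")]

    @pytest.mark.parametrize("body,err", [
        ("", "no data rows"),
        ("rs1\t1\t100\tA\tG\t0.3\t0.1\t0.05\t1e-6\t18340\n"
         "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.05\t1e-6\t18340\n", "duplicate snp_id"),
    ])
    def test_structural_errors(self, tmp_path, body, err):
        with pytest.raises(GwasFormatError, match=err):
            read_gwas_table(_write(tmp_path, body), "t", "binary")

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\n"
                        "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.05\t1e-6\n")
        with pytest.raises(GwasFormatError, match="n"):
            read_gwas_table(path, "t", "binary")

    def test_round_trip_50_records(self, tmp_path):
        ds = simulate_summary_dataset(SimConfig(n_snp=50, seed=5))
        path = tmp_path / "rt.tsv"
        write_gwas_table(ds.exposure, path)
        back = read_gwas_table(path, "exposure", "quantitative")
        for col in ("eaf", "beta", "se", "pval"):
            np.testing.assert_allclose(back.df[col], ds.exposure.df[col],
                                       rtol=1e-11)  # 12 significant digits
        assert list(back.df["snp_id"]) == list(ds.exposure.df["snp_id"])

    def test_ld_round_trip(self, tmp_path):
        ld = LdInfo()
        ld.set_r2("rs1", "rs2", 0.5)
        ld.set_r2("rs3", "rs1", 0.25)
        path = tmp_path / "ld.tsv"
        write_ld(ld, path)
        back = read_ld(path)
        assert back.r2("rs2", "rs1") == 0.5 and back.r2("rs1", "rs3") == 0.25
        assert back.get("rs1", "rs9") is None and back.r2("rs1", "rs9") == 0.0


class TestHarmonize:
    def _pair(self, exp_alleles, out_alleles, beta_out=0.2, eaf_out=0.3,
              eaf_exp=0.3):
        exp = build_table([{"snp_id": "rs1", "effect_allele": exp_alleles[0],
                            "other_allele": exp_alleles[1], "eaf": eaf_exp}])
        out = build_table([{"snp_id": "rs1", "effect_allele": out_alleles[0],
                            "other_allele": out_alleles[1], "beta": beta_out,
                            "eaf": eaf_out}], trait_name="out")
        return exp, out

    def test_identical_alleles_unchanged(self):
        h = harmonize(*self._pair(("A", "G"), ("A", "G")))
        assert h.rows.loc[0, "beta_out"] == 0.2
        assert h.rows.loc[0, "eaf_out"] == 0.3

    def test_swapped_alleles_flip_beta_and_eaf(self):
        h = harmonize(*self._pair(("A", "G"), ("G", "A")))
        assert h.rows.loc[0, "beta_out"] == -0.2
        assert h.rows.loc[0, "eaf_out"] == 0.7

    def test_strand_flip_same_orientation(self):
        h = harmonize(*self._pair(("A", "G"), ("T", "C")))
        assert h.rows.loc[0, "beta_out"] == 0.2

    def test_ambiguous_palindrome_dropped(self):
        h = harmonize(*self._pair(("A", "T"), ("A", "T"), eaf_exp=0.50,
                                  eaf_out=0.50))
        assert h.n_snp == 0 and h.n_dropped_palindromic == 1

    def test_palindrome_inferred_by_frequency(self):
        # exposure minor (0.2) but outcome reports 0.8 on written alleles:
        # other strand, so beta must flip
        h = harmonize(*self._pair(("A", "T"), ("A", "T"), eaf_exp=0.2,
                                  eaf_out=0.8))
        assert h.n_snp == 1 and h.rows.loc[0, "beta_out"] == -0.2

    def test_drop_palindromic_action(self):
        h = harmonize(*self._pair(("C", "G"), ("C", "G"), eaf_exp=0.2,
                                  eaf_out=0.2), action="drop_palindromic")
        assert h.n_snp == 0 and h.n_dropped_palindromic == 1

    def test_incompatible_alleles_counted(self):
        h = harmonize(*self._pair(("A", "G"), ("A", "C")))
        assert h.n_snp == 0 and h.n_dropped_incompatible == 1

    def test_no_overlap_flagged(self):
        exp = build_table([{"snp_id": "rs1"}])
        out = build_table([{"snp_id": "rs2"}], trait_name="out")
        h = harmonize(exp, out)
        assert h.no_overlap and h.n_snp == 0

    def test_idempotent_on_generator_output(self):
        ds = simulate_summary_dataset(SimConfig(n_snp=40, seed=9,
                                                swap_frac=0.4,
                                                palindromic_frac=0.2))
        h1 = harmonize(ds.exposure, ds.outcome)
        # rebuild aligned tables from the harmonized rows and re-harmonize
        exp2 = build_table([
            {"snp_id": r.snp_id, "effect_allele": r.effect_allele,
             "other_allele": r.other_allele, "eaf": r.eaf_exp,
             "beta": r.beta_exp, "se": r.se_exp, "pval": r.pval_exp}
            for r in h1.rows.itertuples(index=False)])
        out2 = build_table([
            {"snp_id": r.snp_id, "effect_allele": r.effect_allele,
             "other_allele": r.other_allele, "eaf": r.eaf_out,
             "beta": r.beta_out, "se": r.se_out, "pval": r.pval_out}
            for r in h1.rows.itertuples(index=False)], trait_name="out",
            trait_type="binary")
        h2 = harmonize(exp2, out2)
        assert h2.n_dropped_palindromic == 0 and h2.n_dropped_incompatible == 0
        np.testing.assert_array_equal(h2.rows["beta_out"], h1.rows["beta_out"])
        np.testing.assert_array_equal(h2.rows["beta_exp"], h1.rows["beta_exp"])

    def test_swap_recovers_unswapped_effects(self):
        plain = simulate_summary_dataset(SimConfig(n_snp=40, seed=13))
        swapped = simulate_summary_dataset(SimConfig(n_snp=40, seed=13,
                                                     swap_frac=0.5))
        h_plain = harmonize(plain.exposure, plain.outcome)
        h_swap = harmonize(swapped.exposure, swapped.outcome)
        np.testing.assert_allclose(h_swap.rows["beta_out"],
                                   h_plain.rows["beta_out"], rtol=1e-12)


class TestClump:
    def _two_snp(self, r2):
        t = build_table([
            {"snp_id": "rsA", "chrom": "1", "pos": 1_000_000, "pval": 1e-8},
            {"snp_id": "rsB", "chrom": "1", "pos": 1_100_000, "pval": 1e-6},
        ])
        ld = LdInfo()
        ld.set_r2("rsA", "rsB", r2)
        return t, ld

    def test_correlated_pair_keeps_best_p(self):
        t, ld = self._two_snp(0.5)
        out = clump(t, ld, 0.001, 10_000)
        assert list(out.df["snp_id"]) == ["rsA"]

    def test_independent_pair_both_kept(self):
        t, ld = self._two_snp(0.0)
        out = clump(t, ld, 0.001, 10_000)
        assert set(out.df["snp_id"]) == {"rsA", "rsB"}

    def test_missing_ld_pair_tallied_as_zero(self):
        t, _ = self._two_snp(0.0)
        out = clump(t, LdInfo(), 0.001, 10_000)
        assert set(out.df["snp_id"]) == {"rsA", "rsB"}
        assert out.n_missing_ld == 1

    def test_outside_window_not_compared(self):
        t = build_table([
            {"snp_id": "rsA", "chrom": "1", "pos": 1_000_000, "pval": 1e-8},
            {"snp_id": "rsB", "chrom": "1", "pos": 1_000_000 + 10_001_000,
             "pval": 1e-6},
        ])
        ld = LdInfo()
        ld.set_r2("rsA", "rsB", 0.9)
        assert len(clump(t, ld, 0.001, 10_000)) == 2

    @staticmethod
    def _brute_force(table, ld, r2_threshold, window_kb):
        recs = sorted(table.df.to_dict("records"),
                      key=lambda r: (r["pval"], r["chrom"], r["pos"], r["snp_id"]))
        kept = []
        for rec in recs:
            ok = True
            for k in kept:
                if (k["chrom"] == rec["chrom"]
                        and abs(k["pos"] - rec["pos"]) <= window_kb * 1000
                        and ld.r2(k["snp_id"], rec["snp_id"]) >= r2_threshold):
                    ok = False
            if ok:
                kept.append(rec)
        return {r["snp_id"] for r in kept}

    def test_matches_brute_force_on_random_instance(self):
        rng = np.random.default_rng(1234)
        records, ld = [], LdInfo()
        ids = [f"rs{j}" for j in range(50)]
        for j, sid in enumerate(ids):
            records.append({"snp_id": sid, "chrom": str(rng.integers(1, 4)),
                            "pos": int(rng.integers(1, 3_000_000)),
                            "pval": float(rng.uniform(1e-10, 1e-4))})
        for _ in range(200):
            a, b = rng.choice(50, 2, replace=False)
            ld.set_r2(ids[a], ids[b], float(rng.uniform(0, 1)))
        t = build_table(records)
        got = set(clump(t, ld, 0.1, 1_000).df["snp_id"])
        assert got == self._brute_force(t, ld, 0.1, 1_000)

    @given(st.randoms(use_true_random=False))
    def test_invariant_to_input_order(self, rnd):
        rng = np.random.default_rng(rnd.randrange(2**31))
        records, ld = [], LdInfo()
        ids = [f"rs{j}" for j in range(12)]
        for sid in ids:
            records.append({"snp_id": sid, "chrom": str(rng.integers(1, 3)),
                            "pos": int(rng.integers(1, 500_000)),
                            "pval": float(rng.uniform(1e-9, 1e-4))})
        for _ in range(20):
            a, b = rng.choice(12, 2, replace=False)
            ld.set_r2(ids[a], ids[b], float(rng.uniform(0, 1)))
        t = build_table(records)
        shuffled = GwasTable(t.trait_name, t.trait_type,
                             t.df.sample(frac=1, random_state=7)
                             .reset_index(drop=True))
        out1 = clump(t, ld, 0.2, 500)
        out2 = clump(shuffled, ld, 0.2, 500)
        assert list(out1.df["snp_id"]) == list(out2.df["snp_id"])
        # every retained pair within window is below the threshold
        kept = out1.df
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept.iloc[i], kept.iloc[j]
                if a["chrom"] == b["chrom"] and abs(a["pos"] - b["pos"]) <= 500_000:
                    assert ld.r2(a["snp_id"], b["snp_id"]) < 0.2
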