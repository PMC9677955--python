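"""Reading, validation, palindrome detection and pairwise harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ldmr import (EmptyOverlapError, FormatError, VariantRecord,
                  harmonize_pair, is_palindromic, read_sumstats)
from ldmr.errors import EmptyInputError
from ldmr.sumstats_io import SumStats, validate_frame

from conftest import make_sumstats_frame


def _write(tmp_path, df, name="ss.tsv"):
    path = tmp_path / name
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadSumstats:
    def test_identity_read(self, tmp_path):
        df = make_sumstats_frame(3)
        ss = read_sumstats(_write(tmp_path, df), trait_label="t")
        assert len(ss) == 3
        assert ss.drop_log == {}

    def test_zero_se_row_dropped(self, tmp_path):
        df = make_sumstats_frame(3)
        df.loc[1, "se"] = 0.0
        ss = read_sumstats(_write(tmp_path, df))
        assert len(ss) == 2
        assert ss.drop_log["invalid_se"] == 1

    def test_lowercase_alleles_normalized(self, tmp_path):
        # oracle: upper-casing then re-validating accepts the row unchanged
        df = make_sumstats_frame(2)
        df.loc[0, ["effect_allele", "other_allele"]] = ["a", "t"]
        ss = read_sumstats(_write(tmp_path, df))
        assert len(ss) == 2
        assert list(ss.df.loc[ss.df["snp_id"] == "rs0000",
                              ["effect_allele", "other_allele"]].iloc[0]) == ["A", "T"]
        upper = df.copy()
        upper["effect_allele"] = upper["effect_allele"].str.upper()
        upper["other_allele"] = upper["other_allele"].str.upper()
        clean, _, _ = validate_frame(upper)
        pd.testing.assert_frame_equal(ss.df, clean)

    def test_missing_mandatory_column_is_format_error(self, tmp_path):
        df = make_sumstats_frame(3).drop(columns=["beta"])
        with pytest.raises(FormatError):
            read_sumstats(_write(tmp_path, df))

    def test_all_rows_invalid_is_empty_input_error(self, tmp_path):
        df = make_sumstats_frame(2, se=0.0)
        with pytest.raises(EmptyInputError):
            read_sumstats(_write(tmp_path, df))

    def test_dialect_mapping_loads_foreign_headers(self, tmp_path):
        df = make_sumstats_frame(3).rename(columns={
            "snp_id": "SNP", "beta": "Effect", "se": "StdErr",
            "effect_allele": "A1", "other_allele": "A2"})
        dialect = {"snp_id": "SNP", "beta": "Effect", "se": "StdErr",
                   "effect_allele": "A1", "other_allele": "A2"}
        ss = read_sumstats(_write(tmp_path, df), dialect=dialect)
        assert len(ss) == 3

    def test_gzip_input(self, tmp_path):
        df = make_sumstats_frame(4)
        path = tmp_path / "ss.tsv.gz"
        df.to_csv(path, sep="\t", index=False, compression="gzip")
        assert len(read_sumstats(path)) == 4

    def test_duplicate_ids_keep_first(self, tmp_path):
        df = make_sumstats_frame(4)
        df.loc[3, "snp_id"] = "rs0000"
        ss = read_sumstats(_write(tmp_path, df))
        assert len(ss) == 3
        assert ss.drop_log["duplicate_id"] == 1

    def test_pz_discrepancy_logged_not_corrected(self, tmp_path):
        df = make_sumstats_frame(3)
        df["pvalue"] = [0.9, 0.9, 0.9]  # inconsistent with beta/se
        ss = read_sumstats(_write(tmp_path, df))
        assert "pz_discrepant_warned" in ss.drop_log
        assert (ss.df["pvalue"] == 0.9).all()


class TestPalindromeDetection:
    @pytest.mark.parametrize("ea,oa,eaf,pal,inter", [
        ("A", "T", 0.50, True, True),
        ("A", "G", 0.50, False, False),
        ("G", "C", 0.10, True, False),
        ("C", "G", 0.43, True, True),
        ("T", "A", None, True, True),  # missing frequency: unresolvable
    ])
    def test_classification(self, ea, oa, eaf, pal, inter):
        rec = VariantRecord("rs1", effect_allele=ea, other_allele=oa, eaf=eaf)
        flags = is_palindromic(rec)
        assert flags.palindromic is pal
        assert flags.intermediate is inter


def _pair(exp_rows, out_rows):
    exp = SumStats.from_frame("exp", pd.DataFrame(exp_rows), validate=False)
    out = SumStats.from_frame("out", pd.DataFrame(out_rows), validate=False)
    return exp, out


def _row(snp="rs1", ea="A", oa="G", beta=0.1, eaf=0.3, se=0.02, p=1e-6):
    return {"snp_id": snp, "chrom": 1, "pos": 100, "effect_allele": ea,
            "other_allele": oa, "eaf": eaf, "beta": beta, "se": se,
            "pvalue": p, "n": 1000.0}


class TestHarmonizePair:
    def test_allele_swap_flips_sign(self):
        exp, out = _pair([_row(ea="A", oa="G", beta=0.10)],
                         [_row(ea="G", oa="A", beta=0.05, eaf=0.7)])
        pair = harmonize_pair(exp, out)
        row = pair.df.iloc[0]
        assert row["beta_out"] == pytest.approx(-0.05)
        assert row["action"] == "flip"
        assert row["eaf_out"] == pytest.approx(0.3)

    def test_strand_complement_aligned(self):
        exp, out = _pair([_row(ea="A", oa="G", beta=0.10)],
                         [_row(ea="T", oa="C", beta=0.05)])
        pair = harmonize_pair(exp, out)
        assert pair.df.iloc[0]["beta_out"] == pytest.approx(0.05)
        assert pair.df.iloc[0]["action"] == "complement"

    def test_irreconcilable_alleles_dropped_and_logged(self):
        exp, out = _pair([_row(ea="A", oa="G")], [_row(ea="A", oa="C")])
        pair = harmonize_pair(exp, out)
        assert len(pair.df) == 0
        assert list(pair.exclusions["reason"]) == ["allele_mismatch"]

    def test_palindromic_intermediate_dropped(self):
        exp, out = _pair([_row(ea="A", oa="T", eaf=0.5)],
                         [_row(ea="A", oa="T", eaf=0.5)])
        pair = harmonize_pair(exp, out)
        assert len(pair.df) == 0
        assert list(pair.exclusions["reason"]) == ["palindromic_intermediate"]

    def test_palindromic_informative_oriented_by_frequency(self):
        # frequencies on opposite sides of 0.5: the outcome is on the
        # other strand, so its effect flips
        exp, out = _pair([_row(ea="A", oa="T", eaf=0.2)],
                         [_row(ea="A", oa="T", beta=0.05, eaf=0.8)])
        pair = harmonize_pair(exp, out)
        assert pair.df.iloc[0]["beta_out"] == pytest.approx(-0.05)
        assert pair.df.iloc[0]["action"] == "palindromic_flipped"

    def test_zero_overlap_raises(self):
        exp, out = _pair([_row(snp="rs1")], [_row(snp="rs2")])
        with pytest.raises(EmptyOverlapError):
            harmonize_pair(exp, out)

    def test_idempotent(self):
        rows_exp = [_row(), _row(snp="rs2", ea="C", oa="T", beta=-0.04, eaf=0.25),
                    _row(snp="rs3", ea="G", oa="C", eaf=0.15)]
        rows_out = [_row(ea="G", oa="A", beta=0.02, eaf=0.72),
                    _row(snp="rs2", ea="G", oa="A", beta=0.07, eaf=0.3),
                    _row(snp="rs3", ea="C", oa="G", beta=0.01, eaf=0.88)]
        exp, out = _pair(rows_exp, rows_out)
        first = harmonize_pair(exp, out)

        def rebuild(df, which):
            return SumStats.from_frame(which, pd.DataFrame({
                "snp_id": df["snp_id"], "chrom": df["chrom"], "pos": df["pos"],
                "effect_allele": df["ea"], "other_allele": df["oa"],
                "eaf": df["eaf"] if which == "exp" else df["eaf_out"],
                "beta": df[f"beta_{which}"], "se": df[f"se_{which}"],
                "pvalue": df[f"p_{which}"], "n": 1000.0}), validate=False)

        second = harmonize_pair(rebuild(first.df, "exp"), rebuild(first.df, "out"))
        assert len(second.exclusions) == 0
        np.testing.assert_allclose(second.df["beta_out"], first.df["beta_out"])
        np.testing.assert_allclose(second.df["beta_exp"], first.df["beta_exp"])

    def test_sign_flip_involution(self):
        """Re-encoding both inputs on the swapped allele frame negates the
        aligned effects; re-encoding twice restores them exactly."""
        rows_exp = [_row(), _row(snp="rs2", ea="C", oa="T", beta=-0.04)]
        rows_out = [_row(beta=0.03), _row(snp="rs2", ea="T", oa="C", beta=0.07)]
        exp, out = _pair(rows_exp, rows_out)
        base = harmonize_pair(exp, out)

        def swapped(ss):
            df = ss.df.copy()
            df[["effect_allele", "other_allele"]] = \
                df[["other_allele", "effect_allele"]].to_numpy()
            df["beta"] = -df["beta"]
            df["eaf"] = 1 - df["eaf"]
            return SumStats.from_frame(ss.trait_label, df, validate=False)

        flipped = harmonize_pair(swapped(exp), swapped(out))
        np.testing.assert_allclose(flipped.df["beta_exp"], -base.df["beta_exp"])
        np.testing.assert_allclose(flipped.df["beta_out"], -base.df["beta_out"])
        twice = harmonize_pair(swapped(swapped(exp)), swapped(swapped(out)))
        np.testing.assert_allclose(twice.df["beta_out"], base.df["beta_out"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.sampled_from(["AG", "AC", "TC", "TG", "AT", "CG"]),
                  st.integers(0, 3),
                  st.floats(0.05, 0.95),
                  st.floats(-0.2, 0.2)),
        min_size=1, max_size=12))
    def test_every_shared_variant_kept_or_logged_once(self, variants):
        """Partition property: kept rows plus exclusion-log rows cover each
        shared variant exactly once, whatever the allele encodings."""
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        exp_rows, out_rows = [], []
        for i, (pair_code, enc, eaf, beta) in enumerate(variants):
            ea, oa = pair_code[0], pair_code[1]
            exp_rows.append(_row(snp=f"v{i}", ea=ea, oa=oa, eaf=eaf, beta=beta))
            oea, ooa, obeta, oeaf = ea, oa, beta / 2, eaf
            if enc in (1, 3):
                oea, ooa, obeta, oeaf = ooa, oea, -obeta, 1 - oeaf
            if enc in (2, 3):
                oea, ooa = comp[oea], comp[ooa]
            out_rows.append(_row(snp=f"v{i}", ea=oea, oa=ooa, eaf=oeaf, beta=obeta))
        exp, out = _pair(exp_rows, out_rows)
        try:
            pair = harmonize_pair(exp, out)
        except EmptyOverlapError:
            pytest.skip("construction guarantees overlap")
        kept = list(pair.df["snp_id"])
        dropped = list(pair.exclusions["snp_id"])
        assert sorted(kept + dropped) == sorted(f"v{i}" for i in range(len(variants)))
        assert len(set(dropped)) == len(dropped)
        # non-palindromic re-encodings are lossless: aligned effect halves
        for row in pair.df.itertuples(index=False):
            if row.action in ("same", "flip", "complement", "complement_flip"):
                assert row.beta_out == pytest.approx(row.beta_exp / 2)
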