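"""Instrument selection: clumping, proxy search, and the six-step protocol."""

import numpy as np
import pandas as pd
import pytest

from ldmr import (EmptyInstrumentError, IVConfig, MRScenario, PanelConfig,
                  clump, find_proxy, select_instruments, simulate_mr_scenario,
                  simulate_panel)
from ldmr.panel import ReferencePanel
from ldmr.sumstats_io import SumStats


def brute_force_clump(candidates, panel, r2_thresh, distance_kb):
    """Independent oracle: literal greedy rule with per-pair r2 from raw
    dosages."""
    rows = candidates.sort_values(["pvalue", "snp_id"]).to_dict("records")
    kept, discarded = [], set()
    for row in rows:
        if row["snp_id"] in discarded:
            continue
        if row["snp_id"] not in panel:
            kept.append(row["snp_id"])
            continue
        kept.append(row["snp_id"])
        for other in rows:
            sid = other["snp_id"]
            if sid == row["snp_id"] or sid in discarded or sid not in panel:
                continue
            if sid in kept:
                continue
            if other["chrom"] != row["chrom"]:
                continue
            if abs(other["pos"] - row["pos"]) > distance_kb * 1000:
                continue
            r = np.corrcoef(panel.column(row["snp_id"]),
                            panel.column(sid))[0, 1]
            if r * r >= r2_thresh:
                discarded.add(sid)
    return [s for s in kept if s not in discarded]


def candidates_from_panel(panel, seed=0):
    rng = np.random.default_rng(seed)
    df = panel.variants[["snp_id", "chrom", "pos"]].copy()
    df["pvalue"] = 10.0 ** rng.uniform(-12, -5, len(df))
    return df


class TestClump:
    def test_single_candidate_kept(self, small_panel):
        cand = candidates_from_panel(small_panel).head(1)
        kept, no_ld, removed = clump(cand, small_panel, 0.001, 10_000)
        assert kept == [cand["snp_id"].iloc[0]]
        assert removed.empty

    def test_perfectly_correlated_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, size=(200, 1)).astype(float)
        variants = pd.DataFrame({
            "snp_id": ["lead", "shadow"], "chrom": [1, 1], "pos": [100, 200],
            "effect_allele": "A", "other_allele": "G", "maf": 0.3})
        panel = ReferencePanel(np.hstack([x, x]), variants)
        cand = pd.DataFrame({"snp_id": ["shadow", "lead"], "chrom": [1, 1],
                             "pos": [200, 100], "pvalue": [1e-6, 1e-8]})
        kept, _, removed = clump(cand, panel, 0.001, 10_000)
        assert kept == ["lead"]
        assert list(removed["snp_id"]) == ["shadow"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_block_panels(self, seed):
        panel = simulate_panel(PanelConfig(n_ind=400, m_snps=20, block_size=5,
                                           within_block_r=0.7, seed=seed))
        # compress positions so blocks fall within clumping distance
        panel.variants["pos"] = 10_000 + 100 * np.arange(panel.m)
        cand = candidates_from_panel(panel, seed=seed)
        kept, _, _ = clump(cand, panel, r2_thresh=0.1, distance_kb=10)
        oracle = brute_force_clump(cand, panel, 0.1, 10)
        assert sorted(kept) == sorted(oracle)

    def test_candidates_absent_from_panel_kept_with_flag(self, small_panel):
        cand = candidates_from_panel(small_panel).head(3).copy()
        cand.loc[cand.index[0], "snp_id"] = "not_in_panel"
        kept, no_ld, _ = clump(cand, small_panel, 0.001, 10_000)
        assert "not_in_panel" in kept
        assert no_ld == ["not_in_panel"]


class TestFindProxy:
    def _target(self, ids):
        df = pd.DataFrame({
            "snp_id": ids, "chrom": 1, "pos": np.arange(len(ids)),
            "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
            "beta": 0.01, "se": 0.01, "pvalue": 0.5, "n": 1000.0})
        return SumStats.from_frame("target", df, validate=False)

    def test_duplicated_column_is_perfect_proxy(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, size=(100, 1)).astype(float)
        y = rng.integers(0, 3, size=(100, 1)).astype(float)
        variants = pd.DataFrame({
            "snp_id": ["a", "dup", "other"], "chrom": 1, "pos": [1, 2, 3],
            "effect_allele": "A", "other_allele": "G", "maf": 0.3})
        panel = ReferencePanel(np.hstack([x, x, y]), variants)
        proxy, r = find_proxy("a", self._target(["dup", "other"]), panel, 0.8)
        assert proxy == "dup"
        assert r == pytest.approx(1.0)

    def test_no_proxy_above_threshold(self, small_panel):
        ids = list(small_panel.variants["snp_id"])
        # target holds only variants from a different block
        target = self._target([i for i in ids if small_panel.blocks[ids.index(i)] == 3])
        proxy, reason = find_proxy(ids[0], target, small_panel, 0.8)
        assert proxy is None

    def test_matches_exhaustive_search(self, small_panel):
        ids = list(small_panel.variants["snp_id"])
        target = self._target(ids[1:10])
        proxy, r = find_proxy(ids[0], target, small_panel, 0.0)
        corrs = {s: np.corrcoef(small_panel.column(ids[0]),
                                small_panel.column(s))[0, 1] ** 2
                 for s in ids[1:10]}
        assert proxy == max(corrs, key=corrs.get)

    def test_absent_snp_reports_reason(self, small_panel):
        proxy, reason = find_proxy("ghost", self._target(["pv000001"]),
                                   small_panel, 0.8)
        assert proxy is None and reason == "snp_absent_from_panel"


class TestSelectInstruments:
    def test_no_suggestive_exposure_variant_fails_at_step_one(self):
        exp, out, _ = simulate_mr_scenario(MRScenario(beta_causal=0.01, k_iv=5, seed=1))
        weak = exp.df.copy()
        weak["pvalue"] = 0.5
        exp_weak = SumStats.from_frame("exp", weak, validate=False)
        with pytest.raises(EmptyInstrumentError) as err:
            select_instruments(exp_weak, out, None)
        assert err.value.step == 1

    def test_planted_confounders_and_palindrome_bookkeeping(self):
        exp, out, truth = simulate_mr_scenario(MRScenario(
            beta_causal=0.01, k_iv=20, seed=2, n_palindromic_intermediate=1))
        conf = frozenset(truth.snp_ids[5:7])  # two non-palindromic instruments
        cfg = IVConfig(confounder_snps=conf)
        iv = select_instruments(exp, out, None, cfg)
        assert iv.k == 17
        steps = iv.exclusions.groupby("step").size().to_dict()
        assert steps.get(4, 0) == 2
        assert steps.get(5, 0) == 1
        assert set(iv.exclusions.loc[iv.exclusions["step"] == 4, "snp_id"]) == set(conf)

    def test_conservation_of_candidates(self):
        exp, out, _ = simulate_mr_scenario(MRScenario(
            beta_causal=0.01, k_iv=25, seed=3, n_palindromic_intermediate=2))
        cfg = IVConfig(confounder_snps=frozenset(["iv0010"]))
        iv = select_instruments(exp, out, None, cfg)
        n_candidates = int((exp.df["pvalue"] < cfg.p_exposure_max).sum())
        assert iv.k + len(iv.exclusions) == n_candidates
        assert not set(iv.df["snp_id"]) & set(iv.exclusions["snp_id"])

    def test_rerun_on_kept_set_is_fixed_point(self):
        exp, out, _ = simulate_mr_scenario(MRScenario(beta_causal=0.01, k_iv=15, seed=4))
        iv = select_instruments(exp, out, None)
        kept = set(iv.df["snp_id"])
        exp2 = SumStats.from_frame(
            "exp", exp.df[exp.df["snp_id"].isin(kept)], validate=False)
        iv2 = select_instruments(exp2, out, None)
        assert set(iv2.df["snp_id"]) == kept
        np.testing.assert_allclose(
            iv2.df.sort_values("snp_id")["beta_out"],
            iv.df.sort_values("snp_id")["beta_out"])

    def test_outcome_association_exclusion(self):
        exp, out, truth = simulate_mr_scenario(MRScenario(beta_causal=0.01, k_iv=10, seed=5))
        hot = out.df.copy()
        hot.loc[hot["snp_id"] == "iv0003", "pvalue"] = 1e-9
        out_hot = SumStats.from_frame("out", hot, validate=False)
        iv = select_instruments(exp, out_hot, None)
        assert "iv0003" not in set(iv.df["snp_id"])
        row = iv.exclusions[iv.exclusions["snp_id"] == "iv0003"]
        assert list(row["step"]) == [3]

    def test_threshold_tightening_never_increases_kept_count(self):
        exp, out, _ = simulate_mr_scenario(MRScenario(beta_causal=0.01, k_iv=40, seed=6))
        kept = []
        for p_max in (1e-5, 1e-7, 1e-9, 1e-11):
            try:
                iv = select_instruments(exp, out, None,
                                        IVConfig(p_exposure_max=p_max))
                kept.append(iv.k)
            except EmptyInstrumentError:
                kept.append(0)
        assert kept == sorted(kept, reverse=True)

    def test_proxy_substitution_for_missing_outcome_variant(self):
        exp, out, _ = simulate_mr_scenario(MRScenario(beta_causal=0.01, k_iv=6, seed=7))
        # panel where the missing instrument has a perfect proxy present
        rng = np.random.default_rng(8)
        x = rng.integers(0, 3, size=(200, 1)).astype(float)
        cols = {sid: rng.integers(0, 3, size=(200, 1)).astype(float)
                for sid in exp.df["snp_id"]}
        cols["iv0000"] = x
        cols["proxy0"] = x.copy()
        ids = list(cols)
        variants = pd.DataFrame({
            "snp_id": ids, "chrom": 1, "pos": np.arange(len(ids)),
            "effect_allele": "A", "other_allele": "G", "maf": 0.3})
        panel = ReferencePanel(np.hstack([cols[s] for s in ids]), variants)
        # outcome lacks iv0000 but carries the proxy
        out_df = out.df[out.df["snp_id"] != "iv0000"].copy()
        proxy_row = out.df[out.df["snp_id"] == "iv0000"].copy()
        proxy_row["snp_id"] = "proxy0"
        out2 = SumStats.from_frame("out", pd.concat([out_df, proxy_row]),
                                   validate=False)
        iv = select_instruments(exp, out2, panel, IVConfig(clump_r2=1.0))
        row = iv.df[iv.df["snp_id"] == "iv0000"]
        assert len(row) == 1
        assert bool(row["proxy_used"].iloc[0])
        assert row["proxy_id"].iloc[0] == "proxy0"

    def test_fstat_column_reported(self):
        exp, out, _ = simulate_mr_scenario(MRScenario(beta_causal=0.01, k_iv=8, seed=9))
        iv = select_instruments(exp, out, None)
        z2 = (iv.df["beta_exp"] / iv.df["se_exp"]) ** 2
        np.testing.assert_allclose(iv.df["f_stat"], z2)
        assert (iv.df["f_stat"] > 10).all()  # strong instruments by design

    def test_write_read_round_trip(self, tmp_path):
        exp, out, _ = simulate_mr_scenario(MRScenario(beta_causal=0.01, k_iv=8, seed=10))
        iv = select_instruments(exp, out, None)
        iv.write(tmp_path / "run")
        back = __import__("ldmr").IVSet.read(tmp_path / "run")
        assert back.k == iv.k
        np.testing.assert_allclose(back.df["beta_exp"], iv.df["beta_exp"])
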