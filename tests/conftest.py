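"""Shared fixtures: small panels, summary-statistics frames, scenarios."""

import logging

import numpy as np
import pandas as pd
import pytest

from ldmr import (IVSet, MRScenario, PanelConfig, harmonize_pair,
                  simulate_mr_scenario, simulate_panel)
from ldmr.sumstats_io import SumStats

logging.getLogger("ldmr").setLevel(logging.ERROR)


def make_sumstats_frame(n=5, seed=0, **overrides):
    """A well-formed summary-statistics frame with n rows."""
    rng = np.random.default_rng(seed)
    pairs = [("A", "G"), ("T", "C"), ("C", "A"), ("G", "T"), ("A", "C")]
    df = pd.DataFrame({
        "snp_id": [f"rs{i:04d}" for i in range(n)],
        "chrom": (np.arange(n) % 22) + 1,
        "pos": 1000 + 500 * np.arange(n),
        "effect_allele": [pairs[i % len(pairs)][0] for i in range(n)],
        "other_allele": [pairs[i % len(pairs)][1] for i in range(n)],
        "eaf": rng.uniform(0.1, 0.4, n),
        "beta": rng.normal(0, 0.1, n),
        "se": rng.uniform(0.01, 0.05, n),
        "n": 10_000.0,
    })
    df["pvalue"] = np.nan
    for key, val in overrides.items():
        df[key] = val
    return df


@pytest.fixture
def sumstats_frame():
    return make_sumstats_frame()


@pytest.fixture
def small_panel():
    return simulate_panel(PanelConfig(n_ind=300, m_snps=20, block_size=5,
                                      within_block_r=0.5, seed=11))


def scenario_ivset(seed=0, **kw):
    """Harmonized instrument set straight from an MR scenario."""
    kw.setdefault("k_iv", 30)
    exposure, outcome, truth = simulate_mr_scenario(MRScenario(seed=seed, **kw))
    pair = harmonize_pair(exposure, outcome)
    return IVSet.from_harmonized(pair.df), truth


@pytest.fixture
def clean_ivset():
    iv, _ = scenario_ivset(seed=5, pleiotropy_mode="none")
    return iv


def ivset_from_arrays(beta_exp, beta_out, se_exp, se_out):
    """Hand-built instrument table for arithmetic oracles."""
    k = len(beta_exp)
    df = pd.DataFrame({
        "snp_id": [f"h{i}" for i in range(k)],
        "ea": "A", "oa": "G",
        "beta_exp": np.asarray(beta_exp, float),
        "se_exp": np.asarray(se_exp, float),
        "p_exp": 1e-8,
        "beta_out": np.asarray(beta_out, float),
        "se_out": np.asarray(se_out, float),
        "p_out": 0.5,
        "eaf": 0.3,
    })
    return IVSet.from_harmonized(df)
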