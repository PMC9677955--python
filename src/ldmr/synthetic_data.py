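"""Synthetic reference panels and GWAS summary statistics with known truth.

Three generators give every downstream stage a ground truth to recover:

* :func:`simulate_panel` — a block-exchangeable dosage panel for LD-score,
  clumping and proxy oracles.
* :func:`simulate_bivariate_gwas` — paired per-variant z-scores whose first
  and second moments obey the LD-score-regression expectation model
  ``E[chi2 | l_j] = N h2 l_j / M + N a + 1`` and whose cross products
  satisfy ``E[z1 z2] = sqrt(N1 N2) rg sqrt(h2_1 h2_2) l_j / M``.  This
  "summary-statistics-first" construction is exact for the quantities the
  regression estimates and keeps desk-scale variant counts feasible;
  individual-level phenotype simulation is deliberately avoided except via
  small panels in oracle tests.
* :func:`simulate_mr_scenario` — a two-sample Mendelian-randomization
  scenario with a known causal effect and, optionally, planted horizontal
  pleiotropy (balanced, directional, or single-outlier), violating the MR
  exclusion-restriction assumptions in controlled ways.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .ldscore import LdScores, compute_ld_scores
from .panel import ReferencePanel
from .sumstats_io import SumStats

_EXPOSURE_P_MAX = 1e-5  # instruments are genome-wide-suggestive by construction

#: non-palindromic allele pairs used for generated variants
_SAFE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
               ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class PanelConfig:
    """Block-exchangeable reference-panel configuration."""

    n_ind: int = 2_000
    m_snps: int = 100
    block_size: int = 10
    within_block_r: float = 0.3
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.m_snps % self.block_size:
            raise ConfigError("m_snps must divide into whole blocks")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ConfigError("within_block_r must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")


@dataclass(frozen=True)
class BivariateGwasConfig:
    """Bivariate polygenic architecture under the LDSC expectation model.

    ``confound_a`` is the per-study confounding inflation a >= 0, injected
    as a shared variance component so the fitted regression intercept
    targets ``N a + 1`` exactly.  ``cross_intercept`` models sample overlap
    between the two studies and defaults to 0 (non-overlapping cohorts).
    """

    h2_1: float
    h2_2: float
    rg_true: float
    n1: int
    n2: int
    confound_a: float = 0.0
    cross_intercept: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for h in (self.h2_1, self.h2_2):
            if not 0.0 <= h <= 1.0:
                raise ConfigError("heritabilities must lie in [0, 1]")
        if abs(self.rg_true) > 1.0:
            raise ConfigError("|rg_true| must not exceed 1")
        if self.confound_a < 0:
            raise ConfigError("confound_a must be non-negative")


@dataclass(frozen=True)
class MRScenario:
    """A two-sample MR scenario with known causal structure.

    ``beta_causal`` is the true effect of the exposure on the outcome per
    unit exposure.  Pleiotropy modes: ``none``; ``balanced`` (direct
    effects N(0, pleiotropy_sd), mean zero — InSIDE holds); ``directional``
    (direct effects pleiotropy_mean + N(0, pleiotropy_sd) on the first
    ``n_invalid`` instruments, all by default); ``outlier`` (``n_outlier``
    instruments receive a single large direct effect ``outlier_effect``,
    default 10 standard errors of the outcome effect).  Per-instrument true
    exposure effects are drawn uniformly from ``gamma_range`` — strong
    instruments, so the MR relevance assumption holds with margin.
    """

    k_iv: int
    beta_causal: float = 0.1
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.005
    pleiotropy_mean: float = 0.05
    n_invalid: int | None = None
    n_outlier: int = 0
    outlier_effect: float | None = None
    gamma_range: tuple[float, float] = (0.15, 0.35)
    n1: int = 50_000
    n2: int = 200_000
    noise_scale: float = 1.0
    n_palindromic_intermediate: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.k_iv < 3:
            raise ConfigError("k_iv must be at least 3")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "outlier"):
            raise ConfigError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode == "outlier":
            if self.n_outlier < 1:
                raise ConfigError("outlier mode needs n_outlier >= 1")
            if self.k_iv < 4:
                raise ConfigError("outlier scenarios need k_iv >= 4")
        if self.n_invalid is not None and not 0 <= self.n_invalid <= self.k_iv:
            raise ConfigError("n_invalid out of range")


@dataclass
class MRTruth:
    """Latent parameters of a generated MR scenario."""

    beta_causal: float
    snp_ids: list[str]
    gamma: np.ndarray          # true per-instrument exposure effects
    alpha: np.ndarray          # latent direct (pleiotropic) effects
    invalid_ids: list[str]     # instruments with nonzero direct effect
    outlier_ids: list[str]
    mode: str

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"beta_causal={self.beta_causal}\n")
            fh.write(f"mode={self.mode}\n")
            fh.write(f"snp_ids={','.join(self.snp_ids)}\n")
            fh.write(f"gamma={','.join(f'{g:.10g}' for g in self.gamma)}\n")
            fh.write(f"alpha={','.join(f'{a:.10g}' for a in self.alpha)}\n")
            fh.write(f"invalid_ids={','.join(self.invalid_ids)}\n")
            fh.write(f"outlier_ids={','.join(self.outlier_ids)}\n")

    @classmethod
    def read(cls, path) -> "MRTruth":
        kv = {}
        for line in Path(path).read_text().splitlines():
            key, _, val = line.partition("=")
            kv[key] = val
        split = lambda v: v.split(",") if v else []
        return cls(
            beta_causal=float(kv["beta_causal"]), mode=kv["mode"],
            snp_ids=split(kv["snp_ids"]),
            gamma=np.array([float(x) for x in split(kv["gamma"])]),
            alpha=np.array([float(x) for x in split(kv["alpha"])]),
            invalid_ids=split(kv["invalid_ids"]),
            outlier_ids=split(kv["outlier_ids"]),
        )


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def simulate_panel(cfg: PanelConfig) -> ReferencePanel:
    """Dosage panel with exchangeable within-block genotype correlation.

    Haplotypes are thresholded latent Gaussians sharing a per-block factor
    of weight sqrt(within_block_r); genotypes are the sum of two
    independent haplotypes.  Monomorphic columns are redrawn so every
    variant is usable for LD computation.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m, b = cfg.n_ind, cfg.m_snps, cfg.block_size
    n_blocks = m // b
    freqs = rng.uniform(*cfg.maf_range, size=m)
    thresh = stats.norm.ppf(freqs)

    def draw_haplotype():
        shared = np.repeat(rng.standard_normal((n, n_blocks)), b, axis=1)
        noise = rng.standard_normal((n, m))
        latent = np.sqrt(cfg.within_block_r) * shared + np.sqrt(1 - cfg.within_block_r) * noise
        return (latent < thresh).astype(float)

    dosages = draw_haplotype() + draw_haplotype()
    for _ in range(20):  # redraw monomorphic columns
        mono = np.flatnonzero(dosages.std(axis=0) == 0)
        if mono.size == 0:
            break
        repl = rng.standard_normal((n, 2 * mono.size))
        h1 = (repl[:, :mono.size] < thresh[mono]).astype(float)
        h2 = (repl[:, mono.size:] < thresh[mono]).astype(float)
        dosages[:, mono] = h1 + h2

    pairs = [_SAFE_PAIRS[i % len(_SAFE_PAIRS)] for i in range(m)]
    variants = pd.DataFrame({
        "snp_id": [f"pv{i:06d}" for i in range(m)],
        "chrom": 1 + np.arange(m) // max(1, -(-m // 22)),
        "pos": 10_000 + 5_000 * np.arange(m),
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "maf": freqs,
    })
    blocks = np.repeat(np.arange(n_blocks), b)
    return ReferencePanel(dosages, variants, blocks=blocks)


# ---------------------------------------------------------------------------
# bivariate GWAS under the LDSC expectation model
# ---------------------------------------------------------------------------

def simulate_ld_scores(m_snps: int, seed: int = 0, mean_excess: float = 4.0,
                       shape: float = 2.0) -> LdScores:
    """Synthetic LD-score distribution: l = 1 + Gamma(shape, mean_excess/shape).

    Mimics the right-skewed genome-wide LD-score distribution at desk
    scale; every score is at least the self-term 1.
    """
    rng = np.random.default_rng(seed)
    values = 1.0 + rng.gamma(shape, mean_excess / shape, size=m_snps)
    per_chrom = -(-m_snps // 22)
    variants = pd.DataFrame({
        "snp_id": [f"sv{i:07d}" for i in range(m_snps)],
        "chrom": 1 + np.arange(m_snps) // per_chrom,
        "pos": 10_000 + 5_000 * (np.arange(m_snps) % per_chrom),
    })
    return LdScores.from_values(values, variants)


def _sumstats_frame(variants: pd.DataFrame, z: np.ndarray, n: int,
                    eaf: np.ndarray, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    se = 1.0 / np.sqrt(n)
    return pd.DataFrame({
        "snp_id": variants["snp_id"].to_numpy(),
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "eaf": eaf,
        "beta": z * se,
        "se": np.full(len(z), se),
        "pvalue": np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
        "n": float(n),
    })


def _scramble(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Randomly re-encode records (allele swap / strand complement) without
    changing their meaning, to exercise harmonization."""
    from .sumstats_io import _COMPLEMENT
    df = df.copy()
    mode = rng.integers(0, 4, size=len(df))  # 0 keep, 1 swap, 2 complement, 3 both
    swap = (mode == 1) | (mode == 3)
    comp = (mode == 2) | (mode == 3)
    ea, oa = df["effect_allele"].copy(), df["other_allele"].copy()
    df.loc[swap, "effect_allele"] = oa[swap]
    df.loc[swap, "other_allele"] = ea[swap]
    df.loc[swap, "beta"] = -df.loc[swap, "beta"]
    df.loc[swap, "eaf"] = 1.0 - df.loc[swap, "eaf"]
    df.loc[comp, "effect_allele"] = df.loc[comp, "effect_allele"].map(_COMPLEMENT)
    df.loc[comp, "other_allele"] = df.loc[comp, "other_allele"].map(_COMPLEMENT)
    return df


def simulate_bivariate_gwas(scores_or_panel, cfg: BivariateGwasConfig,
                            scramble_frames: bool = False,
                            trait_labels: tuple[str, str] = ("trait1", "trait2"),
                            ) -> tuple[SumStats, SumStats]:
    """Paired z-scores satisfying the LDSC expectation model exactly.

    Per variant j with LD score l_j the generated pair has
    ``Var(z_t) = N_t h2_t l_j / M + N_t a + 1`` and covariance
    ``sqrt(N1 N2) rg sqrt(h2_1 h2_2) l_j / M + cross_intercept``; betas are
    z / sqrt(N) with standard error 1 / sqrt(N).
    """
    if isinstance(scores_or_panel, ReferencePanel):
        scores = compute_ld_scores(scores_or_panel)
    else:
        scores = scores_or_panel
    l = scores.values
    m = len(l)
    variants = scores.df
    rng = np.random.default_rng(cfg.seed)

    v1 = cfg.n1 * cfg.h2_1 * l / m + cfg.n1 * cfg.confound_a + 1.0
    v2 = cfg.n2 * cfg.h2_2 * l / m + cfg.n2 * cfg.confound_a + 1.0
    cov = (np.sqrt(cfg.n1 * cfg.n2) * cfg.rg_true
           * np.sqrt(cfg.h2_1 * cfg.h2_2) * l / m + cfg.cross_intercept)
    e1, e2 = rng.standard_normal((2, m))
    z1 = np.sqrt(v1) * e1
    resid = np.clip(v2 - cov ** 2 / v1, 0.0, None)
    z2 = (cov / np.sqrt(v1)) * e1 + np.sqrt(resid) * e2

    eaf = rng.uniform(0.05, 0.95, size=m)
    pairs = [_SAFE_PAIRS[i] for i in rng.integers(0, len(_SAFE_PAIRS), size=m)]
    df1 = _sumstats_frame(variants, z1, cfg.n1, eaf, pairs)
    df2 = _sumstats_frame(variants, z2, cfg.n2, eaf, pairs)
    if scramble_frames:
        df2 = _scramble(df2, rng)
    ss1 = SumStats.from_frame(trait_labels[0], df1, n_default=cfg.n1, validate=False)
    ss2 = SumStats.from_frame(trait_labels[1], df2, n_default=cfg.n2, validate=False)
    return ss1, ss2


# ---------------------------------------------------------------------------
# MR scenarios
# ---------------------------------------------------------------------------

def simulate_mr_scenario(sc: MRScenario) -> tuple[SumStats, SumStats, MRTruth]:
    """Exposure and outcome summary statistics for ``k_iv`` instruments.

    Observed exposure effects are the true effects plus sampling noise at
    scale 1/sqrt(n1) (redrawn in the rare event an instrument's p-value
    exceeds the suggestive threshold, so instruments qualify by
    construction); observed outcome effects are
    ``beta_causal * gamma + alpha + noise / sqrt(n2)``.
    """
    rng = np.random.default_rng(sc.seed)
    k = sc.k_iv
    gamma = rng.uniform(*sc.gamma_range, size=k)
    alpha = np.zeros(k)
    outlier_idx: np.ndarray = np.array([], dtype=int)
    if sc.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, sc.pleiotropy_sd, size=k)
    elif sc.pleiotropy_mode == "directional":
        n_inv = k if sc.n_invalid is None else sc.n_invalid
        alpha[:n_inv] = sc.pleiotropy_mean + sc.pleiotropy_sd * rng.standard_normal(n_inv)
    elif sc.pleiotropy_mode == "outlier":
        outlier_idx = rng.choice(k, size=sc.n_outlier, replace=False)
        effect = sc.outlier_effect if sc.outlier_effect is not None else 10.0 / np.sqrt(sc.n2)
        alpha[outlier_idx] = effect

    se1, se2 = 1.0 / np.sqrt(sc.n1), 1.0 / np.sqrt(sc.n2)
    beta_exp = gamma + sc.noise_scale * se1 * rng.standard_normal(k)
    if sc.noise_scale > 0:
        z_min = stats.norm.isf(_EXPOSURE_P_MAX / 2.0)
        for _ in range(100):
            weak = np.abs(beta_exp / se1) < z_min
            if not weak.any():
                break
            beta_exp[weak] = gamma[weak] + sc.noise_scale * se1 * rng.standard_normal(int(weak.sum()))
    beta_out = sc.beta_causal * gamma + alpha + sc.noise_scale * se2 * rng.standard_normal(k)

    pairs = [_SAFE_PAIRS[i] for i in rng.integers(0, len(_SAFE_PAIRS), size=k)]
    eaf = rng.uniform(0.1, 0.9, size=k)
    # avoid accidental intermediate-band frequencies for non-palindromic pairs
    for i in range(sc.n_palindromic_intermediate):
        pairs[i] = ("A", "T")
        eaf[i] = 0.5
    variants = pd.DataFrame({
        "snp_id": [f"iv{i:04d}" for i in range(k)],
        "chrom": 1 + (np.arange(k) % 22),
        "pos": 1_000_000 + 20_000_000 * (np.arange(k) // 22),
    })

    def frame(beta, n, se):
        z = beta / se
        return pd.DataFrame({
            "snp_id": variants["snp_id"], "chrom": variants["chrom"],
            "pos": variants["pos"],
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "eaf": eaf, "beta": beta, "se": np.full(k, se),
            "pvalue": np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
            "n": float(n),
        })

    exposure = SumStats.from_frame("exposure", frame(beta_exp, sc.n1, se1),
                                   n_default=sc.n1, validate=False)
    outcome = SumStats.from_frame("outcome", frame(beta_out, sc.n2, se2),
                                  n_default=sc.n2, validate=False)
    ids = list(variants["snp_id"])
    truth = MRTruth(
        beta_causal=sc.beta_causal, snp_ids=ids, gamma=gamma, alpha=alpha,
        invalid_ids=[ids[i] for i in np.flatnonzero(alpha != 0)],
        outlier_ids=[ids[i] for i in sorted(outlier_idx)],
        mode=sc.pleiotropy_mode,
    )
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# multi-exposure screen battery
# ---------------------------------------------------------------------------

def simulate_screen_battery(scores: LdScores, n_exposures: int = 5,
                            planted: int = 0, rg_planted: float = -0.6,
                            h2_exposure: float = 0.4, h2_outcome: float = 0.3,
                            n1: int = 2_000, n2: int = 20_000,
                            seed: int = 0) -> tuple[SumStats, list[SumStats], dict]:
    """One outcome plus ``n_exposures`` exposures, one genetically
    correlated with the outcome (index ``planted``), the rest null.

    The default exposure sample size (2,000) emulates a single
    microbiome-GWAS-scale cohort and yields on the order of ten
    suggestive-threshold instruments per exposure; the outcome emulates a
    larger disease GWAS."""
    rng = np.random.default_rng(seed)
    l = scores.values
    m = len(l)
    variants = scores.df
    v_out = n2 * h2_outcome * l / m + 1.0
    z_out = np.sqrt(v_out) * rng.standard_normal(m)
    eaf = rng.uniform(0.05, 0.95, size=m)
    pairs = [_SAFE_PAIRS[i] for i in rng.integers(0, len(_SAFE_PAIRS), size=m)]
    outcome = SumStats.from_frame(
        "outcome", _sumstats_frame(variants, z_out, n2, eaf, pairs),
        n_default=n2, validate=False)

    exposures = []
    for e in range(n_exposures):
        v1 = n1 * h2_exposure * l / m + 1.0
        if e == planted:
            cov = np.sqrt(n1 * n2) * rg_planted * np.sqrt(h2_exposure * h2_outcome) * l / m
            resid = np.clip(v1 - cov ** 2 / v_out, 0.0, None)
            z = (cov / v_out) * z_out + np.sqrt(resid) * rng.standard_normal(m)
        else:
            z = np.sqrt(v1) * rng.standard_normal(m)
        exposures.append(SumStats.from_frame(
            f"exposure_{e}", _sumstats_frame(variants, z, n1, eaf, pairs),
            n_default=n1, validate=False))
    truth = {"planted": planted, "rg_planted": rg_planted,
             "h2_exposure": h2_exposure, "h2_outcome": h2_outcome}
    return outcome, exposures, truth
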