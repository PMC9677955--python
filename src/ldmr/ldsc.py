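"""LD-score regression: heritability, confounding intercept, genetic
covariance and genetic correlation from GWAS summary statistics.

Model: under a polygenic architecture the expected association chi-square
of variant j is ``E[chi2_j] = N h2 l_j / M + N a + 1``, where l_j is the
LD score, M the variant count, N the sample size and ``a`` the contribution
of confounding (cryptic relatedness, stratification).  A weighted linear
regression of chi2 on l therefore estimates h2 from the slope (times M/N)
while the intercept minus one estimates the mean confounding inflation.
For two traits, regressing the per-variant product z1*z2 on l estimates the
genetic covariance (slope times M/sqrt(N1 N2)); the genetic correlation rg
normalizes it by the geometric mean of the component heritabilities.

Uncertainty comes from a delete-one-block jackknife over contiguous blocks
of variants; for rg the full ratio statistic is jackknifed, so the standard
error reflects the uncertainty of all three regressions jointly.

Regression weights are the baseline heteroskedasticity proxy 1/max(l, 1);
the reference software's fuller iterative variance weights are out of scope
(recorded in the fit metadata).  The intercept is always estimated freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import RankDeficiencyError, UndefinedRgError, ConfigError
from .ldscore import LdScores
from .sumstats_io import SumStats, harmonize_pair

DEFAULT_N_BLOCKS = 200
#: |rg| beyond which the estimate gets a quality flag (never clamped)
RG_FLAG_LIMIT = 1.25


@dataclass
class LdscFit:
    """Single-trait (h2) or cross-trait (gencov) regression fit."""

    h2: float
    intercept: float
    se_h2: float
    se_intercept: float
    n_snps_used: int
    n_blocks: int
    meta: dict = field(default_factory=dict)


@dataclass
class RgEstimate:
    rg: float
    se_rg: float
    p_rg: float
    gencov: float
    h2_1: LdscFit
    h2_2: LdscFit
    n_snps_used: int
    n_blocks: int
    flags: list[str] = field(default_factory=list)


def _block_bounds(n: int, n_blocks: int) -> np.ndarray:
    """Split points of ``n`` items into ``n_blocks`` contiguous blocks."""
    if not 2 <= n_blocks <= n:
        raise ConfigError(f"need 2 <= n_blocks <= n ({n_blocks} vs {n})")
    return np.linspace(0, n, n_blocks + 1).round().astype(int)


def _auto_blocks(n_snps: int, n_blocks: int) -> int:
    """Default 200 blocks, reduced for small data so each block holds
    around 50 variants or more."""
    return max(2, min(n_blocks, n_snps // 50 if n_snps >= 100 else 2))


def _suffstats(x: np.ndarray, w: np.ndarray, ys: list[np.ndarray],
               bounds: np.ndarray) -> np.ndarray:
    """Per-block weighted sufficient statistics for straight-line fits.

    Returns array of shape (n_blocks, 3 + 2 * len(ys)):
    [sum w, sum w x, sum w x^2, (sum w y, sum w x y) per y].
    """
    cols = [w, w * x, w * x * x]
    for y in ys:
        cols += [w * y, w * x * y]
    mat = np.column_stack(cols)
    cum = np.zeros((len(bounds), mat.shape[1]))
    cum[1:] = np.cumsum(mat, axis=0)[bounds[1:] - 1]
    return cum[1:] - cum[:-1]


def _line_from_stats(s: np.ndarray, y_index: int):
    """Slope/intercept of WLS line from sufficient statistics.

    ``s`` may be a single stats vector or a matrix of them (vectorized over
    delete-one-block totals).
    """
    s = np.atleast_2d(s)
    sw, swx, swxx = s[:, 0], s[:, 1], s[:, 2]
    swy, swxy = s[:, 3 + 2 * y_index], s[:, 4 + 2 * y_index]
    det = sw * swxx - swx ** 2
    if np.any(np.abs(det) <= 1e-12 * np.maximum(sw * swxx, 1e-300)):
        raise RankDeficiencyError(
            "regression design is rank-deficient (LD scores all identical?)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy - slope * swx) / sw
    return slope, intercept


def wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares straight line; returns (slope, intercept)."""
    bounds = np.array([0, len(x)])
    s = _suffstats(np.asarray(x, float), np.asarray(w, float),
                   [np.asarray(y, float)], bounds).sum(axis=0)
    slope, intercept = _line_from_stats(s, 0)
    return float(slope[0]), float(intercept[0])


def _jackknife_se(pseudo: np.ndarray) -> float:
    """Delete-one-block jackknife SE from the B leave-one-out estimates."""
    pseudo = pseudo[np.isfinite(pseudo)]
    b = len(pseudo)
    if b < 2:
        return float("nan")
    return float(np.sqrt((b - 1) / b * np.sum((pseudo - pseudo.mean()) ** 2)))


def block_jackknife_se(statistic, data, n_blocks: int) -> float:
    """Generic delete-one-block jackknife SE of ``statistic``.

    ``data`` is an array or a tuple of equal-length arrays; blocks are
    contiguous along the first axis.  ``statistic`` receives the reduced
    array(s) and returns a scalar.
    """
    arrays = data if isinstance(data, tuple) else (data,)
    n = len(arrays[0])
    bounds = _block_bounds(n, n_blocks)
    pseudo = np.empty(n_blocks)
    for b in range(n_blocks):
        keep = np.r_[0:bounds[b], bounds[b + 1]:n]
        reduced = tuple(a[keep] for a in arrays)
        pseudo[b] = statistic(*reduced) if isinstance(data, tuple) else statistic(reduced[0])
    return _jackknife_se(pseudo)


def _regression_weights(l: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(l, 1.0)


def estimate_h2(ss: SumStats, scores: LdScores, m_total: int | None = None,
                n: float | None = None, n_blocks: int = DEFAULT_N_BLOCKS,
                chisq_cap: float | str | None = None) -> LdscFit:
    """Observed-scale SNP heritability and confounding intercept.

    Regresses chi2 = z^2 on the LD score with weights 1/max(l, 1);
    ``h2 = slope * M / N``.  ``chisq_cap`` optionally removes extreme
    chi-square variants (``"auto"`` caps at max(80, 0.001 N)); off by
    default and logged in ``meta`` when applied.
    """
    merged = ss.df[["snp_id", "beta", "se"]].merge(
        scores.df[["snp_id", "L2"]], on="snp_id")
    merged = merged[np.isfinite(merged["L2"])]
    if len(merged) < 2:
        raise RankDeficiencyError("fewer than 2 variants with LD scores")
    l = merged["L2"].to_numpy()
    if np.ptp(l) == 0:
        raise RankDeficiencyError("all LD scores identical")
    z = (merged["beta"] / merged["se"]).to_numpy()
    chi2 = z ** 2
    n_eff = float(n) if n is not None else ss.mean_n()
    m = int(m_total) if m_total is not None else len(scores)

    n_capped = 0
    if chisq_cap is not None:
        cap = max(80.0, 0.001 * n_eff) if chisq_cap == "auto" else float(chisq_cap)
        keep = chi2 <= cap
        n_capped = int((~keep).sum())
        l, chi2 = l[keep], chi2[keep]

    w = _regression_weights(l)
    n_blocks = _auto_blocks(len(l), n_blocks)
    bounds = _block_bounds(len(l), n_blocks)
    per_block = _suffstats(l, w, [chi2], bounds)
    total = per_block.sum(axis=0)
    slope, intercept = _line_from_stats(total, 0)
    slope_d, inter_d = _line_from_stats(total[None, :] - per_block, 0)

    return LdscFit(
        h2=float(slope[0] * m / n_eff),
        intercept=float(intercept[0]),
        se_h2=_jackknife_se(slope_d * m / n_eff),
        se_intercept=_jackknife_se(inter_d),
        n_snps_used=len(l),
        n_blocks=n_blocks,
        meta={"weights": "1/max(l,1)", "m_total": m, "n": n_eff,
              "chisq_capped": n_capped},
    )


def estimate_rg(ss1: SumStats, ss2: SumStats, scores: LdScores,
                m_total: int | None = None, n1: float | None = None,
                n2: float | None = None,
                n_blocks: int = DEFAULT_N_BLOCKS) -> RgEstimate:
    """Genetic correlation between two traits by cross-trait LDSC.

    The two studies are harmonized onto a common allele frame first; the
    slope of z1*z2 on l gives the genetic covariance, normalized by the
    component heritability fits.  The jackknife deletes each variant block
    from all three regressions jointly and re-evaluates the full ratio
    statistic, so ``se_rg`` propagates every component's uncertainty.
    """
    pair = harmonize_pair(ss1, ss2)
    merged = pair.df.merge(scores.df[["snp_id", "L2"]], on="snp_id")
    merged = merged[np.isfinite(merged["L2"])]
    if len(merged) < 2:
        raise RankDeficiencyError("fewer than 2 harmonized variants with LD scores")
    l = merged["L2"].to_numpy()
    if np.ptp(l) == 0:
        raise RankDeficiencyError("all LD scores identical")
    z1 = (merged["beta_exp"] / merged["se_exp"]).to_numpy()
    z2 = (merged["beta_out"] / merged["se_out"]).to_numpy()
    n1_eff = float(n1) if n1 is not None else ss1.mean_n()
    n2_eff = float(n2) if n2 is not None else ss2.mean_n()
    m = int(m_total) if m_total is not None else len(scores)

    w = _regression_weights(l)
    n_blocks = _auto_blocks(len(l), n_blocks)
    bounds = _block_bounds(len(l), n_blocks)
    per_block = _suffstats(l, w, [z1 ** 2, z2 ** 2, z1 * z2], bounds)
    total = per_block.sum(axis=0)

    def components(s):
        s1, i1 = _line_from_stats(s, 0)
        s2, i2 = _line_from_stats(s, 1)
        sx, ix = _line_from_stats(s, 2)
        h2_1 = s1 * m / n1_eff
        h2_2 = s2 * m / n2_eff
        gencov = sx * m / np.sqrt(n1_eff * n2_eff)
        return h2_1, h2_2, gencov, i1, i2, ix

    h2_1, h2_2, gencov, i1, i2, ix = components(total[None, :])
    if h2_1[0] <= 0 or h2_2[0] <= 0:
        raise UndefinedRgError(
            f"non-positive component heritability (h2_1={h2_1[0]:.4g}, "
            f"h2_2={h2_2[0]:.4g}); rg undefined")
    rg = float(gencov[0] / np.sqrt(h2_1[0] * h2_2[0]))

    h1_d, h2_d, gc_d, i1_d, i2_d, _ = components(total[None, :] - per_block)
    with np.errstate(invalid="ignore"):
        prod = h1_d * h2_d
        rg_d = np.where((h1_d > 0) & (h2_d > 0), gc_d / np.sqrt(np.abs(prod)), np.nan)
    se_rg = _jackknife_se(rg_d)
    p_rg = (float(min(1.0, max(2.0 * stats.norm.sf(abs(rg) / se_rg), 1e-300)))
            if se_rg > 0 else 1.0)

    flags = []
    if abs(rg) > RG_FLAG_LIMIT:
        flags.append("rg_out_of_range")
    n_bad = int((~np.isfinite(rg_d)).sum())
    if n_bad:
        flags.append(f"jackknife_blocks_dropped:{n_bad}")

    def fit(h, i, h_d, i_d, n_eff):
        return LdscFit(h2=float(h[0]), intercept=float(i[0]),
                       se_h2=_jackknife_se(h_d), se_intercept=_jackknife_se(i_d),
                       n_snps_used=len(l), n_blocks=n_blocks,
                       meta={"m_total": m, "n": n_eff})

    return RgEstimate(
        rg=rg, se_rg=se_rg, p_rg=p_rg, gencov=float(gencov[0]),
        h2_1=fit(h2_1, i1, h1_d, i1_d, n1_eff),
        h2_2=fit(h2_2, i2, h2_d, i2_d, n2_eff),
        n_snps_used=len(l), n_blocks=n_blocks, flags=flags,
    )
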