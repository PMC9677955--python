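"""Two-sample Mendelian-randomization estimators.

All five estimators operate on the per-instrument Wald ratios
``beta_out / beta_exp`` (first-order delta-method standard errors
``se_out / |beta_exp|`` by default; a second-order variant that also
propagates exposure uncertainty is available behind a flag):

* random-effects IVW — inverse-variance-weighted mean, the primary method;
  multiplicative random effects inflate the SE by sqrt(Q/(k-1)) when the
  heterogeneity statistic exceeds its degrees of freedom, never deflate;
* MR-Egger — weighted regression of outcome on exposure effects with a
  free intercept (average directional pleiotropy); exposure effects are
  oriented non-negative first;
* weighted median — consistent when at least half the weight comes from
  valid instruments;
* simple and weighted mode — kernel-density modal estimate, consistent
  when the largest homogeneous cluster of instruments is valid.

Estimates are reported per unit exposure together with exp(beta) as an
odds ratio and a 95% CI; p-values are two-sided normal (bootstrap-SE based
for the median and mode estimators).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError

_Z95 = float(stats.norm.ppf(0.975))

METHODS = ("IVW-RE", "Egger", "weighted-median", "simple-mode", "weighted-mode")


@dataclass
class MRResult:
    method: str
    beta: float
    se: float
    pvalue: float
    k: int
    extra: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - _Z95 * self.se, self.beta + _Z95 * self.se)

    @property
    def or_ci95(self) -> tuple[float, float]:
        lo, hi = self.ci95
        return (float(np.exp(lo)), float(np.exp(hi)))


@dataclass
class EggerIntercept:
    intercept: float
    se: float
    pvalue: float


def _iv_frame(iv) -> pd.DataFrame:
    return iv.df if hasattr(iv, "df") else iv


def wald_ratios(iv, second_order: bool = False):
    """Per-instrument causal ratios and SEs.

    Returns ``(ratios, ses, frame, excluded_ids)``; instruments with a zero
    exposure effect carry no information about the ratio and are excluded
    with a log entry.
    """
    df = _iv_frame(iv)
    zero = df["beta_exp"] == 0
    excluded = list(df.loc[zero, "snp_id"])
    df = df.loc[~zero]
    if df.empty:
        raise InsufficientInstrumentsError("no instrument with nonzero exposure effect")
    bx = df["beta_exp"].to_numpy(dtype=float)
    by = df["beta_out"].to_numpy(dtype=float)
    sy = df["se_out"].to_numpy(dtype=float)
    ratios = by / bx
    se = sy / np.abs(bx)
    if second_order:
        sx = df["se_exp"].to_numpy(dtype=float)
        se = np.sqrt(sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4)
    return ratios, se, df, excluded


def _p_normal(beta: float, se: float) -> float:
    if se <= 0:
        return 1.0
    # floor keeps p strictly positive even for astronomical z-scores
    return float(min(1.0, max(2.0 * stats.norm.sf(abs(beta) / se), 1e-300)))


def ivw_random_effects(iv, second_order: bool = False) -> MRResult:
    """Multiplicative random-effects IVW — the primary causal estimate."""
    ratios, se, df, _ = wald_ratios(iv, second_order)
    k = len(ratios)
    if k < 2:
        raise InsufficientInstrumentsError(f"IVW needs >= 2 instruments, got {k}")
    w = 1.0 / se ** 2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratios - beta) ** 2))
    inflation = float(np.sqrt(max(1.0, q / (k - 1))))
    se_re = se_fixed * inflation
    return MRResult("IVW-RE", beta, se_re, _p_normal(beta, se_re), k,
                    extra={"q": q, "df_q": k - 1, "inflation": inflation,
                           "se_fixed": se_fixed})


def _egger_wls(df: pd.DataFrame):
    """Oriented weighted Egger regression; returns the fit pieces."""
    bx = df["beta_exp"].to_numpy(dtype=float)
    by = df["beta_out"].to_numpy(dtype=float)
    sy = df["se_out"].to_numpy(dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)  # orient exposure effects non-negative
    x = bx * sign
    y = by * sign
    w = 1.0 / sy ** 2
    sw, swx, swxx = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    det = sw * swxx - swx ** 2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy - slope * swx) / sw
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid ** 2))
    k = len(x)
    # multiplicative overdispersion, floored at 1 (same convention as IVW)
    phi = max(1.0, q / (k - 2)) if k > 2 else 1.0
    var_slope = phi * sw / det
    var_int = phi * swxx / det
    return slope, intercept, np.sqrt(var_slope), np.sqrt(var_int), q, k


def mr_egger(iv) -> tuple[MRResult, EggerIntercept]:
    """Egger regression: slope = causal estimate, intercept = average
    directional pleiotropy."""
    _, _, df, _ = wald_ratios(iv)
    if len(df) < 3:
        raise InsufficientInstrumentsError(
            f"Egger needs >= 3 instruments, got {len(df)}")
    slope, intercept, se_slope, se_int, q, k = _egger_wls(df)
    result = MRResult("Egger", float(slope), float(se_slope),
                      _p_normal(slope, se_slope), k,
                      extra={"q_rucker": q, "df_q": k - 2})
    egger_int = EggerIntercept(float(intercept), float(se_int),
                               _p_normal(intercept, se_int))
    return result, egger_int


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cw = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cw, r))


def _bootstrap_draws(df: pd.DataFrame, n_boot: int, rng: np.random.Generator):
    bx = df["beta_exp"].to_numpy(dtype=float)
    by = df["beta_out"].to_numpy(dtype=float)
    sx = df["se_exp"].to_numpy(dtype=float)
    sy = df["se_out"].to_numpy(dtype=float)
    bxs = bx + sx * rng.standard_normal((n_boot, len(bx)))
    bys = by + sy * rng.standard_normal((n_boot, len(by)))
    bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
    return bxs, bys, sy


def weighted_median(iv, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Inverse-variance-weighted 50th percentile of the Wald ratios, with a
    parametric-bootstrap standard error."""
    ratios, se, df, _ = wald_ratios(iv)
    k = len(ratios)
    if k < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= 3 instruments, got {k}")
    est = _weighted_median(ratios, 1.0 / se ** 2)

    rng = np.random.default_rng(seed)
    bxs, bys, sy = _bootstrap_draws(df, n_boot, rng)
    rb = bys / bxs
    wb = (bxs / sy) ** 2
    order = np.argsort(rb, axis=1)
    rs = np.take_along_axis(rb, order, axis=1)
    ws = np.take_along_axis(wb, order, axis=1)
    cw = (np.cumsum(ws, axis=1) - 0.5 * ws) / np.sum(ws, axis=1, keepdims=True)
    idx = np.clip((cw < 0.5).sum(axis=1), 1, k - 1)
    rows = np.arange(n_boot)
    c0, c1 = cw[rows, idx - 1], cw[rows, idx]
    r0, r1 = rs[rows, idx - 1], rs[rows, idx]
    frac = np.where(c1 > c0, (0.5 - c0) / np.where(c1 > c0, c1 - c0, 1.0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)  # matches np.interp at the boundaries
    boots = r0 + frac * (r1 - r0)
    se_boot = float(np.std(boots, ddof=1))
    return MRResult("weighted-median", est, se_boot, _p_normal(est, se_boot), k,
                    extra={"n_boot": n_boot, "seed": seed})


def _mode_estimate(ratios: np.ndarray, weights: np.ndarray,
                   bandwidth_factor: float) -> float:
    """Kernel-density mode with a MAD-based bandwidth rule."""
    k = len(ratios)
    mad = np.median(np.abs(ratios - np.median(ratios)))
    spread = min(np.std(ratios, ddof=1) if k > 1 else 0.0, 1.4826 * mad) \
        if mad > 0 else (np.std(ratios, ddof=1) if k > 1 else 0.0)
    h = bandwidth_factor * 0.9 * spread * k ** (-0.2)
    if not np.isfinite(h) or h <= 0:
        # degenerate density: return the ratio carrying the most weight
        uniq, inv = np.unique(ratios, return_inverse=True)
        totals = np.bincount(inv, weights=weights)
        return float(uniq[np.argmax(totals)])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[np.argmax(dens)])


def mode_estimators(iv, bandwidth_factor: float = 1.0, weighted: bool = False,
                    n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Mode-based estimate: unweighted kernel mode of the Wald ratios
    (simple mode) or inverse-variance-weighted (weighted mode)."""
    ratios, se, df, _ = wald_ratios(iv)
    k = len(ratios)
    if k < 3:
        raise InsufficientInstrumentsError(
            f"mode estimators need >= 3 instruments, got {k}")
    weights = 1.0 / se ** 2 if weighted else np.ones(k)
    est = _mode_estimate(ratios, weights / weights.sum(), bandwidth_factor)

    rng = np.random.default_rng(seed)
    bxs, bys, sy = _bootstrap_draws(df, n_boot, rng)
    rb = bys / bxs
    boots = np.empty(n_boot)
    for b in range(n_boot):
        wb = (bxs[b] / sy) ** 2 if weighted else np.ones(k)
        boots[b] = _mode_estimate(rb[b], wb / wb.sum(), bandwidth_factor)
    se_boot = float(np.std(boots, ddof=1))
    name = "weighted-mode" if weighted else "simple-mode"
    return MRResult(name, est, se_boot, _p_normal(est, se_boot), k,
                    extra={"bandwidth_factor": bandwidth_factor,
                           "n_boot": n_boot, "seed": seed})


def simple_mode(iv, **kw) -> MRResult:
    return mode_estimators(iv, weighted=False, **kw)


def weighted_mode(iv, **kw) -> MRResult:
    return mode_estimators(iv, weighted=True, **kw)


def run_all_methods(iv, n_boot: int = 1000, seed: int = 0):
    """All five estimators on one instrument set.

    Returns ``(results_table, egger_intercept)`` with one row per method:
    method, nsnp, beta, se, pvalue, OR, CI_low, CI_high.
    """
    ivw = ivw_random_effects(iv)
    egger, egger_int = mr_egger(iv)
    wm = weighted_median(iv, n_boot=n_boot, seed=seed)
    sm = mode_estimators(iv, weighted=False, n_boot=n_boot, seed=seed + 1)
    wmo = mode_estimators(iv, weighted=True, n_boot=n_boot, seed=seed + 2)
    rows = []
    for res in (ivw, egger, wm, sm, wmo):
        lo, hi = res.or_ci95
        rows.append({"method": res.method, "nsnp": res.k, "beta": res.beta,
                     "se": res.se, "pvalue": res.pvalue, "OR": res.odds_ratio,
                     "CI_low": lo, "CI_high": hi})
    return pd.DataFrame(rows), egger_int


def scatter_export(iv, results: pd.DataFrame,
                   egger_intercept: EggerIntercept | None = None) -> pd.DataFrame:
    """Per-instrument effects plus each method's fitted line, as plot-ready
    tab-separated data (points then one `line` row per method)."""
    df = _iv_frame(iv)
    pts = df[["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"]].copy()
    pts.insert(0, "kind", "point")
    pts["method"] = ""
    pts["slope"] = np.nan
    pts["intercept"] = np.nan
    lines = []
    for row in results.itertuples(index=False):
        intercept = (egger_intercept.intercept
                     if row.method == "Egger" and egger_intercept else 0.0)
        lines.append({"kind": "line", "snp_id": "", "beta_exp": np.nan,
                      "se_exp": np.nan, "beta_out": np.nan, "se_out": np.nan,
                      "method": row.method, "slope": row.beta,
                      "intercept": intercept})
    return pd.concat([pts, pd.DataFrame(lines)], ignore_index=True)
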