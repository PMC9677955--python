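"""Heterogeneity and horizontal-pleiotropy diagnostics for MR.

* Cochran's Q — heterogeneity of the Wald ratios about the IVW estimate,
  chi-square with k-1 degrees of freedom;
* Rucker's Q — residual heterogeneity about the Egger fit (free intercept),
  chi-square with k-2 df; nested within Cochran's Q, so Q' <= Q always;
* Egger intercept test — two-sided test of zero average directional
  pleiotropy, with the same multiplicative overdispersion floor as IVW;
* MR-PRESSO — simulation-based residual sum of squares battery with its
  canonical role assignment: the *global* test detects horizontal
  pleiotropy from the leave-one-out residual RSS, the *outlier* test flags
  individual instruments (Bonferroni-corrected against the simulated
  reference), and the *distortion* test quantifies how much the causal
  estimate shifts once flagged outliers are removed.  When nothing is
  flagged the distortion test reports a not-applicable marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .mr_estimators import (EggerIntercept, _egger_wls, _iv_frame,
                            ivw_random_effects, mr_egger, wald_ratios)


def cochran_q(iv, ivw_beta: float | None = None):
    """Q = sum_j w_j (ratio_j - beta_IVW)^2 with w_j = 1/se_j^2.

    Returns ``(Q, df, p)``; p from the chi-square distribution with k-1
    degrees of freedom.
    """
    ratios, se, _, _ = wald_ratios(iv)
    k = len(ratios)
    if k < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    w = 1.0 / se ** 2
    if ivw_beta is None:
        ivw_beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - ivw_beta) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def rucker_q(iv, egger_fit=None):
    """Residual heterogeneity about the Egger regression (k-2 df)."""
    frame = _iv_frame(iv)
    if len(frame) < 3:
        raise InsufficientInstrumentsError("Rucker's Q needs >= 3 instruments")
    _, _, df_kept, _ = wald_ratios(iv)
    slope, intercept, _, _, q, k = _egger_wls(df_kept)
    if egger_fit is not None:  # recompute about a supplied fit
        bx = df_kept["beta_exp"].to_numpy(dtype=float)
        by = df_kept["beta_out"].to_numpy(dtype=float)
        sy = df_kept["se_out"].to_numpy(dtype=float)
        sign = np.where(bx < 0, -1.0, 1.0)
        resid = by * sign - egger_fit[1] - egger_fit[0] * bx * sign
        q = float(np.sum(resid ** 2 / sy ** 2))
    df = k - 2
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(iv) -> EggerIntercept:
    """Two-sided test of a zero Egger intercept (no directional pleiotropy)."""
    _, egger_int = mr_egger(iv)
    return egger_int


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_p: pd.DataFrame          # snp_id, p_raw, p_bonferroni
    outliers: list[str]
    distortion_pct: float | None     # None <=> "NA" (no outliers flagged)
    distortion_p: float | None
    beta_all: float
    beta_no_outliers: float | None
    n_sim: int
    seed: int


def _ivw_slope(bx, by, sy):
    """IVW causal estimate as the weighted through-origin slope of outcome
    on exposure effects (identical to the weighted mean of Wald ratios)."""
    w = 1.0 / sy ** 2
    return np.sum(w * bx * by, axis=-1) / np.sum(w * bx * bx, axis=-1)


def _loo_slopes(bx, by, sy):
    w = 1.0 / sy ** 2
    num = np.sum(w * bx * by, axis=-1, keepdims=True) - w * bx * by
    den = np.sum(w * bx * bx, axis=-1, keepdims=True) - w * bx * bx
    return num / den


def mr_presso(iv, n_sim: int = 1000, seed: int = 0, sig_level: float = 0.05
              ) -> PressoResult:
    """Pleiotropy residual-sum-of-squares and outlier battery.

    The observed weighted RSS of leave-one-out IVW predictions is compared
    against ``n_sim`` parametric simulations generated under no pleiotropy
    (outcome effects drawn around their leave-one-out predictions, exposure
    effects around their observed values).  Per-instrument outlier p-values
    use the same simulated reference with Bonferroni correction over k; the
    distortion test compares the estimate shift after outlier removal with
    a distribution of shifts from random same-size instrument subsets.
    """
    _, _, df, _ = wald_ratios(iv)
    k = len(df)
    if k < 4:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs >= 4 instruments, got {k}")
    rng = np.random.default_rng(seed)
    bx = df["beta_exp"].to_numpy(dtype=float)
    by = df["beta_out"].to_numpy(dtype=float)
    sx = df["se_exp"].to_numpy(dtype=float)
    sy = df["se_out"].to_numpy(dtype=float)
    ids = list(df["snp_id"])
    w = 1.0 / sy ** 2

    beta_loo = _loo_slopes(bx[None, :], by[None, :], sy[None, :])[0]
    res_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    bxs = bx + sx * rng.standard_normal((n_sim, k))
    bys = beta_loo * bx + sy * rng.standard_normal((n_sim, k))
    loo_s = _loo_slopes(bxs, bys, sy[None, :])
    res_sim = w * (bys - loo_s * bxs) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))
    p_raw = (1 + np.sum(res_sim >= res_obs[None, :], axis=0)) / (1 + n_sim)
    p_bonf = np.minimum(1.0, p_raw * k)
    outlier_p = pd.DataFrame({"snp_id": ids, "p_raw": p_raw,
                              "p_bonferroni": p_bonf})
    flagged = [ids[j] for j in np.flatnonzero(p_bonf < sig_level)]

    beta_all = float(_ivw_slope(bx, by, sy))
    beta_no = distortion_pct = distortion_p = None
    if flagged:
        keep = ~np.isin(ids, flagged)
        if keep.sum() >= 2:
            beta_no = float(_ivw_slope(bx[keep], by[keep], sy[keep]))
            distortion_pct = 100.0 * (beta_all - beta_no) / abs(beta_no)
            nb = int(keep.sum())
            # reference: shifts from random subsets of the non-outlier size
            perm = np.argsort(rng.random((n_sim, k)), axis=1)[:, :nb]
            bxp, byp, syp = bx[perm], by[perm], sy[perm]
            beta_sub = _ivw_slope(bxp, byp, syp)
            d_sim = 100.0 * (beta_all - beta_sub) / np.abs(beta_sub)
            d_obs = distortion_pct
            distortion_p = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs)))
                                 / (1 + n_sim))
    return PressoResult(rss_obs, global_p, outlier_p, flagged,
                        distortion_pct, distortion_p, beta_all, beta_no,
                        n_sim, seed)


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------

@dataclass
class SensitivityReport:
    """Full diagnostic battery for one exposure-outcome pair."""

    q_ivw: float
    df_ivw: int
    p_q_ivw: float
    q_egger: float
    df_egger: int
    p_q_egger: float
    egger_intercept: float
    se_intercept: float
    p_intercept: float
    presso_global_p: float | None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_p: float | None = None
    meta: dict = field(default_factory=dict)

    def to_row(self, exposure: str = "", outcome: str = "") -> dict:
        """One tab-separated row: heterogeneity p's, pleiotropy p, outlier
        list (NA when empty) and global p."""
        return {
            "exposure": exposure,
            "outcome": outcome,
            "cochran_q_p": self.p_q_ivw,
            "rucker_q_p": self.p_q_egger,
            "egger_intercept_p": self.p_intercept,
            "distortion_outliers": (",".join(self.presso_outliers)
                                    if self.presso_outliers else "NA"),
            "global_test_p": (self.presso_global_p
                              if self.presso_global_p is not None else "NA"),
        }


def sensitivity_battery(iv, n_sim: int = 1000, seed: int = 0,
                        sig_level: float = 0.05) -> SensitivityReport:
    """Run Q, Q', the Egger intercept test and MR-PRESSO on one IVSet.

    MR-PRESSO requires at least 4 instruments; with fewer its fields are
    reported as missing rather than failing the whole battery.
    """
    ivw = ivw_random_effects(iv)
    q, dfq, pq = cochran_q(iv, ivw.beta)
    qe, dfe, pqe = rucker_q(iv)
    egger_int = egger_intercept_test(iv)
    try:
        presso = mr_presso(iv, n_sim=n_sim, seed=seed, sig_level=sig_level)
        gp, outl, dp = presso.global_p, presso.outliers, presso.distortion_p
    except InsufficientInstrumentsError:
        gp, outl, dp = None, [], None
    return SensitivityReport(
        q_ivw=q, df_ivw=dfq, p_q_ivw=pq,
        q_egger=qe, df_egger=dfe, p_q_egger=pqe,
        egger_intercept=egger_int.intercept, se_intercept=egger_int.se,
        p_intercept=egger_int.pvalue,
        presso_global_p=gp, presso_outliers=outl, presso_distortion_p=dp,
        meta={"n_sim": n_sim, "seed": seed, "sig_level": sig_level},
    )
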