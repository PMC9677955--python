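"""Two-stage screen: cross-trait LDSC over many exposures against one
outcome with multiple-testing control, then the full MR + sensitivity
battery on every exposure that clears the suggestive band.

Tiers follow the screening convention: ``significant`` below the
Bonferroni threshold alpha/n_tests, ``suggestive`` between that threshold
and alpha, ``null`` above alpha.  Benjamini-Hochberg q-values are reported
per exposure alongside the raw p-values.  Exposures whose genetic
correlation cannot be estimated (e.g. a non-positive fitted component
heritability) are assigned tier ``null`` with a reason, so a screen never
silently shrinks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .errors import LdmrError
from .iv_selection import IVConfig, select_instruments
from .ldsc import DEFAULT_N_BLOCKS, estimate_rg
from .ldscore import LdScores
from .mr_estimators import run_all_methods, scatter_export
from .panel import ReferencePanel
from .sensitivity import sensitivity_battery
from .sumstats_io import SumStats

logger = logging.getLogger(__name__)

SCREEN_COLUMNS = ("trait", "rg", "se", "p", "fdr", "tier", "reason")


@dataclass
class MultipleTestingResult:
    bonferroni_threshold: float        # full precision alpha / n_tests
    bonferroni_display: float          # rounded to 2 significant figures
    qvalues: np.ndarray                # BH step-up, clamped to [p, 1]


def adjust_pvalues(ps, alpha: float = 0.05,
                   method: str = "fdr_bh") -> MultipleTestingResult:
    """Bonferroni threshold plus per-test BH q-values.

    The threshold alpha/len(ps) is stored at full precision and rounded to
    two significant figures for display (0.05 over 74 tests displays as
    0.00068).
    """
    ps = np.asarray(list(ps), dtype=float)
    if ps.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(ps)) or np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    threshold = alpha / ps.size
    display = float(f"{threshold:.2g}")
    _, qvalues, _, _ = multipletests(ps, alpha=alpha, method=method)
    qvalues = np.clip(qvalues, ps, 1.0)
    return MultipleTestingResult(threshold, display, qvalues)


@dataclass(frozen=True)
class ScreenConfig:
    alpha: float = 0.05
    fdr_method: str = "fdr_bh"
    mr_tiers: tuple[str, ...] = ("significant", "suggestive")
    iv: IVConfig = field(default_factory=IVConfig)
    n_blocks: int = DEFAULT_N_BLOCKS
    m_total: int | None = None
    n_boot: int = 1000
    presso_nsim: int = 1000

    def to_dict(self) -> dict:
        d = asdict(self)
        d["iv"]["confounder_snps"] = sorted(self.iv.confounder_snps)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        d = dict(d)
        iv = dict(d.pop("iv", {}))
        if "confounder_snps" in iv:
            iv["confounder_snps"] = frozenset(iv["confounder_snps"])
        if "palindrome_band" in iv:
            iv["palindrome_band"] = tuple(iv["palindrome_band"])
        if "mr_tiers" in d:
            d["mr_tiers"] = tuple(d["mr_tiers"])
        return cls(iv=IVConfig(**iv), **d)


@dataclass
class ScreenReport:
    """Everything one screen run produces.

    ``screen`` mirrors the screen-table layout (trait, rg, se, p, fdr plus
    tier/reason); ``mr`` holds the five-method causal-estimate blocks;
    ``sensitivity`` one diagnostics row per MR-eligible exposure;
    ``scatter`` plot-ready per-instrument data; ``manifest`` echoes the
    configuration and master seed so a run can be reproduced from it alone.
    """

    screen: pd.DataFrame
    mr: pd.DataFrame
    sensitivity: pd.DataFrame
    scatter: pd.DataFrame
    manifest: dict
    log: list[str] = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.screen.to_csv(out / "screen.tsv", sep="\t", index=False)
        self.mr.to_csv(out / "mr.tsv", sep="\t", index=False)
        self.sensitivity.to_csv(out / "sensitivity.tsv", sep="\t", index=False)
        self.scatter.to_csv(out / "scatter.tsv", sep="\t", index=False)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)
        (out / "run.log").write_text("\n".join(self.log) + "\n")


def run_screen(outcome: SumStats, exposures: list[SumStats],
               scores: LdScores, panel: ReferencePanel | None = None,
               cfg: ScreenConfig | None = None, seed: int = 0) -> ScreenReport:
    """LDSC screen then MR on suggestive-or-better exposures.

    Per-exposure failures are recorded (tier ``null`` with a reason) and do
    not abort the remaining exposures.  Identical inputs, configuration and
    master seed produce byte-identical reports.
    """
    cfg = cfg or ScreenConfig()
    log: list[str] = [f"ldmr {__version__} screen over "
                      f"{len(exposures)} exposures, seed={seed}"]
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2 ** 31 - 1, size=max(1, len(exposures)))

    rows = []
    for i, exposure in enumerate(exposures):
        row = {"trait": exposure.trait_label, "rg": np.nan, "se": np.nan,
               "p": np.nan, "fdr": np.nan, "tier": "null", "reason": ""}
        try:
            est = estimate_rg(exposure, outcome, scores,
                              m_total=cfg.m_total, n_blocks=cfg.n_blocks)
            row.update(rg=est.rg, se=est.se_rg, p=est.p_rg)
            if est.flags:
                row["reason"] = ";".join(est.flags)
        except LdmrError as err:
            row["reason"] = f"rg_failed:{err}"
            log.append(f"{exposure.trait_label}: rg failed ({err})")
        rows.append(row)
    screen = pd.DataFrame(rows, columns=list(SCREEN_COLUMNS))

    tested = screen["p"].notna()
    if tested.any():
        adj = adjust_pvalues(screen.loc[tested, "p"], alpha=cfg.alpha,
                             method=cfg.fdr_method)
        screen.loc[tested, "fdr"] = adj.qvalues
        thr = adj.bonferroni_threshold
        log.append(f"bonferroni_threshold={adj.bonferroni_display:g} "
                   f"(full precision {thr:.6g})")
        sig = tested & (screen["p"] <= thr)
        sugg = tested & ~sig & (screen["p"] <= cfg.alpha)
        screen.loc[sig, "tier"] = "significant"
        screen.loc[sugg, "tier"] = "suggestive"
    else:
        log.append("no exposure produced a genetic-correlation estimate")
    if not exposures:
        log.append("warning: empty exposure list")

    mr_rows, sens_rows, scat_rows = [], [], []
    for i, exposure in enumerate(exposures):
        tier = screen.loc[screen["trait"] == exposure.trait_label, "tier"].iloc[0]
        if tier not in cfg.mr_tiers:
            continue
        sub_seed = int(sub_seeds[i])
        try:
            iv = select_instruments(exposure, outcome, panel, cfg.iv)
            results, egger_int = run_all_methods(iv, n_boot=cfg.n_boot,
                                                 seed=sub_seed)
            report = sensitivity_battery(iv, n_sim=cfg.presso_nsim,
                                         seed=sub_seed + 3)
        except LdmrError as err:
            log.append(f"{exposure.trait_label}: MR failed ({err})")
            screen.loc[screen["trait"] == exposure.trait_label,
                       "reason"] = f"mr_failed:{err}"
            continue
        results.insert(0, "exposure", exposure.trait_label)
        mr_rows.append(results)
        sens_rows.append(report.to_row(exposure.trait_label,
                                       outcome.trait_label))
        scat = scatter_export(iv, results, egger_int)
        scat.insert(0, "exposure", exposure.trait_label)
        scat_rows.append(scat)
        log.append(f"{exposure.trait_label}: k={iv.k} instruments, "
                   f"tier={tier}")

    empty_mr = pd.DataFrame(columns=["exposure", "method", "nsnp", "beta",
                                     "se", "pvalue", "OR", "CI_low", "CI_high"])
    manifest = {
        "package": "ldmr",
        "version": __version__,
        "seed": int(seed),
        "config": cfg.to_dict(),
        "outcome": outcome.trait_label,
        "exposures": [e.trait_label for e in exposures],
        "n_score_variants": len(scores),
    }
    return ScreenReport(
        screen=screen,
        mr=pd.concat(mr_rows, ignore_index=True) if mr_rows else empty_mr,
        sensitivity=pd.DataFrame(sens_rows),
        scatter=(pd.concat(scat_rows, ignore_index=True)
                 if scat_rows else pd.DataFrame()),
        manifest=manifest,
        log=log,
    )
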