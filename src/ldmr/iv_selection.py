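"""Six-step instrument quality control for two-sample MR.

The protocol, applied in order to an exposure/outcome pair:

1. keep exposure variants with p below the suggestive threshold (1e-5);
2. LD-clump the survivors greedily (r2 < 0.001 within 10,000 kb);
3. exclude variants associated with the outcome (p < 1e-5);
4. exclude variants on a user-supplied confounder list (a local stand-in
   for a confounder-association database query);
5. drop palindromic variants of intermediate allele frequency during
   harmonization (other palindromes are oriented by frequency and kept);
6. substitute a high-LD proxy (r2 >= 0.8 in the panel) for instruments
   absent from the outcome study.

Every candidate surviving step 1 appears exactly once in the kept set or
the exclusion log, with the step and a machine-readable reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInstrumentError
from .panel import ReferencePanel
from .sumstats_io import (DEFAULT_PALINDROME_BAND, SumStats, harmonize_pair)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IVConfig:
    """Thresholds of the quality-control protocol."""

    p_exposure_max: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    p_outcome_max: float = 1e-5
    confounder_snps: frozenset = frozenset()
    proxy_r2_min: float = 0.8
    palindrome_band: tuple[float, float] = DEFAULT_PALINDROME_BAND

    def __post_init__(self):
        if not (0 < self.p_exposure_max <= 1 and 0 < self.p_outcome_max <= 1):
            raise ValueError("p-value thresholds must lie in (0, 1]")
        if not 0 <= self.clump_r2 <= 1 or not 0 <= self.proxy_r2_min <= 1:
            raise ValueError("r2 thresholds must lie in [0, 1]")


@dataclass
class IVSet:
    """Harmonized instrument table with full exclusion provenance.

    ``df`` columns: snp_id, ea, oa, beta_exp, se_exp, p_exp, beta_out,
    se_out, p_out, eaf, proxy_used, proxy_id, f_stat, no_ld_info.
    ``exclusions`` columns: snp_id, step, reason.
    """

    df: pd.DataFrame
    exclusions: pd.DataFrame
    config: IVConfig = field(default_factory=IVConfig)

    @property
    def k(self) -> int:
        return len(self.df)

    @classmethod
    def from_harmonized(cls, pair_df: pd.DataFrame,
                        config: IVConfig | None = None) -> "IVSet":
        df = pair_df.copy()
        df["proxy_used"] = df.get("proxy_used", False)
        df["proxy_id"] = df.get("proxy_id", "")
        df["f_stat"] = (df["beta_exp"] / df["se_exp"]) ** 2
        df["no_ld_info"] = df.get("no_ld_info", False)
        empty_log = pd.DataFrame(columns=["snp_id", "step", "reason"])
        return cls(df.reset_index(drop=True), empty_log, config or IVConfig())

    def write(self, prefix) -> None:
        prefix = Path(prefix)
        with open(prefix.with_suffix(".ivset.tsv"), "w") as fh:
            for key, val in asdict(self.config).items():
                if isinstance(val, frozenset):
                    val = ",".join(sorted(val))
                fh.write(f"# {key}={val}\n")
            self.df.to_csv(fh, sep="\t", index=False)
        self.exclusions.to_csv(prefix.with_suffix(".exclusions.tsv"),
                               sep="\t", index=False)

    @classmethod
    def read(cls, prefix) -> "IVSet":
        prefix = Path(prefix)
        df = pd.read_csv(prefix.with_suffix(".ivset.tsv"), sep="\t", comment="#")
        exc_path = prefix.with_suffix(".exclusions.tsv")
        exc = (pd.read_csv(exc_path, sep="\t") if exc_path.exists()
               else pd.DataFrame(columns=["snp_id", "step", "reason"]))
        return cls(df, exc)


def clump(candidates: pd.DataFrame, panel: ReferencePanel | None,
          r2_thresh: float = 0.001, distance_kb: float = 10_000.0):
    """Greedy LD clumping.

    Repeatedly keeps the remaining candidate with the smallest p-value and
    discards all others on the same chromosome within ``distance_kb`` whose
    panel r2 with it is at least ``r2_thresh``.  Candidates absent from the
    panel cannot be clumped and are kept with a ``no_ld_info`` flag.

    Returns ``(kept_ids, no_ld_ids, removed)`` where ``removed`` is a frame
    (snp_id, lead_snp, r2).
    """
    cand = candidates.sort_values(["pvalue", "snp_id"]).reset_index(drop=True)
    in_panel = (cand["snp_id"].map(lambda s: panel is not None and s in panel)
                .to_numpy())
    no_ld = list(cand.loc[~in_panel, "snp_id"])
    if no_ld:
        logger.warning("%d clump candidate(s) absent from panel kept "
                       "without LD information (flagged no_ld_info)", len(no_ld))
    sub = cand.loc[in_panel].reset_index(drop=True)
    kept: list[str] = []
    removed_rows = []
    if len(sub):
        r2 = panel.correlations(list(sub["snp_id"])) ** 2
        chrom = sub["chrom"].to_numpy()
        pos = sub["pos"].to_numpy(dtype=float)
        alive = np.ones(len(sub), dtype=bool)
        for i in range(len(sub)):  # already p-sorted
            if not alive[i]:
                continue
            kept.append(sub["snp_id"].iloc[i])
            near = (alive & (chrom == chrom[i])
                    & (np.abs(pos - pos[i]) <= distance_kb * 1_000.0)
                    & (r2[i] >= r2_thresh))
            near[i] = False
            for j in np.flatnonzero(near):
                removed_rows.append((sub["snp_id"].iloc[j],
                                     sub["snp_id"].iloc[i], float(r2[i, j])))
            alive &= ~near
            alive[i] = False
    removed = pd.DataFrame(removed_rows, columns=["snp_id", "lead_snp", "r2"])
    return kept + no_ld, no_ld, removed


def find_proxy(snp_id: str, target: SumStats, panel: ReferencePanel,
               r2_min: float = 0.8):
    """Best available LD proxy for ``snp_id`` among the target's variants.

    Returns ``(proxy_id, r)`` — the signed dosage correlation is needed to
    orient the proxy's effect — or ``(None, reason)`` when no panel variant
    reaches ``r2_min``.
    """
    if snp_id not in panel:
        return None, "snp_absent_from_panel"
    target_ids = [s for s in target.df["snp_id"] if s in panel and s != snp_id]
    if not target_ids:
        return None, "no_candidates_in_panel"
    r = panel.correlations([snp_id] + target_ids)[0, 1:]
    r2 = r ** 2
    ok = np.flatnonzero(r2 >= r2_min)
    if ok.size == 0:
        return None, "no_proxy_above_threshold"
    pos0 = float(panel.variants.set_index("snp_id").loc[snp_id, "pos"])
    pos = panel.variants.set_index("snp_id").loc[
        [target_ids[i] for i in ok], "pos"].to_numpy(dtype=float)
    order = sorted(range(ok.size),
                   key=lambda i: (-r2[ok[i]], abs(pos[i] - pos0), target_ids[ok[i]]))
    best = ok[order[0]]
    return target_ids[best], float(r[best])


def select_instruments(exposure: SumStats, outcome: SumStats,
                       panel: ReferencePanel | None,
                       cfg: IVConfig | None = None) -> IVSet:
    """Apply the full quality-control protocol; returns the surviving
    instruments with a complete per-variant exclusion log."""
    cfg = cfg or IVConfig()
    exc_rows: list[tuple[str, int, str]] = []

    # step 1: exposure association threshold
    cand = exposure.df[exposure.df["pvalue"] < cfg.p_exposure_max].copy()
    if cand.empty:
        raise EmptyInstrumentError(1, "no exposure variant below "
                                      f"p={cfg.p_exposure_max:g}")

    # step 2: LD clumping
    kept_ids, no_ld, removed = clump(cand, panel, cfg.clump_r2, cfg.clump_kb)
    for row in removed.itertuples(index=False):
        exc_rows.append((row.snp_id, 2, f"ld_r2={row.r2:.3f}_with_{row.lead_snp}"))
    cand = cand[cand["snp_id"].isin(kept_ids)]
    if cand.empty:
        raise EmptyInstrumentError(2, "clumping removed every candidate")

    # step 6 (executed here out of listed order because later steps need
    # outcome statistics): proxy substitution for instruments the outcome
    # study lacks
    out_ids = set(outcome.df["snp_id"])
    proxy_map: dict[str, tuple[str, float]] = {}
    for sid in cand["snp_id"]:
        if sid in out_ids:
            continue
        if panel is None:
            exc_rows.append((sid, 6, "missing_from_outcome_no_panel"))
            continue
        proxy, r = find_proxy(sid, outcome, panel, cfg.proxy_r2_min)
        if proxy is None:
            exc_rows.append((sid, 6, f"no_proxy:{r}"))
        else:
            proxy_map[sid] = (proxy, r)
    dropped6 = {r[0] for r in exc_rows if r[1] == 6}
    cand = cand[~cand["snp_id"].isin(dropped6)]
    if cand.empty:
        raise EmptyInstrumentError(6, "no instrument present in outcome or proxied")

    # build the outcome-side table, substituting proxies
    direct_ids = [s for s in cand["snp_id"] if s not in proxy_map]
    out_sub = outcome.df[outcome.df["snp_id"].isin(direct_ids)].copy()
    proxy_rows = []
    for sid, (proxy, r) in proxy_map.items():
        row = outcome.df[outcome.df["snp_id"] == proxy].iloc[0].copy()
        # orient the proxy's outcome effect to the original variant's
        # panel coding via the signed LD correlation
        row["beta"] = np.sign(r) * row["beta"]
        orig = cand[cand["snp_id"] == sid].iloc[0]
        row["snp_id"] = sid
        row["effect_allele"] = orig["effect_allele"]
        row["other_allele"] = orig["other_allele"]
        row["eaf"] = orig["eaf"]
        proxy_rows.append(row)
    if proxy_rows:
        out_sub = pd.concat([out_sub, pd.DataFrame(proxy_rows)], ignore_index=True)

    # step 3: outcome-association exclusion
    strong_out = set(out_sub.loc[out_sub["pvalue"] < cfg.p_outcome_max, "snp_id"])
    for sid in sorted(strong_out & set(cand["snp_id"])):
        exc_rows.append((sid, 3, f"outcome_p<{cfg.p_outcome_max:g}"))
    cand = cand[~cand["snp_id"].isin(strong_out)]
    if cand.empty:
        raise EmptyInstrumentError(3, "all instruments associated with outcome")

    # step 4: confounder-list exclusion
    conf = set(cfg.confounder_snps) & set(cand["snp_id"])
    for sid in sorted(conf):
        exc_rows.append((sid, 4, "confounder_associated"))
    cand = cand[~cand["snp_id"].isin(conf)]
    if cand.empty:
        raise EmptyInstrumentError(4, "all instruments on confounder list")

    # step 5: harmonization (palindrome handling, allele reconciliation)
    exp_sub = SumStats.from_frame(exposure.trait_label, cand, validate=False)
    out_keep = out_sub[out_sub["snp_id"].isin(set(cand["snp_id"]))]
    out_ss = SumStats.from_frame(outcome.trait_label, out_keep, validate=False)
    pair = harmonize_pair(exp_sub, out_ss, band=cfg.palindrome_band)
    for row in pair.exclusions.itertuples(index=False):
        exc_rows.append((row.snp_id, 5, row.reason))
    if pair.df.empty:
        raise EmptyInstrumentError(5, "harmonization removed every instrument")

    df = pair.df.copy()
    df["proxy_used"] = df["snp_id"].isin(proxy_map)
    df["proxy_id"] = df["snp_id"].map(lambda s: proxy_map.get(s, ("", 0.0))[0])
    df["f_stat"] = (df["beta_exp"] / df["se_exp"]) ** 2
    df["no_ld_info"] = df["snp_id"].isin(no_ld)
    exclusions = pd.DataFrame(exc_rows, columns=["snp_id", "step", "reason"])
    return IVSet(df.reset_index(drop=True), exclusions, cfg)
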