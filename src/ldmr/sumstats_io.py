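"""Reading, validation and pairwise harmonization of GWAS summary statistics.

A GWAS summary-statistics table has one row per variant: identifier,
chromosome, 1-based position, effect allele, other allele, effect-allele
frequency, additive effect size (beta), its standard error, p-value and
sample size.  :class:`SumStats` is the universal exchange object between
every stage of the package (LD-score regression, instrument selection,
Mendelian randomization).

Harmonization places two studies on a common effect-allele frame: swapped
allele orders flip the sign of the effect, complementary-strand codings are
re-mapped, irreconcilable allele pairs are dropped, and palindromic variants
(A/T or C/G, for which strand is ambiguous) are dropped when their allele
frequency is too close to 0.5 to resolve the orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, EmptyOverlapError, FormatError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names used throughout the package
STANDARD_COLUMNS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
)
MANDATORY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se")

#: default intermediate-frequency band for palindromic variants
DEFAULT_PALINDROME_BAND = (0.42, 0.58)

#: relative tolerance for the p-value vs z-score consistency check
P_Z_RELATIVE_TOL = 1e-3


@dataclass
class VariantRecord:
    """One variant's association summary for a single trait."""

    snp_id: str
    chrom: str = ""
    pos: int = 0
    effect_allele: str = "A"
    other_allele: str = "G"
    eaf: float | None = None
    beta: float = 0.0
    se: float = 1.0
    pvalue: float | None = None
    n: float | None = None

    @property
    def z(self) -> float:
        return self.beta / self.se


class PalindromeFlags(NamedTuple):
    palindromic: bool
    intermediate: bool


def complement_allele(a: str) -> str:
    return _COMPLEMENT[a]


def is_palindromic(rec, band: tuple[float, float] = DEFAULT_PALINDROME_BAND) -> PalindromeFlags:
    """Classify a variant as palindromic and/or of intermediate frequency.

    A palindromic variant carries alleles that are reverse complements of
    each other ({A,T} or {C,G}); its strand orientation cannot be resolved
    from the alleles alone.  ``intermediate`` is True when the effect-allele
    frequency lies inside ``band`` (or is missing — conservatively treated
    as unresolvable).
    """
    pal = _COMPLEMENT.get(rec.effect_allele) == rec.other_allele
    eaf = getattr(rec, "eaf", None)
    if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
        inter = True
    else:
        inter = band[0] <= eaf <= band[1]
    return PalindromeFlags(pal, pal and inter)


@dataclass
class SumStats:
    """A trait's per-variant association summary table.

    ``df`` holds the :data:`STANDARD_COLUMNS`; ``snp_id`` values are unique.
    ``drop_log`` counts rows removed during validation, keyed by a
    machine-readable reason code.
    """

    trait_label: str
    df: pd.DataFrame
    n_default: float | None = None
    drop_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.df) == 0:
            raise EmptyInputError(f"{self.trait_label}: zero valid rows")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def zscores(self) -> np.ndarray:
        return (self.df["beta"] / self.df["se"]).to_numpy()

    def mean_n(self) -> float:
        """Mean per-variant sample size, falling back to ``n_default``."""
        n = self.df["n"]
        if n.notna().any():
            return float(n.mean())
        if self.n_default is not None:
            return float(self.n_default)
        raise ValueError(f"{self.trait_label}: no sample size available")

    @classmethod
    def from_frame(cls, trait_label: str, df: pd.DataFrame,
                   n_default: float | None = None, validate: bool = True) -> "SumStats":
        if validate:
            df, log, _ = validate_frame(df, n_default=n_default)
        else:
            df, log = df.reset_index(drop=True), {}
        return cls(trait_label, df, n_default=n_default, drop_log=log)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def records(self) -> Iterable[VariantRecord]:
        for row in self.df.itertuples(index=False):
            yield VariantRecord(
                snp_id=row.snp_id, chrom=str(row.chrom), pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                beta=float(row.beta), se=float(row.se),
                pvalue=None if pd.isna(row.pvalue) else float(row.pvalue),
                n=None if pd.isna(row.n) else float(row.n),
            )


def validate_frame(df: pd.DataFrame, n_default: float | None = None):
    """Validate a raw summary-statistics frame.

    Returns ``(clean, drop_log, n_pz_discrepant)``.  Rows violating a hard
    invariant (bad alleles, non-positive SE, non-finite beta, out-of-range
    p-value, duplicate identifier) are dropped and counted; out-of-range
    allele frequencies are set to missing rather than dropped since ``eaf``
    is optional.  Where a p-value is present it is cross-checked against the
    two-sided normal p implied by z = beta/se and discrepancies are logged,
    never auto-corrected.
    """
    log: dict[str, int] = {}
    df = df.copy()
    for col in STANDARD_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(STANDARD_COLUMNS)]

    def drop(mask: pd.Series, reason: str):
        nonlocal df
        n_bad = int(mask.sum())
        if n_bad:
            log[reason] = log.get(reason, 0) + n_bad
            df = df.loc[~mask]

    drop(df["snp_id"].isna(), "missing_id")
    df["snp_id"] = df["snp_id"].astype(str)

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    bad_allele = (~df["effect_allele"].isin(VALID_BASES)
                  | ~df["other_allele"].isin(VALID_BASES))
    drop(bad_allele, "invalid_allele")
    drop(df["effect_allele"] == df["other_allele"], "identical_alleles")

    for col in ("eaf", "beta", "se", "pvalue", "n", "pos"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    drop(~np.isfinite(df["beta"]), "nonfinite_beta")
    drop(~(df["se"] > 0) | ~np.isfinite(df["se"]), "invalid_se")

    # eaf is optional: coerce out-of-range values to missing
    bad_eaf = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    if bad_eaf.any():
        log["eaf_set_missing"] = int(bad_eaf.sum())
        df.loc[bad_eaf, "eaf"] = np.nan

    drop(df["pvalue"].notna() & ((df["pvalue"] <= 0) | (df["pvalue"] > 1)),
         "invalid_pvalue")
    drop(df["n"].notna() & (df["n"] <= 0), "invalid_n")
    if n_default is not None:
        df["n"] = df["n"].fillna(float(n_default))

    drop(df["snp_id"].duplicated(keep="first"), "duplicate_id")

    # fill missing p-values from z; check present ones for consistency
    z = (df["beta"] / df["se"]).to_numpy()
    p_from_z = 2.0 * stats.norm.sf(np.abs(z))
    missing_p = df["pvalue"].isna()
    df.loc[missing_p, "pvalue"] = np.clip(p_from_z[missing_p.to_numpy()], 1e-300, 1.0)
    have_p = (~missing_p).to_numpy()
    n_discrepant = 0
    if have_p.any():
        p_obs = df["pvalue"].to_numpy()[have_p]
        p_exp = np.clip(p_from_z[have_p], 1e-300, 1.0)
        rel = np.abs(p_obs - p_exp) / np.maximum(p_obs, p_exp)
        n_discrepant = int((rel > P_Z_RELATIVE_TOL).sum())
        if n_discrepant:
            logger.warning(
                "%d variants have p-values inconsistent with beta/se "
                "(relative discrepancy > %g); values left as supplied",
                n_discrepant, P_Z_RELATIVE_TOL)
            log["pz_discrepant_warned"] = n_discrepant

    if len(df) == 0:
        raise EmptyInputError("zero valid rows after validation")
    return df.reset_index(drop=True), log, n_discrepant


def read_sumstats(path, dialect: Mapping[str, str] | None = None,
                  trait_label: str | None = None,
                  n_default: float | None = None) -> SumStats:
    """Read a tab-separated (optionally gzipped) summary-statistics file.

    ``dialect`` maps canonical column names (:data:`STANDARD_COLUMNS`) to the
    file's own header names, so differently-labelled dialects all load
    through the same path.  Rows failing validation are dropped with counted
    reasons in ``drop_log``.
    """
    raw = pd.read_csv(path, sep="\t")
    dialect = dict(dialect or {})
    rename = {src: std for std, src in dialect.items() if src in raw.columns}
    missing = [std for std, src in dialect.items()
               if std in MANDATORY_COLUMNS and src not in raw.columns]
    raw = raw.rename(columns=rename)
    missing += [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {sorted(set(missing))}")
    df, log, _ = validate_frame(raw, n_default=n_default)
    label = trait_label or str(path)
    return SumStats(label, df, n_default=n_default, drop_log=log)


# ---------------------------------------------------------------------------
# pairwise harmonization
# ---------------------------------------------------------------------------

HARMONIZED_COLUMNS = ("snp_id", "ea", "oa", "beta_exp", "se_exp", "p_exp",
                      "beta_out", "se_out", "p_out", "eaf", "action")


@dataclass
class HarmonizedPair:
    """Exposure/outcome table on a common effect-allele frame.

    ``df`` carries :data:`HARMONIZED_COLUMNS` plus ``chrom``/``pos``/
    ``eaf_out`` bookkeeping columns; ``exclusions`` lists every shared
    variant that was dropped, exactly once, with a machine-readable reason.
    """

    df: pd.DataFrame
    exclusions: pd.DataFrame
    band: tuple[float, float] = DEFAULT_PALINDROME_BAND

    def write(self, path) -> None:
        self.df[list(HARMONIZED_COLUMNS)].to_csv(path, sep="\t", index=False)


def _complement_series(s: pd.Series) -> pd.Series:
    return s.map(_COMPLEMENT)


def harmonize_pair(exposure: SumStats, outcome: SumStats,
                   band: tuple[float, float] = DEFAULT_PALINDROME_BAND) -> HarmonizedPair:
    """Align two studies' effects onto the exposure's effect-allele frame.

    For each shared identifier: identical allele pairs are kept; swapped
    pairs flip the outcome's effect sign and frequency; complementary-strand
    codings are complemented first and then treated the same way;
    irreconcilable pairs are dropped.  Palindromic variants are oriented by
    allele frequency when both frequencies are informative (outside
    ``band``), and dropped otherwise.
    """
    cols = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pvalue"]
    m = pd.merge(exposure.df[cols], outcome.df[cols[:1] + cols[3:]],
                 on="snp_id", suffixes=("_exp", "_out"))
    if m.empty:
        raise EmptyOverlapError(
            f"no shared variants between {exposure.trait_label!r} and "
            f"{outcome.trait_label!r}")

    ea_x = m["effect_allele_exp"]
    oa_x = m["other_allele_exp"]
    ea_o = m["effect_allele_out"]
    oa_o = m["other_allele_out"]
    cea_o = _complement_series(ea_o)
    coa_o = _complement_series(oa_o)

    same = (ea_o == ea_x) & (oa_o == oa_x)
    swap = (ea_o == oa_x) & (oa_o == ea_x)
    csame = (cea_o == ea_x) & (coa_o == oa_x)
    cswap = (cea_o == oa_x) & (coa_o == ea_x)
    pal = _complement_series(ea_x) == oa_x  # exposure pair is A/T or C/G
    matched = same | swap | csame | cswap

    eaf_x = m["eaf_exp"]
    eaf_o_raw = m["eaf_out"]
    # outcome eaf expressed for the outcome's stated effect allele; when the
    # stated pair is the (possibly complemented) swap of the exposure frame,
    # the aligned outcome frequency is 1 - eaf.
    plain_flip = (~pal) & (swap | cswap)

    action = pd.Series("same", index=m.index)
    action[plain_flip] = "flip"
    action[(~pal) & csame] = "complement"
    action[(~pal) & cswap] = "complement_flip"

    reason = pd.Series("", index=m.index)
    reason[~matched] = "allele_mismatch"

    # palindromic handling: orientation is resolvable only via frequency
    pal_inter = pal & matched & (
        eaf_x.isna() | eaf_o_raw.isna()
        | ((eaf_x >= band[0]) & (eaf_x <= band[1]))
        | ((eaf_o_raw >= band[0]) & (eaf_o_raw <= band[1]))
    )
    reason[pal_inter] = "palindromic_intermediate"
    pal_keep = pal & matched & ~pal_inter
    pal_flip = pal_keep & ((eaf_x - 0.5) * (eaf_o_raw - 0.5) < 0)
    action[pal_keep] = "palindromic_kept"
    action[pal_flip] = "palindromic_flipped"

    flip = plain_flip | pal_flip
    beta_out = m["beta_out"].where(~flip, -m["beta_out"])
    eaf_out_aligned = eaf_o_raw.where(~flip, 1.0 - eaf_o_raw)

    keep = matched & ~pal_inter
    out = pd.DataFrame({
        "snp_id": m["snp_id"],
        "chrom": m["chrom_exp"] if "chrom_exp" in m else m["chrom"],
        "pos": m["pos_exp"] if "pos_exp" in m else m["pos"],
        "ea": ea_x,
        "oa": oa_x,
        "beta_exp": m["beta_exp"],
        "se_exp": m["se_exp"],
        "p_exp": m["pvalue_exp"],
        "beta_out": beta_out,
        "se_out": m["se_out"],
        "p_out": m["pvalue_out"],
        "eaf": eaf_x.where(eaf_x.notna(), eaf_out_aligned),
        "eaf_out": eaf_out_aligned,
        "action": action,
    })
    exclusions = pd.DataFrame({
        "snp_id": m.loc[~keep, "snp_id"],
        "reason": reason[~keep],
    }).reset_index(drop=True)
    return HarmonizedPair(out.loc[keep].reset_index(drop=True), exclusions, band)
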