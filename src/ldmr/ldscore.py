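"""Per-variant LD scores from a reference panel.

The LD score of variant j is the sum of squared genotype correlations with
the variants in its window, including itself:  l_j = sum_k r2_jk.  It
measures how much genetic variation variant j tags, and is the regressor of
LD-score regression.  With only the self term, l_j = 1, matching the "+1"
baseline of the expectation model for the association chi-square statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel import ReferencePanel


@dataclass
class LdScores:
    """Per-variant LD scores keyed by snp_id.

    ``df`` columns: snp_id, chrom, pos, L2 (the conventional ldscore file
    layout).  Monomorphic variants carry a missing score and are listed in
    ``flagged``.
    """

    df: pd.DataFrame
    window: str = "all"
    adjusted: bool = False
    flagged: list[str] | None = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def values(self) -> np.ndarray:
        return self.df["L2"].to_numpy()

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "LdScores":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_values(cls, values, variants: pd.DataFrame) -> "LdScores":
        df = variants[["snp_id", "chrom", "pos"]].copy()
        df["L2"] = np.asarray(values, dtype=float)
        return cls(df, window="supplied")


def _groups(panel: ReferencePanel, window) -> tuple[str, list[np.ndarray]]:
    """Index groups within which all pairwise r2 are summed."""
    m = panel.m
    if window is None and panel.blocks is not None:
        labels = panel.blocks
        desc = "block"
        return desc, [np.flatnonzero(labels == b) for b in np.unique(labels)]
    chrom = panel.variants["chrom"].to_numpy()
    if window is None:
        return "chrom", [np.flatnonzero(chrom == c) for c in pd.unique(chrom)]
    if not (isinstance(window, int) and window >= 0):
        raise ConfigError("window must be a non-negative variant count or None")
    return f"±{window} variants", [np.arange(m)]  # windowing handled per-variant


def compute_ld_scores(panel: ReferencePanel, window: int | None = None,
                      adjust: bool = False) -> LdScores:
    """Sum of squared correlations of each variant with its window.

    ``window`` is a half-width in variant count (k variants each side,
    within the same chromosome); ``None`` uses the panel's LD blocks when
    recorded, otherwise whole chromosomes — adequate at the desk scales this
    package targets.  With ``adjust`` each r2 is replaced by the
    small-sample-unbiased r2 - (1 - r2)/(n_ind - 2), so adjusted scores
    never exceed unadjusted ones.
    """
    n = panel.n_ind
    xs = panel.standardized()
    mono = np.flatnonzero(np.isnan(xs[0]))
    scores = np.full(panel.m, np.nan)
    desc, groups = _groups(panel, window)

    def r2_block(idx):
        x = xs[:, idx]
        r = (x.T @ x) / (n - 1)
        r2 = r ** 2
        if adjust:
            r2 = r2 - (1.0 - r2) / (n - 2)
        return r2

    if window is None:
        for idx in groups:
            r2 = r2_block(idx)
            scores[idx] = np.nansum(r2, axis=1)
    else:
        chrom = panel.variants["chrom"].to_numpy()
        for j in range(panel.m):
            lo, hi = max(0, j - window), min(panel.m, j + window + 1)
            idx = np.arange(lo, hi)
            idx = idx[chrom[idx] == chrom[j]]
            xj = xs[:, j]
            r = (xs[:, idx].T @ xj) / (n - 1)
            r2 = r ** 2
            if adjust:
                r2 = r2 - (1.0 - r2) / (n - 2)
            scores[j] = np.nansum(r2)

    scores[mono] = np.nan
    return LdScores(
        df=pd.DataFrame({
            "snp_id": panel.variants["snp_id"],
            "chrom": panel.variants["chrom"],
            "pos": panel.variants["pos"],
            "L2": scores,
        }),
        window=desc,
        adjusted=adjust,
        flagged=[panel.variants["snp_id"].iloc[j] for j in mono],
    )
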