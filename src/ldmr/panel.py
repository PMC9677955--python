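"""Reference genotype panel: an individuals x variants dosage matrix.

The panel is the substrate for every LD computation in the package —
LD scores, clumping and proxy search.  Dosages count copies (0/1/2) of the
variant's effect allele as listed in the sidecar variant table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass
class ReferencePanel:
    """Dosage matrix (``n_ind`` x ``m``) plus a variant table.

    ``variants`` has columns snp_id, chrom, pos, effect_allele,
    other_allele, maf; ``blocks`` optionally labels each variant with an LD
    block index (block-exchangeable panels record this so windowing can
    follow the true block structure).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    blocks: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.dosages.ndim != 2:
            raise ConfigError("dosage matrix must be 2-D (individuals x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ConfigError("dosage columns and variant table length differ")
        self._index = {s: i for i, s in enumerate(self.variants["snp_id"])}

    @property
    def n_ind(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self._index[snp_id]]

    def standardized(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Column-standardized dosages; zero-variance columns become NaN."""
        x = self.dosages if idx is None else self.dosages[:, idx]
        x = x - x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sd > 0, x / sd, np.nan)

    def correlations(self, snp_ids: list[str]) -> np.ndarray:
        """Pearson correlation matrix of the named variants (NaN where a
        variant is monomorphic)."""
        idx = np.array([self._index[s] for s in snp_ids])
        xs = self.standardized(idx)
        return (xs.T @ xs) / (self.n_ind - 1)

    def write(self, prefix) -> None:
        prefix = Path(prefix)
        dos = pd.DataFrame(self.dosages, columns=self.variants["snp_id"])
        dos.to_csv(prefix.with_suffix(".dosages.tsv"), sep="\t", index=False)
        var = self.variants.copy()
        if self.blocks is not None:
            var["block"] = self.blocks
        var.to_csv(prefix.with_suffix(".variants.tsv"), sep="\t", index=False)

    @classmethod
    def read(cls, prefix) -> "ReferencePanel":
        prefix = Path(prefix)
        dos = pd.read_csv(prefix.with_suffix(".dosages.tsv"), sep="\t")
        var = pd.read_csv(prefix.with_suffix(".variants.tsv"), sep="\t")
        blocks = var.pop("block").to_numpy() if "block" in var.columns else None
        return cls(dos.to_numpy(dtype=float), var, blocks=blocks)
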