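"""Integer miRNA x sample count matrix with sample metadata.

The container every contrast starts from: rows are mature miRNAs, columns
are samples, and each sample carries a cell type (``preAC`` or ``AC``) and a
condition (``lean`` or ``obese``). Counts are raw (un-normalized)
non-negative integers, as produced by a quantification pipeline upstream of
this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CELL_TYPES = ("preAC", "AC")
CONDITIONS = ("lean", "obese")


class ValidationError(ValueError):
    """Raised when an input violates a documented structural contract."""


@dataclass
class CountMatrix:
    """Raw miRNA-seq counts plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = miRNA ids, columns =
        sample ids. Both axes must be unique.
    sample_meta
        DataFrame indexed by sample id with columns ``cell_type`` (preAC or
        AC) and ``condition`` (lean or obese). Every count column must have
        a metadata row.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate miRNA ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(
                f"samples without metadata: {sorted(missing)}"
            )
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("counts contain non-finite values")
        if (vals < 0).any():
            raise ValidationError("counts contain negative values")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]
        bad_ct = set(self.sample_meta["cell_type"]) - set(CELL_TYPES)
        if bad_ct:
            raise ValidationError(f"unknown cell_type values: {sorted(bad_ct)}")
        bad_cond = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown condition values: {sorted(bad_cond)}")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples(self, cell_type: str | None = None,
                condition: str | None = None) -> list[str]:
        """Sample ids matching the given cell type and/or condition."""
        meta = self.sample_meta
        mask = pd.Series(True, index=meta.index)
        if cell_type is not None:
            mask &= meta["cell_type"] == cell_type
        if condition is not None:
            mask &= meta["condition"] == condition
        return list(meta.index[mask])

    # ------------------------------------------------------------------ I/O

    def write(self, counts_path: str | Path, sample_sheet_path: str | Path) -> None:
        """Write counts TSV (first column = miRNA id) and sample sheet TSV."""
        out = self.counts.copy()
        out.index.name = "mirna_id"
        out.to_csv(counts_path, sep="\t")
        meta = self.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(sample_sheet_path, sep="\t")

    @classmethod
    def read(cls, counts_path: str | Path,
             sample_sheet_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(sample_sheet_path, sep="\t", index_col=0,
                           dtype={"cell_type": str, "condition": str})
        return cls(counts=counts, sample_meta=meta)
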