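"""Gene-by-sample count container with group metadata."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GROUPS


@dataclass
class CountMatrix:
    """Integer counts (genes x samples) plus a sample design table.

    ``data`` is indexed by gene ID with one column per sample;
    ``samples`` is indexed by sample ID with columns ``group`` (one of
    :data:`asediverge.config.GROUPS`) and ``replicate``.
    """

    data: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.samples.index):
            raise ValueError("count columns and sample table rows must match in order")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        unknown = set(self.samples["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown sample groups: {sorted(unknown)}")
        if not np.issubdtype(self.data.to_numpy().dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def columns_for(self, group: str) -> list[str]:
        """Sample IDs belonging to one group, in design order."""
        if group not in GROUPS:
            raise ValueError(f"unknown group label {group!r}")
        return list(self.samples.index[self.samples["group"] == group])

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.data.loc[genes], self.samples.copy())
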