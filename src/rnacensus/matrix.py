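"""Counting-matrix containers shared by the quantification stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Integer features x samples matrix plus per-sample metadata.

    ``meta`` is indexed by sample id and carries at least the columns
    ``specimen``, ``batch`` and ``subject_id``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("duplicate feature ids")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        self.meta = self.meta.loc[self.counts.columns]

    @classmethod
    def from_sheet(cls, counts: pd.DataFrame, sample_sheet: pd.DataFrame) -> "CountMatrix":
        meta = sample_sheet.set_index("sample_id")
        return cls(counts=counts, meta=meta)

    def specimen_groups(self) -> pd.Series:
        return self.meta["specimen"]


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized (real-valued) matrix with provenance flags."""

    values: pd.DataFrame
    meta: pd.DataFrame
    size_factors: pd.Series
    batch_corrected: bool = False
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        if (self.values.to_numpy() < -1e-12).any():
            raise ValueError("normalized values must be non-negative")
        self.meta = self.meta.loc[self.values.columns]

    def specimen_groups(self) -> pd.Series:
        return self.meta["specimen"]

    def log10p(self) -> pd.DataFrame:
        return np.log10(self.values + 1.0)
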