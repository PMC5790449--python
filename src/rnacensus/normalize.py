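"""Library-size normalization (median-of-ratios) and batch centering.

The size factor of a sample is the median, over features with all-positive
counts, of the ratio of the sample's count to the feature's geometric mean
across samples. When no all-positive feature exists the implementation falls
back to total-count scaling with a warning.

Batch (study) structure is removed by per-feature per-batch median centering
on the log10(x+1) scale — a documented, fully testable surrogate for latent
factor estimation: each batch's median is subtracted and the grand median
added back, so planted batch offsets are removed exactly and each feature's
grand median is preserved.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import CountMatrix, NormalizedMatrix


def size_factors(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column)."""
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        warnings.warn(
            "no feature has positive counts in every sample; "
            "falling back to total-count scaling",
            RuntimeWarning,
            stacklevel=2,
        )
        totals = values.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot compute size factors: empty sample column")
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=counts.columns, name="size_factor")
    sub = values[positive]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(
    matrix: CountMatrix, factors: pd.Series | None = None
) -> NormalizedMatrix:
    """Divide each column by its size factor; metadata is preserved."""
    if factors is None:
        factors = size_factors(matrix)
    factors = factors.reindex(matrix.counts.columns)
    if factors.isna().any():
        raise ValueError("size factors missing for some samples")
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    values = matrix.counts.astype(float).div(factors, axis=1)
    return NormalizedMatrix(
        values=values,
        meta=matrix.meta.copy(),
        size_factors=factors,
    )


def batch_center(
    normalized: NormalizedMatrix,
    batches: Mapping[str, str] | pd.Series,
    specimen: str = "plasma",
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """Remove per-batch offsets within one specimen group.

    Operates per feature on log10(x + pseudocount): subtracts each batch's
    median, adds back the grand median over the corrected samples, then
    inverse-transforms (clipped at zero). Samples outside ``specimen`` are
    untouched.
    """
    batches = pd.Series(dict(batches) if not isinstance(batches, pd.Series) else batches)
    in_scope = normalized.meta.index[normalized.meta["specimen"] == specimen]
    in_scope = [s for s in in_scope if s in batches.index]
    values = normalized.values.copy()
    notes = list(normalized.notes)
    if len(in_scope) == 0:
        notes.append(f"batch centering skipped: no {specimen!r} samples with a batch")
        return NormalizedMatrix(
            values=values,
            meta=normalized.meta.copy(),
            size_factors=normalized.size_factors,
            batch_corrected=False,
            notes=notes,
        )
    group_batches = batches.loc[in_scope]
    if group_batches.nunique() < 2:
        notes.append("batch centering skipped: fewer than two batches")
        return NormalizedMatrix(
            values=values,
            meta=normalized.meta.copy(),
            size_factors=normalized.size_factors,
            batch_corrected=False,
            notes=notes,
        )
    for batch, members in group_batches.groupby(group_batches).groups.items():
        if len(members) == 1:
            warnings.warn(
                f"batch {batch!r} has a single sample; centering on that value",
                RuntimeWarning,
                stacklevel=2,
            )
    log = np.log10(values[in_scope] + pseudocount)
    grand_median = log.median(axis=1)
    centered = log.copy()
    for _, members in group_batches.groupby(group_batches).groups.items():
        cols = list(members)
        batch_median = log[cols].median(axis=1)
        centered[cols] = log[cols].sub(batch_median, axis=0).add(grand_median, axis=0)
    values[in_scope] = np.clip(10.0**centered - pseudocount, 0.0, None)
    return NormalizedMatrix(
        values=values,
        meta=normalized.meta.copy(),
        size_factors=normalized.size_factors,
        batch_corrected=True,
        notes=notes,
    )
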