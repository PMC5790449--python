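"""Reference-RNA stability ranking by the MAD/median ratio.

MAD is the unscaled median absolute deviation, median(|x - median(x)|); the
ratio to the median is scale-invariant, so any consistency constant would
cancel in the ranking anyway. Candidates default to the features detected
specifically in the specimen under consideration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import NormalizedMatrix


def mad(values: np.ndarray) -> float:
    """Unscaled median absolute deviation."""
    values = np.asarray(values, dtype=float)
    return float(np.median(np.abs(values - np.median(values))))


@dataclass(frozen=True)
class StabilityRecord:
    feature: str
    specimen: str
    median: float
    mad: float
    ratio: float
    rank: int


def stability_rank(
    normalized: NormalizedMatrix,
    specimen: str,
    candidates: Sequence[str],
) -> list[StabilityRecord]:
    """Rank candidate features by ascending MAD/median within one specimen.

    Candidates with median 0 are excluded with a warning (undefined ratio).
    Ties break toward the higher median, then by feature id.
    """
    groups = normalized.specimen_groups()
    cols = groups.index[groups == specimen]
    if len(cols) == 0:
        raise ValueError(f"empty specimen group {specimen!r}")
    sub = normalized.values.loc[list(candidates), cols]
    scored = []
    for feature in sub.index:
        x = sub.loc[feature].to_numpy(dtype=float)
        med = float(np.median(x))
        if med <= 0:
            warnings.warn(
                f"candidate {feature!r} has median 0 in {specimen!r}; excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        m = mad(x)
        scored.append((m / med, -med, feature, med, m))
    scored.sort()
    return [
        StabilityRecord(
            feature=feature, specimen=specimen, median=med, mad=m,
            ratio=ratio, rank=i + 1,
        )
        for i, (ratio, _negmed, feature, med, m) in enumerate(scored)
    ]


def records_to_frame(records: Sequence[StabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "specimen": r.specimen,
                "median": r.median,
                "mad": r.mad,
                "ratio": r.ratio,
                "rank": r.rank,
            }
            for r in records
        ],
        columns=["feature", "specimen", "median", "mad", "ratio", "rank"],
    )


def reference_report(
    records: Sequence[StabilityRecord], k: int = 10
) -> pd.DataFrame:
    """Top-k records per specimen, ordered by ascending ratio.

    With fewer than ``k`` candidates all are returned and the ``note``
    column says so. The output is invariant to the input row order.
    """
    frame = records_to_frame(list(records))
    out = []
    for specimen, sub in frame.groupby("specimen"):
        sub = sub.sort_values(["ratio", "median", "feature"], ascending=[True, False, True])
        top = sub.head(k).copy()
        top["note"] = (
            "" if len(sub) >= k else f"only {len(sub)} candidates (requested {k})"
        )
        out.append(top)
    if not out:
        return frame.assign(note="")
    return pd.concat(out, ignore_index=True)
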