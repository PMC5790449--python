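"""Detection census: per-specimen detection thresholding, Venn decomposition
into common/specific sets, top-expressed features, PCA embedding and
paired-subject cross-specimen correlation.

A feature is *detected* in a specimen group when its median normalized count
in that group is strictly greater than the threshold (default 20). The Venn
partition places every detected feature in exactly the cell matching its
detection pattern, so cells are disjoint and exhaustive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .matrix import NormalizedMatrix

DETECTION_THRESHOLD = 20.0


@dataclass
class DetectionTable:
    """Per-feature group medians, detected flags and detection patterns."""

    frame: pd.DataFrame  # median_<g>, detected_<g> columns, index = feature
    groups: tuple[str, ...]
    threshold: float

    def pattern(self, feature: str) -> frozenset[str]:
        row = self.frame.loc[feature]
        return frozenset(g for g in self.groups if bool(row[f"detected_{g}"]))

    def detected_anywhere(self) -> pd.Index:
        flags = self.frame[[f"detected_{g}" for g in self.groups]]
        return self.frame.index[flags.any(axis=1)]

    def detected_in(self, group: str) -> pd.Index:
        return self.frame.index[self.frame[f"detected_{group}"]]


def detect_features(
    normalized: NormalizedMatrix | pd.DataFrame,
    groups: Mapping[str, str] | pd.Series | None = None,
    threshold: float = DETECTION_THRESHOLD,
) -> DetectionTable:
    """Compute per-group medians and strict-threshold detection flags."""
    if isinstance(normalized, NormalizedMatrix):
        values = normalized.values
        groups = normalized.specimen_groups() if groups is None else groups
    else:
        values = normalized
        if groups is None:
            raise ValueError("groups are required with a bare data frame")
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.reindex(values.columns)
    if groups.isna().any():
        raise ValueError("every sample must belong to a specimen group")
    names = tuple(sorted(groups.unique()))
    out = pd.DataFrame(index=values.index)
    for g in names:
        cols = groups.index[groups == g]
        if len(cols) == 0:
            raise ValueError(f"empty specimen group {g!r}")
        med = values[cols].median(axis=1)
        out[f"median_{g}"] = med
        out[f"detected_{g}"] = med > threshold
    out["pattern"] = [
        "+".join(g for g in names if out.at[f, f"detected_{g}"]) for f in out.index
    ]
    return DetectionTable(frame=out, groups=names, threshold=threshold)


@dataclass
class VennPartition:
    """Disjoint feature sets keyed by detection pattern (non-empty subsets)."""

    cells: dict[frozenset[str], set[str]]
    groups: tuple[str, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "+".join(sorted(k)): len(v) for k, v in sorted(self.cells.items(), key=lambda kv: sorted(kv[0]))
        }

    def common(self) -> set[str]:
        return set(self.cells.get(frozenset(self.groups), set()))

    def singletons(self) -> dict[str, set[str]]:
        return {g: set(self.cells.get(frozenset([g]), set())) for g in self.groups}

    def globally_unique(self) -> set[str]:
        out: set[str] = set()
        for members in self.singletons().values():
            out |= members
        return out


def venn_partition(table: DetectionTable) -> VennPartition:
    """Partition detected features by their exact detection pattern."""
    cells: dict[frozenset[str], set[str]] = {}
    for feature in table.detected_anywhere():
        pattern = table.pattern(feature)
        cells.setdefault(pattern, set()).add(feature)
    return VennPartition(cells=cells, groups=table.groups)


def top_expressed(
    normalized: NormalizedMatrix, group: str, k: int = 10
) -> pd.DataFrame:
    """Top-k features of a specimen group by median normalized count.

    Ties break lexicographically by feature id, so the ranking is
    deterministic across runs.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    groups = normalized.specimen_groups()
    cols = groups.index[groups == group]
    if len(cols) == 0:
        raise ValueError(f"empty specimen group {group!r}")
    med = normalized.values[cols].median(axis=1)
    order = sorted(med.index, key=lambda f: (-med[f], f))[:k]
    return pd.DataFrame(
        {"feature": order, "median": [med[f] for f in order], "rank": range(1, len(order) + 1)}
    ).set_index("feature")


def pca_embed(
    normalized: NormalizedMatrix,
    n_components: int = 2,
    features: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered (unscaled) PCA of samples on log10(x+1) normalized counts.

    Deterministic up to component sign (full SVD solver). Returns sample
    coordinates and the explained variance per component.
    """
    values = normalized.log10p()
    if features is not None:
        values = values.loc[list(features)]
    X = values.T.to_numpy()
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    n_components = min(n_components, X.shape[0], X.shape[1])
    if np.allclose(X, X[0]):
        coords = np.zeros((X.shape[0], n_components))
        return (
            pd.DataFrame(coords, index=values.columns,
                         columns=[f"PC{i + 1}" for i in range(n_components)]),
            np.zeros(n_components),
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(
        coords, index=values.columns, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return frame, pca.explained_variance_


@dataclass(frozen=True)
class PairedCorrelationRecord:
    feature: str
    specimen_pair: tuple[str, str]
    n_subjects: int
    r: float
    p_value: float
    defined: bool


def paired_correlation(
    normalized: NormalizedMatrix,
    pairs: Sequence[tuple[str, str]],
    specimen_pair: tuple[str, str],
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-feature Pearson correlation across paired subjects.

    ``pairs`` lists (sample_in_first_specimen, sample_in_second_specimen)
    for subjects providing both. Correlation is computed on log10(x+1)
    normalized counts; features constant in either specimen are flagged as
    undefined and excluded from summaries. A Benjamini-Hochberg column is
    reported but not used for filtering.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired subjects")
    log = normalized.log10p()
    feats = list(features) if features is not None else list(log.index)
    a_cols = [a for a, _ in pairs]
    b_cols = [b for _, b in pairs]
    rows = []
    for f in feats:
        x = log.loc[f, a_cols].to_numpy(dtype=float)
        y = log.loc[f, b_cols].to_numpy(dtype=float)
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            rows.append((f, len(pairs), np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((f, len(pairs), float(r), float(p), True))
    frame = pd.DataFrame(
        rows, columns=["feature", "n_subjects", "r", "p_value", "defined"]
    ).set_index("feature")
    frame["specimen_pair"] = "-".join(specimen_pair)
    defined = frame["defined"]
    frame["q_value"] = np.nan
    if defined.any():
        frame.loc[defined, "q_value"] = _benjamini_hochberg(
            frame.loc[defined, "p_value"].to_numpy()
        )
    return frame


def _benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    n = len(p_values)
    order = np.argsort(p_values)
    ranked = p_values[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
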