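"""Phase 1: mismatch-tolerant alignment to precursor miRNAs, mature-arm
assignment, the miRNA counting matrix and isomiR calling.

Alignment is ungapped, forward-strand, and returns *every* placement that
achieves the minimum mismatch count within the cap (default 3). Reads tied
between precursors contribute a full count to each tied feature, which is
what makes homologous (identical-sequence) precursors carry exactly equal
counts. Reads with no placement form the phase-2 pool.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import CountMatrix
from .preprocess import RawRead
from .simulate import MatureAnnotation

MAX_N_FRACTION = 0.10

_ENCODE = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENCODE[_b] = _i
# N (code 4) mismatches every reference base


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class PrecursorHit:
    """One ungapped placement of a read on a precursor."""

    read_id: str
    precursor: str
    offset: int
    length: int
    n_mismatches: int

    @property
    def score(self) -> int:
        return self.length - 2 * self.n_mismatches

    @property
    def end(self) -> int:
        return self.offset + self.length


class PrecursorAligner:
    """All-minimum-mismatch ungapped search over a set of precursors.

    Exact placements are resolved through a window dictionary; inexact reads
    fall back to a vectorized mismatch count over every (precursor, offset)
    window of the read's length, so the hit set is complete by construction.
    """

    def __init__(self, precursors: Mapping[str, str], max_mismatches: int = 3):
        if not precursors:
            raise ValueError("precursor set is empty")
        self.precursors = dict(precursors)
        self.max_mismatches = max_mismatches
        self._encoded = {name: _encode(seq) for name, seq in self.precursors.items()}
        self._exact: dict[int, dict[str, list[tuple[str, int]]]] = {}
        self._windows: dict[int, tuple[np.ndarray, list[tuple[str, int]]]] = {}
        self._cache: dict[str, list[tuple[str, int, int]]] = {}

    def _index_for_length(self, length: int) -> dict[str, list[tuple[str, int]]]:
        idx = self._exact.get(length)
        if idx is None:
            idx = {}
            for name, seq in self.precursors.items():
                for off in range(len(seq) - length + 1):
                    idx.setdefault(seq[off : off + length], []).append((name, off))
            self._exact[length] = idx
        return idx

    def _windows_for_length(self, length: int):
        win = self._windows.get(length)
        if win is None:
            rows, keys = [], []
            for name, enc in self._encoded.items():
                for off in range(len(enc) - length + 1):
                    rows.append(enc[off : off + length])
                    keys.append((name, off))
            stack = np.stack(rows) if rows else np.empty((0, length), dtype=np.uint8)
            win = (stack, keys)
            self._windows[length] = win
        return win

    def align(self, read_id: str, sequence: str) -> list[PrecursorHit]:
        placements = self._cache.get(sequence)
        if placements is None:
            placements = self._align_sequence(sequence)
            self._cache[sequence] = placements
        return [
            PrecursorHit(read_id, name, off, len(sequence), nm)
            for name, off, nm in placements
        ]

    def _align_sequence(self, sequence: str) -> list[tuple[str, int, int]]:
        length = len(sequence)
        if length == 0:
            return []
        if "N" not in sequence:
            exact = self._index_for_length(length).get(sequence)
            if exact:
                return [(name, off, 0) for name, off in exact]
        if self.max_mismatches == 0:
            return []
        windows, keys = self._windows_for_length(length)
        if windows.shape[0] == 0:
            return []
        enc = _encode(sequence)
        mism = np.count_nonzero(windows != enc[None, :], axis=1)
        best = mism.min(initial=length + 1)
        if best > self.max_mismatches:
            return []
        return [
            (keys[i][0], keys[i][1], int(best)) for i in np.flatnonzero(mism == best)
        ]


def align_to_precursors(
    read: RawRead | tuple[str, str],
    precursors: Mapping[str, str] | PrecursorAligner,
    max_mismatches: int = 3,
) -> list[PrecursorHit]:
    """Align one read; returns all minimum-mismatch hits (may be empty).

    Reads with more than 10% N bases are skipped (empty hit list); callers
    count them separately.
    """
    if isinstance(read, RawRead):
        rid, seq = read.id, read.sequence
    else:
        rid, seq = read
    if seq and seq.count("N") / len(seq) > MAX_N_FRACTION:
        return []
    if isinstance(precursors, PrecursorAligner):
        if precursors.max_mismatches != max_mismatches:
            raise ValueError("aligner was built with a different mismatch cap")
        return precursors.align(rid, seq)
    return PrecursorAligner(precursors, max_mismatches).align(rid, seq)


def assign_mature(
    hit: PrecursorHit, mature_annotations: Iterable[MatureAnnotation], min_overlap: float = 0.5
) -> str | None:
    """Mature arm with maximal overlap with the hit interval, or None.

    Requires overlap >= ``min_overlap`` of the read length; ties go to the
    5p arm, then lexicographically.
    """
    candidates = [m for m in mature_annotations if m.precursor == hit.precursor]
    best_name, best_key = None, None
    for m in candidates:
        overlap = min(hit.end, m.end) - max(hit.offset, m.start)
        if overlap < min_overlap * hit.length:
            continue
        arm_rank = 0 if m.name.endswith("5p") else 1
        key = (-overlap, arm_rank, m.name)
        if best_key is None or key < best_key:
            best_name, best_key = m.name, key
    return best_name


@dataclass
class AlignedRead:
    """Phase-1 result for one read: its tied best hits and arm assignments."""

    read_id: str
    hits: list[PrecursorHit]
    matures: list[str]  # deduplicated, order-stable


@dataclass
class Phase1Result:
    matrix: CountMatrix
    unmapped: dict[str, list[RawRead]]
    aligned: dict[str, list[AlignedRead]]
    report: pd.DataFrame  # per-sample read accounting


def _assign_read(
    hits: list[PrecursorHit], matures_by_precursor: Mapping[str, list[MatureAnnotation]]
) -> list[str]:
    names: list[str] = []
    for hit in hits:
        name = assign_mature(hit, matures_by_precursor.get(hit.precursor, []))
        if name is not None and name not in names:
            names.append(name)
    return names


def build_mirna_counts(
    samples: Mapping[str, Sequence[RawRead]],
    bundle,
    sample_sheet: pd.DataFrame,
    max_mismatches: int = 3,
) -> Phase1Result:
    """Counting matrix over mature features plus the phase-2 read pools.

    Partition identity per sample: ``n_aligned + n_unmapped == n_input``
    (N-heavy skipped reads land in the unmapped pool and are also reported
    in their own column).
    """
    known = set(sample_sheet["sample_id"])
    unknown = set(samples) - known
    if unknown:
        raise ValueError(f"samples absent from sample sheet: {sorted(unknown)}")
    aligner = PrecursorAligner(bundle.precursors, max_mismatches)
    matures_by_precursor = bundle.mature_by_precursor()
    feature_ids = sorted(m.name for m in bundle.mature_annotations)
    counts = pd.DataFrame(
        0, index=feature_ids, columns=list(samples), dtype=np.int64
    )
    unmapped: dict[str, list[RawRead]] = {}
    aligned: dict[str, list[AlignedRead]] = {}
    rows = []
    assign_cache: dict[tuple, list[str]] = {}
    for sid, reads in samples.items():
        pool: list[RawRead] = []
        hits_out: list[AlignedRead] = []
        n_aligned = n_skipped_n = n_unassigned = 0
        col: Counter[str] = Counter()
        for read in reads:
            seq = read.sequence
            if seq and seq.count("N") / len(seq) > MAX_N_FRACTION:
                n_skipped_n += 1
                pool.append(read)
                continue
            hits = aligner.align(read.id, seq)
            if not hits:
                pool.append(read)
                continue
            n_aligned += 1
            key = tuple((h.precursor, h.offset, h.length) for h in hits)
            matures = assign_cache.get(key)
            if matures is None:
                matures = _assign_read(hits, matures_by_precursor)
                assign_cache[key] = matures
            if not matures:
                n_unassigned += 1
            for name in matures:
                col[name] += 1
            hits_out.append(AlignedRead(read.id, hits, matures))
        unmapped[sid] = pool
        aligned[sid] = hits_out
        if col:
            counts.loc[list(col.keys()), sid] = list(col.values())
        rows.append(
            {
                "sample_id": sid,
                "n_input": len(reads),
                "n_aligned": n_aligned,
                "n_unmapped": len(pool),
                "n_skipped_n": n_skipped_n,
                "n_aligned_unassigned": n_unassigned,
                "alignment_rate": n_aligned / len(reads) if reads else 0.0,
            }
        )
    matrix = CountMatrix.from_sheet(counts, sample_sheet[sample_sheet["sample_id"].isin(samples)])
    return Phase1Result(
        matrix=matrix,
        unmapped=unmapped,
        aligned=aligned,
        report=pd.DataFrame(rows).set_index("sample_id"),
    )


# ---------------------------------------------------------------------------
# isomiRs

VARIANT_CLASSES = ("canonical", "5p_shift", "3p_shift", "internal_mismatch", "combined")
MAX_SHIFT = 5


@dataclass(frozen=True)
class IsomiRCall:
    """One variant group of a mature miRNA with its per-sample support."""

    mature: str
    variant_class: str
    delta5: int
    delta3: int
    n_mismatches: int
    support: Mapping[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        if self.variant_class == "canonical" and (
            self.delta5 or self.delta3 or self.n_mismatches
        ):
            raise ValueError("canonical calls must have zero shifts and mismatches")


def classify_variant(delta5: int, delta3: int, n_mismatches: int) -> str:
    shifted5, shifted3 = delta5 != 0, delta3 != 0
    if not shifted5 and not shifted3 and n_mismatches == 0:
        return "canonical"
    if shifted5 and not shifted3 and n_mismatches == 0:
        return "5p_shift"
    if shifted3 and not shifted5 and n_mismatches == 0:
        return "3p_shift"
    if not shifted5 and not shifted3:
        return "internal_mismatch"
    return "combined"


def _mismatch_signature(hit: PrecursorHit, sequence: str, precursor_seq: str) -> tuple:
    if hit.n_mismatches == 0:
        return ()
    window = precursor_seq[hit.offset : hit.end]
    return tuple(
        (i, sequence[i]) for i in range(hit.length) if sequence[i] != window[i]
    )


def accumulate_isomir_support(
    sample_id: str,
    entries: Sequence[AlignedRead],
    bundle,
    support: dict[tuple, dict[str, int]],
    read_sequences: Mapping[str, str] | None = None,
) -> None:
    """Fold one sample's phase-1 alignments into the variant support map.

    Keys are (mature, delta5, delta3, n_mismatches, mismatch signature);
    shifts beyond +/-5 nt are ignored. Designed for streaming so that the
    pipeline never holds more than one sample's alignments in memory.
    """
    matures = {m.name: m for m in bundle.mature_annotations}
    matures_by_precursor = bundle.mature_by_precursor()
    seq_lookup = read_sequences or {}
    for entry in entries:
        for hit in entry.hits:
            mature_name = assign_mature(hit, matures_by_precursor.get(hit.precursor, []))
            if mature_name is None:
                continue
            mat = matures[mature_name]
            d5 = hit.offset - mat.start
            d3 = hit.end - mat.end
            if abs(d5) > MAX_SHIFT or abs(d3) > MAX_SHIFT:
                continue
            seq = seq_lookup.get(entry.read_id)
            if seq is None and hit.n_mismatches == 0:
                sig: tuple = ()
            elif seq is None:
                sig = ("nm", hit.n_mismatches)
            else:
                sig = _mismatch_signature(hit, seq, bundle.precursors[hit.precursor])
            key = (mature_name, d5, d3, hit.n_mismatches, sig)
            support.setdefault(key, {}).setdefault(sample_id, 0)
            support[key][sample_id] += 1


def calls_from_support(
    support: Mapping[tuple, Mapping[str, int]],
    sample_specimens: Mapping[str, str],
    support_threshold: int = 20,
) -> list[IsomiRCall]:
    """Turn the variant support map into reported isomiR calls.

    A group is reported iff its per-sample support has a median strictly
    greater than ``support_threshold`` in at least one specimen group (zeros
    included for samples without the variant); canonical groups never are.
    """
    specimens = sorted(set(sample_specimens.values()))
    samples_by_specimen = {
        sp: [s for s, v in sample_specimens.items() if v == sp] for sp in specimens
    }
    calls: list[IsomiRCall] = []
    for (mature_name, d5, d3, nm, _sig), per_sample in sorted(
        support.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3], str(kv[0][4]))
    ):
        cls = classify_variant(d5, d3, nm)
        if cls == "canonical":
            continue
        detected = False
        for sp in specimens:
            sids = samples_by_specimen[sp]
            values = [per_sample.get(s, 0) for s in sids]
            if sids and float(np.median(values)) > support_threshold:
                detected = True
                break
        if detected:
            calls.append(
                IsomiRCall(
                    mature=mature_name,
                    variant_class=cls,
                    delta5=d5,
                    delta3=d3,
                    n_mismatches=nm,
                    support=dict(per_sample),
                )
            )
    return calls


def call_isomirs(
    aligned: Mapping[str, Sequence[AlignedRead]],
    bundle,
    sample_specimens: Mapping[str, str],
    support_threshold: int = 20,
    read_sequences: Mapping[str, Mapping[str, str]] | None = None,
) -> list[IsomiRCall]:
    """Group phase-1 alignments into isomiR calls (non-streaming wrapper)."""
    support: dict[tuple, dict[str, int]] = {}
    for sid, entries in aligned.items():
        accumulate_isomir_support(
            sid, entries, bundle, support, (read_sequences or {}).get(sid)
        )
    return calls_from_support(support, sample_specimens, support_threshold)


def isomirs_to_frame(calls: list[IsomiRCall]) -> pd.DataFrame:
    rows = [
        {
            "mature": c.mature,
            "variant_class": c.variant_class,
            "delta5": c.delta5,
            "delta3": c.delta3,
            "n_mismatches": c.n_mismatches,
            "total_support": sum(c.support.values()),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["mature", "variant_class", "delta5", "delta3", "n_mismatches", "total_support"],
    )
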