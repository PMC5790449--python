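"""Raw-read cleaning: adapter clipping, quality filter, length filter.

The filters are applied in the fixed order trim -> quality -> length, and the
per-sample :class:`TrimReport` satisfies the conservation identity
``n_retained + n_discarded_short + n_discarded_low_quality == n_input``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PHRED_OFFSET = 33
DEFAULT_ADAPTER = "AGATCGGAAGAGC"


class ReadError(ValueError):
    """Malformed read handed to a preprocessing operation."""


@dataclass(frozen=True)
class RawRead:
    """One sequencing read (Phred+33)."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ReadError(
                f"read {self.id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


@dataclass
class TrimReport:
    """Per-sample preprocessing counters."""

    n_input: int = 0
    n_adapter_trimmed: int = 0
    n_discarded_short: int = 0
    n_discarded_low_quality: int = 0
    n_retained: int = 0

    @property
    def mean_low_quality_rate(self) -> float:
        return self.n_discarded_low_quality / self.n_input if self.n_input else 0.0

    def check(self) -> None:
        total = self.n_retained + self.n_discarded_short + self.n_discarded_low_quality
        if total != self.n_input:
            raise AssertionError("trim report counters do not sum to n_input")


@dataclass
class PreprocessConfig:
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 3
    max_error_rate: float = 0.1
    quality_threshold: int = 30
    min_length: int = 15
    drop_low_quality: bool = True


def find_adapter(
    sequence: str, adapter: str, min_overlap: int = 3, max_error_rate: float = 0.1
) -> int:
    """Leftmost start of an adapter match, or -1.

    A match at position ``p`` compares ``adapter`` against the read suffix
    starting at ``p``; at the read end only a prefix of the adapter of length
    >= ``min_overlap`` needs to align, with at most
    ``floor(max_error_rate * compared_length)`` mismatches.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 0.0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must be in [0, 0.5)")
    n, m = len(sequence), len(adapter)
    for p in range(0, n - min_overlap + 1):
        cmp_len = min(m, n - p)
        allowed = int(max_error_rate * cmp_len)
        mismatches = 0
        ok = True
        for i in range(cmp_len):
            if sequence[p + i] != adapter[i]:
                mismatches += 1
                if mismatches > allowed:
                    ok = False
                    break
        if ok:
            return p
    return -1


def trim_adapter(
    read: RawRead, adapter: str, min_overlap: int = 3, max_error_rate: float = 0.1
) -> tuple[RawRead, bool]:
    """Clip the 3' adapter; returns the (possibly shortened) read and a flag."""
    pos = find_adapter(read.sequence, adapter, min_overlap, max_error_rate)
    if pos < 0:
        return read, False
    return RawRead(read.id, read.sequence[:pos], read.quality[:pos]), True


def mean_quality(quality: str) -> float:
    if not quality:
        return 0.0
    scores = []
    for ch in quality:
        q = ord(ch) - PHRED_OFFSET
        if q < 0 or ord(ch) > 126:
            raise ReadError(f"invalid Phred+33 quality character {ch!r}")
        scores.append(q)
    return sum(scores) / len(scores)


def quality_filter(read: RawRead, threshold: int = 30) -> bool:
    """True iff the read passes (mean Phred score not below ``threshold``)."""
    return mean_quality(read.quality) >= threshold


def length_filter(read: RawRead, min_length: int = 15) -> bool:
    """True iff the read is long enough to keep."""
    return len(read.sequence) >= min_length


@dataclass
class _TrimCache:
    """Memoised trim positions; simulated cohorts repeat sequences heavily."""

    adapter: str
    min_overlap: int
    max_error_rate: float
    _cache: dict[str, int] = field(default_factory=dict)

    def position(self, sequence: str) -> int:
        pos = self._cache.get(sequence)
        if pos is None:
            pos = find_adapter(sequence, self.adapter, self.min_overlap, self.max_error_rate)
            self._cache[sequence] = pos
        return pos


def preprocess_reads(
    reads, config: PreprocessConfig | None = None
) -> tuple[list[RawRead], TrimReport]:
    """Apply trim -> quality -> length to an iterable of (id, seq, qual).

    Accepts raw tuples or :class:`RawRead` objects; returns the retained
    clean reads and a consistent :class:`TrimReport`.
    """
    config = config or PreprocessConfig()
    cache = _TrimCache(config.adapter, config.min_overlap, config.max_error_rate)
    report = TrimReport()
    retained: list[RawRead] = []
    qual_cache: dict[str, float] = {}
    for item in reads:
        if isinstance(item, RawRead):
            rid, seq, qual = item.id, item.sequence, item.quality
        else:
            rid, seq, qual = item
        if len(seq) != len(qual):
            raise ReadError(f"read {rid}: sequence/quality length mismatch")
        report.n_input += 1
        pos = cache.position(seq)
        if pos >= 0:
            report.n_adapter_trimmed += 1
            seq, qual = seq[:pos], qual[:pos]
        if config.drop_low_quality:
            mq = qual_cache.get(qual)
            if mq is None:
                mq = mean_quality(qual) if qual else 0.0
                qual_cache[qual] = mq
            # empty inserts fall through to the length filter, mirroring the
            # documented order trim -> quality -> length
            if qual and mq < config.quality_threshold:
                report.n_discarded_low_quality += 1
                continue
        if len(seq) < config.min_length:
            report.n_discarded_short += 1
            continue
        report.n_retained += 1
        retained.append(RawRead(rid, seq, qual))
    report.check()
    return retained, report


def preprocess_sample(fastq_path, config: PreprocessConfig | None = None):
    """Preprocess one FASTQ file; see :func:`preprocess_reads`."""
    from .io import iter_fastq

    return preprocess_reads(iter_fastq(fastq_path), config)
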