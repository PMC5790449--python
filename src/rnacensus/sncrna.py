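"""Phase 2: genome alignment of miRNA-unmapped reads, annotation size
selection, strand-aware read-to-annotation assignment with homolog sharing,
and the non-miRNA sncRNA counting matrix.

The genome aligner is complete at its mismatch cap: a read is split into
``max_mismatches + 1`` disjoint segments, so any placement with at most that
many mismatches contains at least one error-free segment and is recovered
through the exact seed index (pigeonhole). Reads too short to seed fall back
to a full scan.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Annotation
from .matrix import CountMatrix
from .preprocess import RawRead
from .simulate import reverse_complement

_MIN_SEED = 8


@dataclass(frozen=True)
class GenomicHit:
    """One ungapped placement on the genome; 0-based half-open."""

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    n_mismatches: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("hit end must exceed start")


def _hamming(a: str, b: str, cap: int) -> int:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > cap:
                return mism
    return mism


class GenomeAligner:
    """All-minimum-mismatch ungapped search over both strands of a genome."""

    def __init__(self, genome: Mapping[str, str], max_mismatches: int = 2):
        if not genome:
            raise ValueError("genome is empty")
        self.genome = dict(genome)
        self.max_mismatches = max_mismatches
        self._seed_index: dict[int, dict[str, list[tuple[str, int]]]] = {}
        self._cache: dict[str, list[tuple[str, int, str, int]]] = {}

    def _index(self, k: int) -> dict[str, list[tuple[str, int]]]:
        idx = self._seed_index.get(k)
        if idx is None:
            idx = {}
            for contig, seq in self.genome.items():
                for pos in range(len(seq) - k + 1):
                    idx.setdefault(seq[pos : pos + k], []).append((contig, pos))
            self._seed_index[k] = idx
        return idx

    def _candidates(self, sequence: str) -> set[tuple[str, int]]:
        length = len(sequence)
        n_seg = self.max_mismatches + 1
        k = length // n_seg
        if k < _MIN_SEED:
            # short read: every placement is a candidate
            return {
                (contig, pos)
                for contig, seq in self.genome.items()
                for pos in range(len(seq) - length + 1)
            }
        index = self._index(k)
        out: set[tuple[str, int]] = set()
        for seg in range(n_seg):
            off = seg * k
            for contig, pos in index.get(sequence[off : off + k], ()):
                start = pos - off
                if start >= 0 and start + length <= len(self.genome[contig]):
                    out.add((contig, start))
        return out

    def _placements(self, sequence: str) -> list[tuple[str, int, str, int]]:
        """(contig, start, strand, mismatches) for all tied-best placements."""
        cached = self._cache.get(sequence)
        if cached is not None:
            return cached
        length = len(sequence)
        found: list[tuple[str, int, str, int]] = []
        best = self.max_mismatches + 1
        for strand, query in (("+", sequence), ("-", reverse_complement(sequence))):
            for contig, start in self._candidates(query):
                window = self.genome[contig][start : start + length]
                mism = _hamming(query, window, self.max_mismatches)
                if mism <= self.max_mismatches:
                    found.append((contig, start, strand, mism))
                    best = min(best, mism)
        result = [p for p in found if p[3] == best] if found else []
        self._cache[sequence] = result
        return result

    def align(self, read_id: str, sequence: str) -> list["GenomicHit"]:
        if not sequence:
            return []
        return [
            GenomicHit(read_id, contig, start, start + len(sequence), strand, mism)
            for contig, start, strand, mism in self._placements(sequence)
        ]


def align_to_genome(
    read: RawRead | tuple[str, str],
    genome: Mapping[str, str] | GenomeAligner,
    max_mismatches: int = 2,
) -> list[GenomicHit]:
    """Align one phase-2 read to the genome (both strands, ungapped)."""
    if isinstance(read, RawRead):
        rid, seq = read.id, read.sequence
    else:
        rid, seq = read
    if isinstance(genome, GenomeAligner):
        if genome.max_mismatches != max_mismatches:
            raise ValueError("aligner was built with a different mismatch cap")
        return genome.align(rid, seq)
    return GenomeAligner(genome, max_mismatches).align(rid, seq)


# ---------------------------------------------------------------------------
# annotation handling


def select_quantifiable_annotations(annotations: Sequence[Annotation]) -> list[Annotation]:
    """Size-selection rule: GENCODE annotations of length <=70 are kept,
    DASHR piRNA/tRNA are kept regardless of length, everything else drops."""
    kept = []
    for ann in annotations:
        if ann.length is None:
            raise ValueError(f"annotation {ann.id} is missing a length")
        if ann.source == "DASHR" and ann.rna_class in ("piRNA", "tRNA"):
            kept.append(ann)
        elif ann.source == "GENCODE" and ann.length <= 70:
            kept.append(ann)
    return kept


class AnnotationIndex:
    """Per-contig interval lookup over a (small) annotation set."""

    def __init__(self, annotations: Sequence[Annotation]):
        self.by_contig: dict[str, list[Annotation]] = {}
        for ann in annotations:
            self.by_contig.setdefault(ann.contig, []).append(ann)

    def overlapping(self, contig: str, start: int, end: int, strand: str) -> list[Annotation]:
        return [
            ann
            for ann in self.by_contig.get(contig, [])
            if ann.strand == strand and ann.start < end and ann.end > start
        ]


def assign_to_annotations(
    hit: GenomicHit,
    index: AnnotationIndex | Sequence[Annotation],
    min_overlap_fraction: float = 0.9,
) -> list[str]:
    """Ids of same-strand annotations covering >= the fraction of the read."""
    if not isinstance(index, AnnotationIndex):
        index = AnnotationIndex(index)
    length = hit.end - hit.start
    out = []
    for ann in index.overlapping(hit.contig, hit.start, hit.end, hit.strand):
        overlap = min(hit.end, ann.end) - max(hit.start, ann.start)
        if overlap >= min_overlap_fraction * length:
            out.append(ann.id)
    return out


def expand_homologs(locus_ids: list[str], group_of_locus: Mapping[str, str],
                    members_of_group: Mapping[str, tuple[str, ...]]) -> list[str]:
    """Share an assignment across every member of each touched homolog group."""
    out: list[str] = []
    for lid in locus_ids:
        group = group_of_locus.get(lid)
        for member in members_of_group.get(group, (lid,)) if group else (lid,):
            if member not in out:
                out.append(member)
    return out


@dataclass
class Phase2Result:
    matrix: CountMatrix
    report: pd.DataFrame  # per-sample genome-alignment / assignment accounting
    unassigned: dict[str, list[RawRead]]


def build_sncrna_counts(
    pools: Mapping[str, Sequence[RawRead]],
    bundle,
    sample_sheet: pd.DataFrame,
    max_mismatches: int = 2,
    min_overlap_fraction: float = 0.9,
) -> Phase2Result:
    """Counting matrix over size-selected annotations for the phase-2 pools.

    Partition identity per sample:
    ``n_assigned + n_unassigned_mapped + n_genome_unmapped == n_pool``.
    Homologous identical-sequence loci receive exactly equal counts.
    """
    known = set(sample_sheet["sample_id"])
    unknown = set(pools) - known
    if unknown:
        raise ValueError(f"samples absent from sample sheet: {sorted(unknown)}")
    aligner = GenomeAligner(bundle.genome, max_mismatches)
    quantifiable = select_quantifiable_annotations(bundle.sncrna_annotations)
    index = AnnotationIndex(quantifiable)
    group_of_locus = bundle.group_of_locus()
    members = bundle.sncrna_groups
    feature_ids = sorted(ann.id for ann in quantifiable)
    counts = pd.DataFrame(0, index=feature_ids, columns=list(pools), dtype=np.int64)
    rows = []
    unassigned_pools: dict[str, list[RawRead]] = {}
    assign_cache: dict[str, tuple[str, ...]] = {}
    for sid, reads in pools.items():
        col: Counter[str] = Counter()
        n_mapped = n_assigned = 0
        leftover: list[RawRead] = []
        for read in reads:
            assigned = assign_cache.get(read.sequence)
            if assigned is None:
                hits = aligner.align(read.id, read.sequence)
                if not hits:
                    assigned = ("__unmapped__",)
                else:
                    loci: list[str] = []
                    for hit in hits:
                        for lid in assign_to_annotations(hit, index, min_overlap_fraction):
                            if lid not in loci:
                                loci.append(lid)
                    loci = expand_homologs(loci, group_of_locus, members)
                    assigned = tuple(loci) if loci else ("__mapped_unassigned__",)
                assign_cache[read.sequence] = assigned
            if assigned == ("__unmapped__",):
                leftover.append(read)
                continue
            n_mapped += 1
            if assigned == ("__mapped_unassigned__",):
                leftover.append(read)
                continue
            n_assigned += 1
            for lid in assigned:
                col[lid] += 1
        if col:
            counts.loc[list(col.keys()), sid] = list(col.values())
        unassigned_pools[sid] = leftover
        n_pool = len(reads)
        rows.append(
            {
                "sample_id": sid,
                "n_pool": n_pool,
                "n_genome_mapped": n_mapped,
                "n_genome_unmapped": n_pool - n_mapped,
                "n_assigned": n_assigned,
                "n_unassigned_mapped": n_mapped - n_assigned,
                "genome_alignment_rate": n_mapped / n_pool if n_pool else 0.0,
                "assignment_rate": n_assigned / n_pool if n_pool else 0.0,
            }
        )
    matrix = CountMatrix.from_sheet(counts, sample_sheet[sample_sheet["sample_id"].isin(pools)])
    return Phase2Result(
        matrix=matrix,
        report=pd.DataFrame(rows).set_index("sample_id"),
        unassigned=unassigned_pools,
    )
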