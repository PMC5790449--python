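"""Format readers/writers binding the pipeline stages together.

All internal coordinates are 0-based half-open; conversions to the 1-based
closed GTF convention happen only here. FASTA/FASTQ parsing is delegated to
Biopython; the tabular formats (BED6, GTF, TSV, JSON) are written with
explicit column control so that round-trips are byte-stable.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class FormatError(ValueError):
    """Malformed record in an input file; message carries the location."""


# ---------------------------------------------------------------------------
# sequence formats


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name→sequence mapping."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) tuples; Phred+33, transparently gunzipped.

    Raises :class:`FormatError` naming the record index on a truncated or
    inconsistent record.
    """
    index = 0
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise FormatError(
                        f"FASTQ record {index} ({title.split()[0]}): sequence and "
                        f"quality lengths differ ({len(seq)} vs {len(qual)})"
                    )
                yield title.split()[0], seq.upper(), qual
                index += 1
        except ValueError as exc:  # Biopython signals truncation with ValueError
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"FASTQ record {index}: {exc}") from exc


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with _open_text(path, "wt") as handle:
        for rid, seq, qual in records:
            handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# annotation tables


@dataclass(frozen=True)
class Annotation:
    """One sncRNA locus; coordinates 0-based half-open on ``contig``."""

    id: str
    rna_class: str
    source: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"annotation {self.id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"annotation {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


GTF_COLUMNS = [
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "attribute",
]


def write_gtf(path: str | Path, annotations: Iterable[Annotation]) -> None:
    """Write annotations as GTF (1-based closed intervals)."""
    with open(path, "w") as handle:
        for ann in annotations:
            attrs = (
                f'gene_id "{ann.id}"; rna_class "{ann.rna_class}"; '
                f'source_db "{ann.source}";'
            )
            fields = [
                ann.contig, ann.source, "exon",
                str(ann.start + 1), str(ann.end),
                ".", ann.strand, ".", attrs,
            ]
            handle.write("\t".join(fields) + "\n")


def _parse_gtf_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError as exc:
            raise FormatError(f"GTF line {lineno}: bad attribute {chunk!r}") from exc
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[Annotation]:
    annotations = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"GTF line {lineno}: expected 9 fields, got {len(fields)}")
            attrs = _parse_gtf_attributes(fields[8], lineno)
            try:
                start = int(fields[3]) - 1  # GTF is 1-based closed
                end = int(fields[4])
            except ValueError as exc:
                raise FormatError(f"GTF line {lineno}: non-integer coordinates") from exc
            annotations.append(
                Annotation(
                    id=attrs.get("gene_id", f"line{lineno}"),
                    rna_class=attrs.get("rna_class", "."),
                    source=attrs.get("source_db", fields[1]),
                    contig=fields[0],
                    start=start,
                    end=end,
                    strand=fields[6],
                )
            )
    return annotations


def write_bed6(path: str | Path, annotations: Iterable[Annotation]) -> None:
    """BED6 export (0-based half-open, same as internal coordinates)."""
    with open(path, "w") as handle:
        for ann in annotations:
            handle.write(
                f"{ann.contig}\t{ann.start}\t{ann.end}\t{ann.id}\t0\t{ann.strand}\n"
            )


def read_bed6(path: str | Path) -> list[Annotation]:
    annotations = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"BED line {lineno}: expected ≥6 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"BED line {lineno}: non-integer coordinates") from exc
            annotations.append(
                Annotation(
                    id=fields[3], rna_class=".", source=".",
                    contig=fields[0], start=start, end=end, strand=fields[5],
                )
            )
    return annotations


# ---------------------------------------------------------------------------
# tables and JSON


def write_tsv(path: str | Path, frame: pd.DataFrame, index_label: str | None = None) -> None:
    frame.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def read_tsv(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(path: str | Path, payload: object) -> None:
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_json(path: str | Path) -> object:
    with open(path) as handle:
        return json.load(handle)
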