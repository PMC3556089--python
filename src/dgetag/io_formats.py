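"""Readers and writers for every external artifact the pipeline touches.

All sequence data are plain-text: FASTA for references, two-column TSV
(tag<TAB>count) for tag libraries, three-column TSV for annotation maps
(gene_id<TAB>term_id<TAB>term_name), and per-stage TSV result tables.
Sequences are normalised to uppercase on ingest; any base outside
{A, C, G, T, N} is a hard error because tag identity is exact-match based.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

TAG_LENGTH = 21
VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A single reference sequence (gene/transcript or genome contig)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise FormatError("empty gene_id")
        if not self.sequence:
            raise FormatError(f"record {self.gene_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.gene_id!r}: invalid bases {sorted(bad)!r}"
            )


@dataclass
class TagCountTable:
    """A named multiset of 21-nt tags with positive copy counts."""

    library_name: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tag, count in self.counts.items():
            _validate_tag_row(tag, count)

    @property
    def total_copies(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def __len__(self) -> int:
        return len(self.counts)


def _validate_tag_row(tag: str, count: int, line: int | None = None) -> None:
    where = f" (line {line})" if line is not None else ""
    if len(tag) != TAG_LENGTH:
        raise FormatError(f"tag {tag!r} has length {len(tag)}, expected {TAG_LENGTH}{where}")
    bad = set(tag) - VALID_BASES
    if bad:
        raise FormatError(f"tag {tag!r}: invalid bases {sorted(bad)!r}{where}")
    if not isinstance(count, int) or count < 1:
        raise FormatError(f"tag {tag!r}: count {count!r} must be a positive integer{where}")


@dataclass
class AnnotationMap:
    """Flat gene -> term annotation for one scheme (GO or pathway)."""

    scheme: str
    gene_terms: dict[str, frozenset[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scheme not in {"GO", "pathway"}:
            raise FormatError(f"unknown annotation scheme {self.scheme!r}")
        for gene, terms in self.gene_terms.items():
            if not terms:
                raise FormatError(f"gene {gene!r}: empty term set stored")

    @property
    def annotated_genes(self) -> frozenset[str]:
        return frozenset(self.gene_terms)

    def genes_of_term(self, term: str) -> frozenset[str]:
        return frozenset(g for g, ts in self.gene_terms.items() if term in ts)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a FASTA file into validated :class:`TranscriptRecord` objects.

    Sequences are uppercased (lowercase soft-masking is kept as sequence);
    duplicate identifiers and empty sequences are rejected.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(TranscriptRecord(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Tag tables
# ---------------------------------------------------------------------------

def read_tag_table(path: str | Path, library_name: str) -> TagCountTable:
    """Read a two-column TSV (tag<TAB>count) into a :class:`TagCountTable`."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            tag = parts[0].upper()
            try:
                count = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: count {parts[1]!r} is not an integer")
            _validate_tag_row(tag, count, line=lineno)
            if tag in counts:
                raise FormatError(f"{path}: line {lineno}: duplicate tag {tag!r}")
            counts[tag] = count
    return TagCountTable(library_name, counts)


def write_tag_table(table: TagCountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tag, count in table.counts.items():
            fh.write(f"{tag}\t{count}\n")


def collapse_fastq(path: str | Path, library_name: str) -> TagCountTable:
    """Collapse 21-nt FASTQ reads into a tag-count table.

    Convenience converter for raw read lists: reads longer than 21 nt are
    truncated to their first 21 nt (tag + downstream adaptor sequence);
    shorter reads are rejected.
    """
    counter: Counter[str] = Counter()
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()
        if len(seq) < TAG_LENGTH:
            raise FormatError(f"read {rec.id!r}: length {len(seq)} < {TAG_LENGTH}")
        counter[seq[:TAG_LENGTH]] += 1
    return TagCountTable(library_name, dict(counter))


# ---------------------------------------------------------------------------
# Annotation maps
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, scheme: str) -> AnnotationMap:
    """Read a gene_id<TAB>term_id<TAB>term_name TSV into an AnnotationMap."""
    gene_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
            gene, term, name = parts
            if not gene or not term:
                raise FormatError(f"{path}: line {lineno}: empty gene or term id")
            if term in term_names and term_names[term] != name:
                raise FormatError(f"{path}: line {lineno}: term {term!r} renamed")
            term_names[term] = name
            gene_terms.setdefault(gene, set()).add(term)
    return AnnotationMap(
        scheme,
        {g: frozenset(ts) for g, ts in gene_terms.items()},
        term_names,
    )


def write_annotation(annotation: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotation.gene_terms):
            for term in sorted(annotation.gene_terms[gene]):
                fh.write(f"{gene}\t{term}\t{annotation.term_names.get(term, term)}\n")


# ---------------------------------------------------------------------------
# Generic result tables (dataclass <-> TSV)
# ---------------------------------------------------------------------------

def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isinf(value):
            return "inf" if value > 0 else "-inf"
        return repr(value)
    return str(value)


def write_results_tsv(records: Sequence, path: str | Path, record_type=None) -> None:
    """Write a homogeneous list of result dataclasses as a TSV with header.

    Column order is the dataclass field order; nested structures (e.g. hit
    lists) must already be string-serialisable via each record's own
    ``to_row``/``from_row`` hooks when present. Round-trips through
    :func:`read_results_tsv`.
    """
    if record_type is None:
        if not records:
            raise ValueError("record_type is required for an empty record list")
        record_type = type(records[0])
    if not dataclasses.is_dataclass(record_type):
        raise TypeError(f"{record_type!r} is not a dataclass")
    fields = [f.name for f in dataclasses.fields(record_type)]
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        for rec in records:
            if type(rec) is not record_type:
                raise TypeError(
                    f"heterogeneous records: expected {record_type.__name__}, got {type(rec).__name__}"
                )
            row = rec.to_row() if hasattr(rec, "to_row") else dataclasses.astuple(rec)
            if len(row) != len(fields):
                raise ValueError("row length does not match field count")
            fh.write("\t".join(_format_cell(v) for v in row) + "\n")


def read_results_tsv(path: str | Path, record_type) -> list:
    """Inverse of :func:`write_results_tsv` for a known record type."""
    fields = dataclasses.fields(record_type)
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = [f.name for f in fields]
        if header != expected:
            raise FormatError(f"{path}: header {header!r} != expected {expected!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(fields):
                raise FormatError(f"{path}: line {lineno}: wrong column count")
            if hasattr(record_type, "from_row"):
                out.append(record_type.from_row(cells))
            else:
                kwargs = {}
                for f, cell in zip(fields, cells):
                    kwargs[f.name] = _parse_cell(cell, f.type)
                out.append(record_type(**kwargs))
    return out


def _parse_cell(cell: str, type_hint) -> object:
    hint = str(type_hint)
    if "int" in hint:
        return int(cell)
    if "float" in hint:
        return float(cell)
    return cell
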