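"""Virtual reference-tag library: all CATG+17-nt tags of a reference.

The NlaIII restriction enzyme cuts at every CATG; MmeI then releases the 17
nt immediately downstream, so every expressible tag is one of the 21-nt
CATG+17-nt substrings of the reference (sense strand) or of its reverse
complement (antisense transcription). The index maps each such tag sequence
to the set of sites producing it, so that experimental tags can be assigned
to genes by exact or 1-mismatch lookup.

All CATG sites are indexed, including overlapping ones; the wet protocol's
preference for the 3'-most site is a property of the *sampling* (modelled in
:mod:`dgetag.synthetic_data`), not of the reference.

Coordinates are 0-based. ``position`` is the forward-strand offset of the C
of the CATG anchor: a sense site occupies ``[position, position + 21)``, an
antisense site ``[position - 20, position + 1)`` (its tag reads 5'->3' on
the reverse strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .io_formats import FormatError, TranscriptRecord, TAG_LENGTH

ANCHOR = "CATG"
TAIL_LENGTH = TAG_LENGTH - len(ANCHOR)  # 17

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SENSE = "sense"
ANTISENSE = "antisense"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TagSite:
    """One genomic/transcriptomic origin of a reference tag."""

    gene_id: str
    position: int  # forward-strand offset of the C of CATG
    strand: str  # "sense" | "antisense"


@dataclass
class ReferenceTagIndex:
    """Map from 21-nt tag sequence to the sites producing it."""

    source: str  # "transcriptome" | "genome"
    entries: dict[str, list[TagSite]] = field(default_factory=dict)

    def sites(self, tag: str, strand: str | None = None) -> list[TagSite]:
        hits = self.entries.get(tag, [])
        if strand is None:
            return hits
        return [s for s in hits if s.strand == strand]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class IndexStats:
    n_reference_sequences: int
    n_with_catg: int
    pct_with_catg: float  # unrounded; round to 2 decimals for display
    n_unambiguous_reference_tags: int


def _scan_sense(seq: str):
    """Yield (position, tag) for every valid sense CATG site of seq."""
    start = 0
    limit = len(seq) - TAG_LENGTH
    while True:
        pos = seq.find(ANCHOR, start)
        if pos == -1:
            return
        if pos <= limit:
            tag = seq[pos : pos + TAG_LENGTH]
            if "N" not in tag:
                yield pos, tag
        start = pos + 1  # overlapping CATGCATG sites each yield a tag


def extract_reference_tags(
    transcripts: list[TranscriptRecord],
    strands: tuple[str, ...] = (SENSE, ANTISENSE),
    source: str = "transcriptome",
) -> ReferenceTagIndex:
    """Build the virtual tag index over the requested strands.

    For each CATG with at least 17 nt downstream, one sense tag is emitted;
    antisense tags come from the same scan over the reverse complement, with
    sites reported in forward-strand coordinates. Tags containing N are
    skipped (a reference tag must be exactly matchable).
    """
    strand_set = set(strands)
    if not strand_set:
        raise ValueError("strand set must be non-empty")
    unknown = strand_set - {SENSE, ANTISENSE}
    if unknown:
        raise ValueError(f"unknown strands {sorted(unknown)!r}")

    index = ReferenceTagIndex(source=source)
    for rec in transcripts:
        if SENSE in strand_set:
            for pos, tag in _scan_sense(rec.sequence):
                index.entries.setdefault(tag, []).append(
                    TagSite(rec.gene_id, pos, SENSE)
                )
        if ANTISENSE in strand_set:
            rc = revcomp(rec.sequence)
            L = len(rc)
            for pos, tag in _scan_sense(rc):
                # C of CATG at rc offset `pos` sits at forward offset L-1-pos
                index.entries.setdefault(tag, []).append(
                    TagSite(rec.gene_id, L - 1 - pos, ANTISENSE)
                )
    return index


def index_stats(
    index: ReferenceTagIndex, transcripts: list[TranscriptRecord]
) -> IndexStats:
    """Reference coverage statistics: how many sequences carry a CATG site
    and how many tags are unambiguous (single-gene) at the gene level."""
    n_ref = len(transcripts)
    if n_ref == 0:
        raise ValueError("percentage undefined for zero reference sequences")
    genes_with_sites = {site.gene_id for sites in index.entries.values() for site in sites}
    n_with = sum(1 for t in transcripts if t.gene_id in genes_with_sites)
    n_unambiguous = sum(
        1
        for sites in index.entries.values()
        if len({s.gene_id for s in sites}) == 1
    )
    return IndexStats(
        n_reference_sequences=n_ref,
        n_with_catg=n_with,
        pct_with_catg=100.0 * n_with / n_ref,
        n_unambiguous_reference_tags=n_unambiguous,
    )


def pct_display(value: float) -> float:
    """Round a percentage to the 2-decimal display convention."""
    return round(value, 2)


# ---------------------------------------------------------------------------
# Serialisation: tag<TAB>source_id<TAB>position<TAB>strand
# ---------------------------------------------------------------------------

def write_index(index: ReferenceTagIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#source={index.source}\n")
        for tag in sorted(index.entries):
            for site in index.entries[tag]:
                fh.write(f"{tag}\t{site.gene_id}\t{site.position}\t{site.strand}\n")


def read_index(path: str | Path) -> ReferenceTagIndex:
    source = "transcriptome"
    entries: dict[str, list[TagSite]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#source="):
                source = line.split("=", 1)[1]
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            tag, gene_id, position, strand = parts
            if len(tag) != TAG_LENGTH or not tag.startswith(ANCHOR):
                raise FormatError(f"{path}: line {lineno}: invalid reference tag {tag!r}")
            entries.setdefault(tag, []).append(TagSite(gene_id, int(position), strand))
    return ReferenceTagIndex(source=source, entries=entries)
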