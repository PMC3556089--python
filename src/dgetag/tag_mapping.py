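"""Assign each distinct clean tag to one category of the mapping taxonomy.

Every tag is pushed through a priority cascade over the transcriptome index
and (optionally) a genome index:

    perfect sense -> 1-mm sense -> perfect antisense -> 1-mm antisense
        -> genome perfect -> genome 1-mm -> unknown

The first non-empty level decides the category; within a level the tag is
"1 to 1" if it hits exactly one gene (one position for the genome) and
"1 to n" otherwise. Mismatches are allowed only in the 17-nt variable
region by default — the CATG anchor is enzymatic, not sequenced
variability — and the 1-mm search probes the 51 single-substitution
neighbours of the query against the hash index rather than scanning it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import TAG_LENGTH
from .reference_index import (
    ANCHOR,
    ANTISENSE,
    SENSE,
    IndexStats,
    ReferenceTagIndex,
    TagSite,
    pct_display,
)

CATEGORIES: tuple[str, ...] = (
    "perfect_sense_1to1",
    "perfect_sense_1ton",
    "mm1_sense_1to1",
    "mm1_sense_1ton",
    "perfect_antisense_1to1",
    "perfect_antisense_1ton",
    "mm1_antisense_1to1",
    "mm1_antisense_1ton",
    "genome_perfect_1to1",
    "genome_perfect_1ton",
    "genome_mm1_1to1",
    "genome_mm1_1ton",
    "unknown",
)

SENSE_1TO1 = ("perfect_sense_1to1", "mm1_sense_1to1")

_BASES = "ACGT"


@dataclass
class MappingRecord:
    tag: str
    category: str
    hits: list[TagSite] = field(default_factory=list)

    def to_row(self) -> tuple:
        hit_str = ";".join(f"{s.gene_id}:{s.position}:{s.strand}" for s in self.hits)
        return (self.tag, self.category, hit_str)

    @classmethod
    def from_row(cls, cells: list[str]) -> "MappingRecord":
        tag, category, hit_str = cells
        hits = []
        if hit_str:
            for part in hit_str.split(";"):
                gene_id, position, strand = part.rsplit(":", 2)
                hits.append(TagSite(gene_id, int(position), strand))
        return cls(tag, category, hits)


@dataclass
class MappingSummary:
    library_name: str
    total_distinct: int
    category_counts: dict[str, int]
    category_pcts: dict[str, float]  # 2-decimal display values
    n_unambiguously_matched_genes: int
    pct_of_reference_genes: float


def one_mismatch_neighbors(tag: str, anchor_exact: bool = True):
    """Yield the single-substitution neighbours of a 21-nt tag.

    With ``anchor_exact`` (default) only the 17 variable positions mutate,
    giving 3 x 17 = 51 neighbours; otherwise all 21 positions do.
    """
    start = len(ANCHOR) if anchor_exact else 0
    for i in range(start, TAG_LENGTH):
        orig = tag[i]
        for base in _BASES:
            if base != orig:
                yield tag[:i] + base + tag[i + 1 :]


def _ambiguity_suffix(sites: list[TagSite], by_position: bool) -> str:
    if by_position:
        n = len({(s.gene_id, s.position, s.strand) for s in sites})
    else:
        n = len({s.gene_id for s in sites})
    return "1to1" if n == 1 else "1ton"


def _probe(index: ReferenceTagIndex, tag: str, strand: str,
           anchor_exact: bool) -> tuple[list[TagSite], list[TagSite]]:
    """Return (perfect sites, 1-mm sites) on one strand of an index."""
    perfect = index.sites(tag, strand)
    mm1: list[TagSite] = []
    seen: set[str] = set()
    for nb in one_mismatch_neighbors(tag, anchor_exact):
        if nb in seen:
            continue
        seen.add(nb)
        mm1.extend(index.sites(nb, strand))
    return perfect, mm1


def map_tag(
    tag: str,
    transcript_index: ReferenceTagIndex,
    genome_index: ReferenceTagIndex | None = None,
    anchor_exact: bool = True,
) -> MappingRecord:
    """Classify one clean tag by the first non-empty cascade level."""
    if len(tag) != TAG_LENGTH:
        raise ValueError(f"tag {tag!r} has length {len(tag)}, expected {TAG_LENGTH}")
    if "N" in tag:
        raise ValueError(f"tag {tag!r} contains N: not a clean tag")

    t_perf_s, t_mm_s = _probe(transcript_index, tag, SENSE, anchor_exact)
    if t_perf_s:
        return MappingRecord(tag, f"perfect_sense_{_ambiguity_suffix(t_perf_s, False)}", t_perf_s)
    if t_mm_s:
        return MappingRecord(tag, f"mm1_sense_{_ambiguity_suffix(t_mm_s, False)}", t_mm_s)

    t_perf_a, t_mm_a = _probe(transcript_index, tag, ANTISENSE, anchor_exact)
    if t_perf_a:
        return MappingRecord(tag, f"perfect_antisense_{_ambiguity_suffix(t_perf_a, False)}", t_perf_a)
    if t_mm_a:
        return MappingRecord(tag, f"mm1_antisense_{_ambiguity_suffix(t_mm_a, False)}", t_mm_a)

    if genome_index is not None:
        g_perf_s, g_mm_s = _probe(genome_index, tag, SENSE, anchor_exact)
        g_perf_a, g_mm_a = _probe(genome_index, tag, ANTISENSE, anchor_exact)
        g_perf = g_perf_s + g_perf_a
        if g_perf:
            return MappingRecord(tag, f"genome_perfect_{_ambiguity_suffix(g_perf, True)}", g_perf)
        g_mm = g_mm_s + g_mm_a
        if g_mm:
            return MappingRecord(tag, f"genome_mm1_{_ambiguity_suffix(g_mm, True)}", g_mm)

    return MappingRecord(tag, "unknown", [])


def map_library(
    clean_tags,
    transcript_index: ReferenceTagIndex,
    genome_index: ReferenceTagIndex | None = None,
    anchor_exact: bool = True,
) -> list[MappingRecord]:
    """Map every distinct tag of a clean library (a TagCountTable or an
    iterable of tag strings)."""
    tags = clean_tags.counts.keys() if hasattr(clean_tags, "counts") else clean_tags
    return [map_tag(t, transcript_index, genome_index, anchor_exact) for t in tags]


def summarize_mapping(
    records: list[MappingRecord],
    index_stats: IndexStats | None = None,
    library_name: str = "",
) -> MappingSummary:
    """Per-category distinct-tag counts/percentages and the count of genes
    hit unambiguously (>=1 sense 1-to-1 tag, perfect or 1-mm)."""
    counts = Counter(r.category for r in records)
    total = len(records)
    category_counts = {c: counts.get(c, 0) for c in CATEGORIES}
    category_pcts = {
        c: pct_display(100.0 * n / total) if total else 0.0
        for c, n in category_counts.items()
    }
    matched_genes = {
        r.hits[0].gene_id for r in records if r.category in SENSE_1TO1
    }
    n_ref = index_stats.n_reference_sequences if index_stats else 0
    return MappingSummary(
        library_name=library_name,
        total_distinct=total,
        category_counts=category_counts,
        category_pcts=category_pcts,
        n_unambiguously_matched_genes=len(matched_genes),
        pct_of_reference_genes=(
            pct_display(100.0 * len(matched_genes) / n_ref) if n_ref else 0.0
        ),
    )
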