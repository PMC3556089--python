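"""Gene-level tag counting and TPM normalisation, plus the 2^-ddCT utility.

A gene's raw count is the total copy number of its *unambiguous* clean tags
— tags whose sense-strand mapping names exactly one gene, perfect or
1-mismatch (the perfect-only restriction is available via ``perfect_only``).
TPM here is transcripts per million clean tags: raw_count x 1e6 divided by
the library's total clean tag count (not the mapped total). Antisense
1-to-1 tags evidence bidirectional transcription and are tallied separately
but excluded from the expression measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_formats import TagCountTable
from .tag_mapping import MappingRecord


@dataclass
class GeneExpression:
    gene_id: str
    raw_count: int
    tpm: float
    library_name: str
    antisense_count: int = 0


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR measurement: threshold cycles for target and reference gene."""

    target_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        if self.target_ct <= 0 or self.reference_ct <= 0:
            raise ValueError("CT values must be positive cycle numbers")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def quantify(
    mapping_records: list[MappingRecord],
    clean: TagCountTable,
    gene_ids: Iterable[str],
    perfect_only: bool = False,
) -> list[GeneExpression]:
    """Per-gene unambiguous tag counts and TPM for one library.

    ``gene_ids`` fixes the gene universe: genes with no unambiguous tag are
    reported with count 0 so both libraries cover the same genes.
    """
    total_clean = clean.total_copies
    if total_clean == 0:
        raise ValueError("total clean tag count is zero: TPM undefined")
    sense_cats = ("perfect_sense_1to1",) if perfect_only else (
        "perfect_sense_1to1", "mm1_sense_1to1")
    antisense_cats = ("perfect_antisense_1to1",) if perfect_only else (
        "perfect_antisense_1to1", "mm1_antisense_1to1")

    counts: dict[str, int] = {}
    anti: dict[str, int] = {}
    for rec in mapping_records:
        copies = clean.counts.get(rec.tag)
        if copies is None:
            continue
        if rec.category in sense_cats:
            gene = rec.hits[0].gene_id
            counts[gene] = counts.get(gene, 0) + copies
        elif rec.category in antisense_cats:
            gene = rec.hits[0].gene_id
            anti[gene] = anti.get(gene, 0) + copies

    scale = 1e6 / total_clean
    return [
        GeneExpression(
            gene_id=g,
            raw_count=counts.get(g, 0),
            tpm=counts.get(g, 0) * scale,
            library_name=clean.library_name,
            antisense_count=anti.get(g, 0),
        )
        for g in gene_ids
    ]


def delta_delta_ct(treatment: CtMeasurement, control: CtMeasurement) -> float:
    """Relative expression level 2^-ddCT.

    ddCT = (target - reference)_treatment - (target - reference)_control;
    a value of 1.0 means no change relative to the control sample.
    """
    ddct = treatment.delta_ct - control.delta_ct
    return 2.0 ** (-ddct)
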