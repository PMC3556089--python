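"""Raw -> clean tag filtering with exact accounting.

Three filters are applied in a fixed order so the accounting rows are
disjoint: (1) tags containing any N, (2) adaptor tags, (3) distinct tags
whose remaining copy number is 1 (singletons). Copy counts, not distinct
tags, are what the accounting totals trace; the conservation identities

    total_clean_stage1 = total_raw - n_containing_N - n_adaptor
    total_clean        = total_clean_stage1 - n_singleton_copies

hold exactly for every input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import TagCountTable

COPY_NUMBER_BINS: tuple[tuple[str, int, float], ...] = (
    ("2-5", 2, 5),
    ("6-10", 6, 10),
    ("11-20", 11, 20),
    ("21-50", 21, 50),
    ("51-100", 51, 100),
    (">100", 101, float("inf")),
)


@dataclass
class FilterReport:
    """Raw -> clean accounting for one library."""

    total_raw: int
    n_containing_N: int
    n_adaptor: int
    n_singleton_copies: int
    total_clean_stage1: int
    total_clean: int
    total_distinct_clean: int | None = None

    def __post_init__(self) -> None:
        if self.total_clean_stage1 != self.total_raw - self.n_containing_N - self.n_adaptor:
            raise ValueError("stage-1 conservation identity violated")
        if self.total_clean != self.total_clean_stage1 - self.n_singleton_copies:
            raise ValueError("final conservation identity violated")
        for name in ("total_raw", "n_containing_N", "n_adaptor",
                     "n_singleton_copies", "total_clean_stage1", "total_clean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")

    @classmethod
    def from_marginals(
        cls,
        total_raw: int,
        n_containing_N: int,
        n_adaptor: int,
        n_singleton_copies: int,
        total_distinct_clean: int | None = None,
    ) -> "FilterReport":
        """Reconstruct the full accounting from the four published marginals."""
        stage1 = total_raw - n_containing_N - n_adaptor
        return cls(
            total_raw=total_raw,
            n_containing_N=n_containing_N,
            n_adaptor=n_adaptor,
            n_singleton_copies=n_singleton_copies,
            total_clean_stage1=stage1,
            total_clean=stage1 - n_singleton_copies,
            total_distinct_clean=total_distinct_clean,
        )


@dataclass
class CopyNumberDistribution:
    """Distinct-tag counts per copy-number bin of a clean library."""

    bins: list[tuple[str, int, float, int]]  # (label, lo, hi, n_distinct_tags)

    @property
    def total_distinct(self) -> int:
        return sum(n for *_, n in self.bins)

    def as_dict(self) -> dict[str, int]:
        return {label: n for label, _, _, n in self.bins}


def is_adaptor_tag(tag: str, adaptors: Sequence[str]) -> bool:
    """A tag is an adaptor tag iff it equals, or extends as a prefix, a
    configured adaptor sequence."""
    return any(tag.startswith(a) for a in adaptors if a)


def filter_tags(
    raw: TagCountTable, adaptors: Sequence[str] = ()
) -> tuple[TagCountTable, FilterReport]:
    """Apply the N -> adaptor -> singleton filter cascade.

    A count-1 tag containing N is booked under "containing N", never under
    the singleton row; the three accounting rows are disjoint by order.
    """
    adaptors = [a.upper() for a in adaptors]
    n_N = 0
    n_adaptor = 0
    stage1: dict[str, int] = {}
    for tag, count in raw.counts.items():
        if "N" in tag:
            n_N += count
        elif is_adaptor_tag(tag, adaptors):
            n_adaptor += count
        else:
            stage1[tag] = count

    n_singleton = 0
    clean: dict[str, int] = {}
    for tag in sorted(stage1):  # sorted: output independent of input order
        count = stage1[tag]
        if count == 1:
            n_singleton += 1
        else:
            clean[tag] = count

    total_raw = raw.total_copies
    report = FilterReport(
        total_raw=total_raw,
        n_containing_N=n_N,
        n_adaptor=n_adaptor,
        n_singleton_copies=n_singleton,
        total_clean_stage1=total_raw - n_N - n_adaptor,
        total_clean=total_raw - n_N - n_adaptor - n_singleton,
        total_distinct_clean=len(clean),
    )
    return TagCountTable(raw.library_name, clean), report


def copy_number_distribution(clean: TagCountTable) -> CopyNumberDistribution:
    """Bin distinct clean tags by copy number (2-5, 6-10, ..., >100)."""
    bins = []
    for label, lo, hi in COPY_NUMBER_BINS:
        bins.append([label, lo, hi, 0])
    for tag, count in clean.counts.items():
        if count < 2:
            raise ValueError(
                f"tag {tag!r} has copy number {count}: singleton filter not applied"
            )
        for b in bins:
            if b[1] <= count <= b[2]:
                b[3] += 1
                break
    return CopyNumberDistribution([tuple(b) for b in bins])


def low_copy_fraction(dist: CopyNumberDistribution, max_copies: int = 10) -> float:
    """Fraction of distinct tags in bins entirely below ``max_copies + 1``."""
    n_low = sum(n for label, lo, hi, n in dist.bins if hi <= max_copies)
    total = dist.total_distinct
    return n_low / total if total else 0.0
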