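"""Sequencing-saturation analysis: detected genes vs subsampled depth.

Each depth on the grid is a without-replacement subsample of the actual
clean library (multivariate hypergeometric over distinct-tag copy counts).
Subsamples are *nested* — each depth extends the previous draw — so the
detected-gene counts are non-decreasing along the grid for every seed, as
they would be for prefixes of one sequencing run. Genes are counted under
two definitions: detected by any mapped tag (ambiguous included) and
detected by unambiguous (sense 1-to-1) tags only. A library is flagged
saturated once the marginal new-gene rate falls below a configurable
threshold (default: 1 gene per 1e5 additional tags).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np

from .io_formats import TagCountTable
from .tag_mapping import SENSE_1TO1, MappingRecord


@dataclass
class SaturationCurve:
    points: list[tuple[int, int, int]]  # (depth, n_genes_all_tags, n_genes_unambiguous)
    seed: int
    saturated: bool = False

    def __post_init__(self) -> None:
        depths = [d for d, *_ in self.points]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("depth grid must be strictly increasing")


def default_grid(total: int, step_fraction: float = 0.05) -> list[int]:
    """Depths at 5% increments of the library size."""
    step = max(1, int(round(total * step_fraction)))
    grid = list(range(step, total + 1, step))
    if grid and grid[-1] != total:
        grid.append(total)
    return grid


def saturation_curve(
    clean: TagCountTable,
    mapping_records: list[MappingRecord],
    grid: list[int] | None = None,
    seed: int = 0,
    saturation_rate: float = 1e-5,
) -> SaturationCurve:
    """Detected-gene counts at each subsampled depth, nested across depths."""
    tags = list(clean.counts)
    counts = np.array([clean.counts[t] for t in tags], dtype=np.int64)
    total = int(counts.sum())
    if grid is None:
        grid = default_grid(total)
    grid = sorted(grid)
    if grid and grid[-1] > total:
        raise ValueError(f"depth {grid[-1]} exceeds library size {total}")

    by_tag = {r.tag: r for r in mapping_records}
    genes_all: list[frozenset[str]] = []
    genes_unamb: list[str | None] = []
    for t in tags:
        rec = by_tag.get(t)
        if rec is None or not rec.hits:
            genes_all.append(frozenset())
            genes_unamb.append(None)
        else:
            genes_all.append(frozenset(s.gene_id for s in rec.hits))
            genes_unamb.append(rec.hits[0].gene_id if rec.category in SENSE_1TO1 else None)

    rng = np.random.default_rng(seed)
    remaining = counts.copy()
    drawn = np.zeros_like(counts)
    points: list[tuple[int, int, int]] = []
    prev_depth = 0
    for depth in grid:
        incr = depth - prev_depth
        if incr > 0:
            drawn += rng.multivariate_hypergeometric(remaining, incr, method="count")
            remaining = counts - drawn
        seen = drawn > 0
        all_genes = set().union(*(genes_all[i] for i in np.flatnonzero(seen))) if seen.any() else set()
        unamb_genes = {genes_unamb[i] for i in np.flatnonzero(seen) if genes_unamb[i] is not None}
        points.append((depth, len(all_genes), len(unamb_genes)))
        prev_depth = depth

    saturated = False
    if len(points) >= 2:
        (d0, g0, _), (d1, g1, _) = points[-2], points[-1]
        saturated = (g1 - g0) / (d1 - d0) < saturation_rate
    return SaturationCurve(points=points, seed=seed, saturated=saturated)


def expected_genes_detected(
    gene_copy_counts: dict[str, int], total: int, depth: int
) -> float:
    """Closed-form E[detected genes] at a without-replacement depth.

    A gene with t copies among T total is missed with probability
    C(T-t, d) / C(T, d); the expectation sums the complements.
    """
    if depth > total:
        raise ValueError("depth exceeds library size")

    def log_comb(a: int, b: int) -> float:
        return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)

    expected = 0.0
    for t in gene_copy_counts.values():
        if total - t < depth:
            expected += 1.0
        else:
            p_miss = np.exp(log_comb(total - t, depth) - log_comb(total, depth))
            expected += 1.0 - p_miss
    return expected
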