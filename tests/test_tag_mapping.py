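import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgetag.io_formats import TranscriptRecord
from dgetag.reference_index import (
    ANTISENSE,
    SENSE,
    ReferenceTagIndex,
    TagSite,
    extract_reference_tags,
    index_stats,
    revcomp,
)
from dgetag.tag_mapping import (
    CATEGORIES,
    MappingRecord,
    map_library,
    map_tag,
    one_mismatch_neighbors,
    summarize_mapping,
)

T_G1 = "CATG" + "A" * 17
T_G2 = "CATG" + "C" * 17


def make_index(entries):
    return ReferenceTagIndex("transcriptome", {
        tag: [TagSite(g, p, s) for g, p, s in sites] for tag, sites in entries.items()
    })


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def oracle_map(tag, index, genome_index=None):
    """Exhaustive scan: Hamming distance to every reference tag, both strands,
    mismatches confined to the 17-nt tail."""

    def level(idx, strand, dist):
        out = []
        for ref, sites in idx.entries.items():
            if ref[:4] == tag[:4] and hamming(ref[4:], tag[4:]) == dist:
                out.extend(s for s in sites if s.strand == strand)
        return out

    cascade = [
        ("perfect_sense", level(index, SENSE, 0), False),
        ("mm1_sense", level(index, SENSE, 1), False),
        ("perfect_antisense", level(index, ANTISENSE, 0), False),
        ("mm1_antisense", level(index, ANTISENSE, 1), False),
    ]
    if genome_index is not None:
        cascade += [
            ("genome_perfect", level(genome_index, SENSE, 0) + level(genome_index, ANTISENSE, 0), True),
            ("genome_mm1", level(genome_index, SENSE, 1) + level(genome_index, ANTISENSE, 1), True),
        ]
    for name, hits, by_pos in cascade:
        if hits:
            if by_pos:
                n = len({(s.gene_id, s.position, s.strand) for s in hits})
            else:
                n = len({s.gene_id for s in hits})
            return f"{name}_{'1to1' if n == 1 else '1ton'}", hits
    return "unknown", []


class TestCascade:
    def test_perfect_unique_hit(self):
        index = make_index({T_G1: [("g1", 0, SENSE)]})
        rec = map_tag(T_G1, index)
        assert rec.category == "perfect_sense_1to1"
        assert [s.gene_id for s in rec.hits] == ["g1"]

    def test_one_mismatch_two_genes(self):
        query = "CATG" + "A" * 16 + "G"
        index = make_index({T_G1: [("g1", 0, SENSE), ("g2", 5, SENSE)]})
        rec = map_tag(query, index)
        assert rec.category == "mm1_sense_1ton"

    def test_no_hit_anywhere_is_unknown(self):
        index = make_index({T_G1: [("g1", 0, SENSE)]})
        assert map_tag(T_G2, index).category == "unknown"

    def test_perfect_sense_beats_perfect_antisense(self):
        index = make_index({
            T_G1: [("g2", 40, ANTISENSE), ("g1", 0, SENSE)],
        })
        rec = map_tag(T_G1, index)
        assert rec.category == "perfect_sense_1to1"
        assert all(s.strand == SENSE for s in rec.hits)

    def test_mm1_sense_beats_perfect_antisense(self):
        query = "CATG" + "A" * 16 + "G"
        index = make_index({
            T_G1: [("g1", 0, SENSE)],
            query: [("g2", 40, ANTISENSE)],
        })
        assert map_tag(query, index).category == "mm1_sense_1to1"

    def test_transcriptome_beats_genome(self):
        index = make_index({T_G1: [("g1", 0, SENSE)]})
        genome = make_index({T_G1: [("contig1", 99, SENSE)]})
        assert map_tag(T_G1, index, genome).category == "perfect_sense_1to1"

    def test_genome_fallback_by_position(self):
        genome = make_index({T_G2: [("contig1", 10, SENSE), ("contig1", 90, SENSE)]})
        index = make_index({T_G1: [("g1", 0, SENSE)]})
        assert map_tag(T_G2, index, genome).category == "genome_perfect_1ton"

    def test_anchor_mismatch_not_allowed_by_default(self):
        query = "CTTG" + "A" * 17  # differs from T_G1 only inside the anchor
        index = make_index({T_G1: [("g1", 0, SENSE)]})
        assert map_tag(query, index).category == "unknown"
        assert map_tag(query, index, anchor_exact=False).category == "mm1_sense_1to1"

    def test_tag_with_n_rejected(self):
        index = make_index({T_G1: [("g1", 0, SENSE)]})
        with pytest.raises(ValueError, match="N"):
            map_tag("CATG" + "N" * 17, index)


def test_neighbor_count_is_51_with_exact_anchor():
    neighbors = set(one_mismatch_neighbors(T_G1))
    assert len(neighbors) == 51
    assert all(n[:4] == "CATG" and hamming(n, T_G1) == 1 for n in neighbors)


@st.composite
def index_and_queries(draw):
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    n = draw(st.integers(1, 12))
    records = [
        TranscriptRecord(f"g{i}", "".join(rng.choice(list("ACGT"), 80)))
        for i in range(n)
    ]
    index = extract_reference_tags(records, (SENSE, ANTISENSE))
    queries = []
    tags = sorted(index.entries)
    for _ in range(draw(st.integers(1, 8))):
        kind = draw(st.integers(0, 2))
        if kind == 0 or not tags:
            queries.append("CATG" + "".join(rng.choice(list("ACGT"), 17)))
        else:
            base = tags[int(rng.integers(0, len(tags)))]
            if kind == 1:
                queries.append(base)
            else:
                pos = int(rng.integers(4, 21))
                sub = rng.choice([b for b in "ACGT" if b != base[pos]])
                queries.append(base[:pos] + sub + base[pos + 1 :])
    return index, queries


@settings(max_examples=150, deadline=None)
@given(index_and_queries())
def test_map_tag_agrees_with_exhaustive_scan(case):
    index, queries = case
    for q in queries:
        rec = map_tag(q, index)
        expected_cat, expected_hits = oracle_map(q, index)
        assert rec.category == expected_cat
        assert sorted(map(repr, rec.hits)) == sorted(map(repr, expected_hits))


def test_adding_reference_tags_never_demotes():
    rank = {c: i for i, c in enumerate(CATEGORIES)}
    query = "CATG" + "A" * 16 + "G"
    small = make_index({T_G1: [("g1", 0, SENSE)]})
    bigger = make_index({T_G1: [("g1", 0, SENSE)], query: [("g3", 7, SENSE)]})
    cat_small = map_tag(query, small).category
    cat_big = map_tag(query, bigger).category
    # within the cascade, more reference only moves the level up (lower rank),
    # never to unknown
    level = lambda c: rank[c] // 2 if c != "unknown" else rank[c]
    assert level(cat_big) <= level(cat_small)
    assert cat_big != "unknown"


class TestSummary:
    def test_partition_and_percentages(self):
        records = [
            MappingRecord(T_G1, "perfect_sense_1to1", [TagSite("g1", 0, SENSE)]),
            MappingRecord(T_G2, "unknown", []),
            MappingRecord("CATG" + "G" * 17, "perfect_sense_1to1", [TagSite("g1", 3, SENSE)]),
            MappingRecord("CATG" + "T" * 17, "mm1_sense_1to1", [TagSite("g2", 8, SENSE)]),
        ]
        index = make_index({T_G1: [("g1", 0, SENSE)]})
        stats = index_stats(index, [TranscriptRecord("g1", T_G1), TranscriptRecord("g2", T_G2)])
        summary = summarize_mapping(records, stats)
        assert sum(summary.category_counts.values()) == len(records)
        assert summary.category_counts["perfect_sense_1to1"] == 2
        assert summary.category_pcts["perfect_sense_1to1"] == 50.0
        # g1 via two perfect tags counts once; g2 via a 1-mm tag counts too
        assert summary.n_unambiguously_matched_genes == 2
        assert summary.pct_of_reference_genes == 100.0

    def test_zero_records_all_zero(self):
        summary = summarize_mapping([])
        assert summary.total_distinct == 0
        assert all(v == 0 for v in summary.category_counts.values())
        assert all(v == 0.0 for v in summary.category_pcts.values())

    def test_partition_holds_on_pipeline_output(self, small_pipeline):
        for lib in ("Ste", "Fer"):
            records = small_pipeline.mapping[lib]
            summary = summarize_mapping(records)
            assert sum(summary.category_counts.values()) == len(records)
            assert summary.total_distinct == small_pipeline.clean[lib].n_distinct
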