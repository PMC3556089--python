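"""Published accounting of the Brassica CMS floral-bud tag libraries.

The study this pipeline re-implements compared a sterile ("Ste") and a
fertile ("Fer") young-floral-bud library (raw data at GEO accession
GSE42513). Its printed library accounting and annotation marginals serve
as inputs for arithmetic cross-checks: the raw-data totals and the three
filter rows determine the clean totals, the copy-number bins sum to the
distinct-tag totals, and the annotation percentages follow from the
printed numerators and denominators.
"""

from __future__ import annotations

# library accounting: raw -> clean copy totals and distinct-tag bins
LIBRARY_ACCOUNTING = {
    "Ste": {
        "total_raw": 4_415_866,
        "n_containing_N": 17_065,
        "n_adaptor": 198_867,
        "n_singleton_copies": 1_439_360,
        "total_clean": 2_760_574,
        "total_distinct_clean": 242_163,
    },
    "Fer": {
        "total_raw": 4_244_140,
        "n_containing_N": 17_032,
        "n_adaptor": 123_817,
        "n_singleton_copies": 1_388_850,
        "total_clean": 2_714_441,
        "total_distinct_clean": 253_507,
    },
}

# distinct clean tags per copy-number bin
COPY_NUMBER_BINS = {
    "Ste": {"2-5": 162_169, "6-10": 32_958, "11-20": 22_111,
            "21-50": 16_065, "51-100": 5_383, ">100": 3_477},
    "Fer": {"2-5": 170_723, "6-10": 35_528, "11-20": 23_436,
            "21-50": 15_826, "51-100": 4_848, ">100": 3_146},
}

# reference coverage: genes with >=1 CATG site / total annotated genes
REFERENCE_CATG_COVERAGE = {
    "B_oleracea": {"n_with_catg": 45_557, "n_genes": 45_758, "pct": 99.56},
    "B_rapa": {"n_with_catg": 40_908, "n_genes": 41_174, "pct": 99.35},
}

# perfect sense-strand matches (distinct tags) per library and reference
PERFECT_MATCH = {
    ("Ste", "B_oleracea"): {"n": 67_633, "pct": 27.93},
    ("Fer", "B_oleracea"): {"n": 72_088, "pct": 28.44},
    ("Ste", "B_rapa"): {"n": 60_153, "pct": 24.84},
    ("Fer", "B_rapa"): {"n": 64_735, "pct": 25.54},
}

# distinct-tag surplus of Fer over Ste
DISTINCT_TAG_DIFFERENCE = 11_344
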