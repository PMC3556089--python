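"""Map every distinct clean tag through the category cascade.

Writes the per-library category table (counts and percentages of distinct
clean tags, mirroring the taxonomy used for the real libraries) to
results/03_mapping_summary.tsv and reports the Fer-only unknown tags that
emulate transcripts from the alien chromosome.
"""

from _common import RESULTS, default_run

from dgetag.pipeline import fer_only_unknown_tags
from dgetag.reference_index import extract_reference_tags, index_stats
from dgetag.tag_mapping import CATEGORIES, summarize_mapping


def main() -> None:
    result = default_run()
    index = extract_reference_tags(result.reference.transcripts)
    stats = index_stats(index, result.reference.transcripts)
    print(f"reference: {stats.n_with_catg}/{stats.n_reference_sequences} genes "
          f"with CATG sites, {stats.n_unambiguous_reference_tags} unambiguous "
          f"reference tags")

    with open(RESULTS / "03_mapping_summary.tsv", "w") as fh:
        fh.write("library\tcategory\tn_distinct\tpct\n")
        for lib, records in result.mapping.items():
            summary = summarize_mapping(records, stats, lib)
            for cat in CATEGORIES:
                fh.write(f"{lib}\t{cat}\t{summary.category_counts[cat]}"
                         f"\t{summary.category_pcts[cat]}\n")
            print(f"{lib}: {summary.n_unambiguously_matched_genes} genes hit "
                  f"unambiguously ({summary.pct_of_reference_genes}% of reference)")

    fer_only = fer_only_unknown_tags(result)
    print(f"{len(fer_only)} Fer-only unknown tags (alien-chromosome signature)")


if __name__ == "__main__":
    main()
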