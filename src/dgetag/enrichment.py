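"""Hypergeometric GO / pathway enrichment of a DEG list.

With N background genes carrying annotation in the scheme, n of them DEGs,
M genes annotated to a term and m DEGs among those M, the enrichment
p-value is the upper hypergeometric tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n),

the probability of drawing at least m term genes in n draws without
replacement. GO terms are corrected by Bonferroni over the tested terms,
pathway terms by Benjamini-Hochberg step-up (the "Q value"); terms with
m = 0 are omitted from output and from the correction denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationMap

SIGNIFICANCE_THRESHOLD = 0.05


@dataclass
class EnrichmentRecord:
    term_id: str
    term_name: str
    N: int
    n: int
    M: int
    m: int
    p_value: float
    corrected_p: float
    significant: bool = False


def hypergeom_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail probability of >= m annotated genes among n draws."""
    for name, v in (("N", N), ("n", n), ("M", M), ("m", m)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    if M > N or n > N:
        raise ValueError("M and n must not exceed N")
    if m > min(n, M):
        raise ValueError("m must not exceed min(n, M)")
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


def enrich(
    deg_gene_ids,
    annotation: AnnotationMap,
    correction: str | None = None,
    bonferroni_all_terms: bool = False,
) -> list[EnrichmentRecord]:
    """Test every term with at least one DEG for over-representation.

    The background N is the set of genes with annotation in the scheme (not
    the whole gene universe); unannotated DEGs therefore do not enter n.
    ``correction`` defaults to Bonferroni for GO and BH for pathway.
    """
    if correction is None:
        correction = "bonferroni" if annotation.scheme == "GO" else "bh"
    if correction not in {"bonferroni", "bh"}:
        raise ValueError(f"unknown correction {correction!r}")
    if not annotation.gene_terms:
        raise ValueError("annotation map is empty")

    background = annotation.annotated_genes
    degs = frozenset(deg_gene_ids) & background
    N = len(background)
    n = len(degs)
    if n == 0:
        return []

    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.gene_terms.items():
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)

    records = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        M = len(genes)
        m = len(genes & degs)
        if m == 0:
            continue
        records.append(
            EnrichmentRecord(
                term_id=term,
                term_name=annotation.term_names.get(term, term),
                N=N,
                n=n,
                M=M,
                m=m,
                p_value=hypergeom_p(N, n, M, m),
                corrected_p=1.0,
            )
        )
    if not records:
        return []

    pvals = [r.p_value for r in records]
    if correction == "bonferroni":
        k = len(term_genes) if bonferroni_all_terms else len(records)
        corrected = [min(1.0, p * k) for p in pvals]
    else:
        _, corrected, _, _ = multipletests(pvals, method="fdr_bh")
        corrected = list(corrected)
    for r, c in zip(records, corrected):
        r.corrected_p = float(c)
        r.significant = r.corrected_p <= SIGNIFICANCE_THRESHOLD
    return records


def go_slim_frequencies(deg_gene_ids, annotation: AnnotationMap) -> list[tuple[str, str, int, float]]:
    """Per-category DEG counts and percentages for a slim-level annotation.

    Genes annotated to several categories count in each, so percentages need
    not sum to 100. Returns (term_id, term_name, n_degs, pct_of_degs) rows.
    """
    degs = set(deg_gene_ids)
    n_degs = len(degs)
    term_counts: dict[str, int] = {}
    for gene in degs & set(annotation.gene_terms):
        for term in annotation.gene_terms[gene]:
            term_counts[term] = term_counts.get(term, 0) + 1
    return [
        (
            term,
            annotation.term_names.get(term, term),
            count,
            round(100.0 * count / n_degs, 2) if n_degs else 0.0,
        )
        for term, count in sorted(term_counts.items())
    ]
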