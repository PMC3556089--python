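"""Exact significance test for digital expression profiles and DEG calling.

Two libraries of total clean-tag depth N1 ("Ste") and N2 ("Fer") yield
counts x and y for a gene. Under the null hypothesis that the gene is
expressed at the same proportion in both libraries, the distribution of y
conditional on x is

    P(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) ),

i.e. a negative binomial with x+1 successes and success probability
N1/(N1+N2). The two-sided p-value is 2 * min(P(Y <= y), P(Y >= y)) capped
at 1 (the alternative minimum-likelihood convention — summing all outcomes
no more probable than the observed one — is available via ``method``).

Tail sums are evaluated in log-space with compensated summation so that
counts up to 10^6 neither overflow nor lose the small tail; only the
smaller tail is summed directly, the other follows by complementation.

Multiple testing across genes uses the Benjamini-Yekutieli step-up
adjustment (valid under arbitrary dependence); significance requires both
FDR <= 0.001 and |log2(TPM ratio)| >= 1 by default, and genes expressed in
only one library carry an infinite log2 ratio, which places them in the
library-specific subclasses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

DEG_CLASSES = ("up_in_fer", "down_in_fer", "fer_specific", "ste_specific", "unchanged")


@dataclass
class DEThresholds:
    max_fdr: float = 0.001
    min_abs_log2: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.max_fdr <= 1.0):
            raise ValueError("max_fdr must lie in (0, 1]")
        if self.min_abs_log2 < 0:
            raise ValueError("min_abs_log2 must be >= 0")


@dataclass
class DEGRecord:
    gene_id: str
    x: int
    y: int
    n1: int
    n2: int
    tpm_ste: float
    tpm_fer: float
    log2_ratio: float
    p_value: float
    fdr: float
    deg_class: str


class _NullModel:
    """Negative-binomial null P(y | x) for fixed x, N1, N2."""

    def __init__(self, x: int, n1: float, n2: float):
        self.x = x
        self.log_p = math.log(n2) - math.log(n1 + n2)  # failure = extra Fer tag
        self.log_q = math.log(n1) - math.log(n1 + n2)
        self.mean = (x + 1) * n2 / n1

    def logpmf(self, j: np.ndarray | int) -> np.ndarray | float:
        j = np.asarray(j, dtype=float)
        x = self.x
        return (
            gammaln(x + j + 1)
            - gammaln(x + 1)
            - gammaln(j + 1)
            + (x + 1) * self.log_q
            + j * self.log_p
        )

    def lower_tail(self, y: int) -> float:
        """P(Y <= y) by direct log-space summation of y+1 terms."""
        lp = self.logpmf(np.arange(0, y + 1))
        return _sum_exp(lp)

    def upper_tail(self, y: int) -> float:
        """P(Y >= y); terms summed until the geometric remainder vanishes."""
        pieces: list[np.ndarray] = []
        running = 0.0
        j0 = y
        chunk = 4096
        while True:
            js = np.arange(j0, j0 + chunk)
            terms = np.exp(self.logpmf(js))
            pieces.append(terms)
            running += float(terms.sum())
            last_j = j0 + chunk - 1
            # pmf ratio r = p * (x + j + 1) / (j + 1); < 1 beyond the mode
            ratio = math.exp(self.log_p) * (self.x + last_j + 2) / (last_j + 2)
            if ratio < 1.0:
                remainder_bound = float(terms[-1]) * ratio / (1.0 - ratio)
                if remainder_bound <= max(running, 1e-300) * 1e-15:
                    break
            j0 += chunk
        return min(math.fsum(float(t) for arr in pieces for t in arr), 1.0)

    def mode(self) -> int:
        r = self.x + 1
        if r <= 1:
            return 0
        return int(math.floor((r - 1) * math.exp(self.log_p - self.log_q)))


def _sum_exp(log_terms: np.ndarray) -> float:
    if log_terms.size == 0:
        return 0.0
    m = float(np.max(log_terms))
    if m == -math.inf:
        return 0.0
    # exact compensated summation of the rescaled terms
    total = math.fsum(float(v) for v in np.exp(log_terms - m))
    return min(math.exp(m) * total, 1.0)


def dge_pvalue(
    x: int, n1: int, y: int, n2: int, method: str = "double"
) -> float:
    """Two-sided exact p-value for observing (x of N1, y of N2).

    ``method="double"`` (default) doubles the smaller conditional tail;
    ``method="minlike"`` sums every outcome whose null probability does not
    exceed that of the observed y.
    """
    if x < 0 or y < 0 or int(x) != x or int(y) != y:
        raise ValueError("counts must be non-negative integers")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    model = _NullModel(int(x), float(n1), float(n2))

    if y <= model.mean:
        lower = model.lower_tail(y)
        pmf_y = math.exp(float(model.logpmf(y)))
        upper = min(1.0, 1.0 - lower + pmf_y)
    else:
        upper = model.upper_tail(y)
        pmf_y = math.exp(float(model.logpmf(y)))
        lower = min(1.0, 1.0 - upper + pmf_y)

    if method == "double":
        return min(1.0, 2.0 * min(lower, upper))
    if method == "minlike":
        return _minlike_pvalue(model, y, lower, upper)
    raise ValueError(f"unknown method {method!r}")


def _minlike_pvalue(model: _NullModel, y: int, lower: float, upper: float) -> float:
    """Sum of P(j) over all j with P(j) <= P(y), using NB unimodality."""
    mode = model.mode()
    log_py = float(model.logpmf(y))
    if y == mode:
        return 1.0
    if y < mode:
        # find smallest b > mode with pmf(b) <= pmf(y); pmf decreasing there
        lo, hi = mode, mode + 1
        step = 1
        while float(model.logpmf(hi)) > log_py:
            lo = hi
            step *= 2
            hi = mode + step
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if float(model.logpmf(mid)) > log_py:
                lo = mid
            else:
                hi = mid
        return min(1.0, lower + model.upper_tail(hi))
    # y > mode: find largest a < mode with pmf(a) <= pmf(y); pmf increasing up to mode
    if float(model.logpmf(0)) <= log_py:
        lo, hi = 0, mode  # a in [0, mode)
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if float(model.logpmf(mid)) <= log_py:
                lo = mid
            else:
                hi = mid
        other = model.lower_tail(lo)
    else:
        other = 0.0
    return min(1.0, upper + other)


def by_fdr(p_values) -> list[float]:
    """Benjamini-Yekutieli step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=0.05, method="fdr_by")
    return list(adjusted)


def log2_tpm_ratio(x: int, n1: int, y: int, n2: int) -> float:
    """log2 of the Fer/Ste TPM ratio with +/-inf sentinels for one-library genes."""
    if x == 0 and y == 0:
        return 0.0
    if x == 0:
        return math.inf
    if y == 0:
        return -math.inf
    return math.log2((y / n2) / (x / n1))


def classify_degs(
    expr_ste,
    expr_fer,
    n1: int,
    n2: int,
    thresholds: DEThresholds | None = None,
    method: str = "double",
) -> list[DEGRecord]:
    """Test every gene of a paired expression table and call DEG classes.

    Genes with x + y > 0 form the multiple-testing family; significance
    requires both the FDR and the |log2 ratio| threshold. Library-specific
    genes (x = 0 or y = 0) satisfy the ratio criterion through the infinite
    sentinel and are subclasses of up-/down-regulated.
    """
    if thresholds is None:
        thresholds = DEThresholds()
    ste = {e.gene_id: e for e in expr_ste}
    fer = {e.gene_id: e for e in expr_fer}
    if set(ste) != set(fer):
        raise ValueError("expression tables cover different gene universes")

    genes = [e.gene_id for e in expr_ste]
    tested = [g for g in genes if ste[g].raw_count + fer[g].raw_count > 0]
    pvals = {g: dge_pvalue(ste[g].raw_count, n1, fer[g].raw_count, n2, method) for g in tested}
    fdrs = dict(zip(tested, by_fdr([pvals[g] for g in tested])))

    records = []
    for g in genes:
        x, y = ste[g].raw_count, fer[g].raw_count
        ratio = log2_tpm_ratio(x, n1, y, n2)
        p = pvals.get(g, 1.0)
        q = fdrs.get(g, 1.0)
        significant = (
            x + y > 0
            and q <= thresholds.max_fdr
            and abs(ratio) >= thresholds.min_abs_log2
        )
        if not significant:
            cls = "unchanged"
        elif x == 0:
            cls = "fer_specific"
        elif y == 0:
            cls = "ste_specific"
        elif ratio > 0:
            cls = "up_in_fer"
        else:
            cls = "down_in_fer"
        records.append(
            DEGRecord(
                gene_id=g,
                x=x,
                y=y,
                n1=n1,
                n2=n2,
                tpm_ste=ste[g].tpm,
                tpm_fer=fer[g].tpm,
                log2_ratio=ratio,
                p_value=p,
                fdr=q,
                deg_class=cls,
            )
        )
    return records


def deg_class_counts(records: list[DEGRecord]) -> dict[str, int]:
    counts = {c: 0 for c in DEG_CLASSES}
    for r in records:
        counts[r.deg_class] += 1
    # specific classes are subclasses of up/down for reporting
    counts["up_in_fer_total"] = counts["up_in_fer"] + counts["fer_specific"]
    counts["down_in_fer_total"] = counts["down_in_fer"] + counts["ste_specific"]
    return counts
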