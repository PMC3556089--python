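import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import nbinom

from dgetag.diff_expression import (
    DEThresholds,
    by_fdr,
    classify_degs,
    dge_pvalue,
    log2_tpm_ratio,
)
from dgetag.quantification import GeneExpression


def exact_lower_tail(x: int, n1: int, y: int, n2: int) -> Fraction:
    """Rational-arithmetic P(Y <= y | x) under the conditional null."""
    r = Fraction(n2, n1)
    total = Fraction(0)
    for j in range(y + 1):
        total += r**j * Fraction(math.comb(x + j, j), 1) / (1 + r) ** (x + j + 1)
    return total


def exact_pvalue(x: int, n1: int, y: int, n2: int) -> Fraction:
    lower = exact_lower_tail(x, n1, y, n2)
    r = Fraction(n2, n1)
    pmf_y = r**y * Fraction(math.comb(x + y, y), 1) / (1 + r) ** (x + y + 1)
    upper = 1 - lower + pmf_y
    return min(Fraction(1), 2 * min(lower, upper))


class TestExactTest:
    def test_equal_zero_counts_give_p_one(self):
        assert dge_pvalue(0, 10_000, 0, 10_000) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "x,n1,y,n2",
        [(5, 10**6, 40, 10**6), (0, 10**6, 25, 10**6), (100, 2_000_000, 60, 1_500_000)],
    )
    def test_matches_rational_oracle(self, x, n1, y, n2):
        exact = float(exact_pvalue(x, n1, y, n2))
        assert dge_pvalue(x, n1, y, n2) == pytest.approx(exact, rel=1e-10)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 200), st.integers(0, 200), st.integers(10_000, 10**6))
    def test_conditional_kernel_is_symmetric_at_equal_depth(self, x, y, n):
        # p(y|x; N,N) = p(x|y; N,N) holds exactly for the kernel ...
        from dgetag.diff_expression import _NullModel

        a = float(_NullModel(x, n, n).logpmf(y))
        b = float(_NullModel(y, n, n).logpmf(x))
        assert a == pytest.approx(b, rel=1e-12, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 100), st.integers(0, 100), st.integers(10_000, 10**6))
    def test_swapped_pvalue_agrees_within_factor_two(self, x, y, n):
        # ... but the two-sided tail test conditions on x, so swapping the
        # libraries changes the p-value by at most the discreteness of one
        # tail step (a factor <= 2 at equal depths)
        a = dge_pvalue(x, n, y, n)
        b = dge_pvalue(y, n, x, n)
        assert max(a, b) <= 2.0 * min(a, b) * (1 + 1e-9)

    def test_p_decreases_as_y_departs_from_expectation(self):
        x, n1, n2 = 50, 10**6, 10**6
        ps = [dge_pvalue(x, n1, y, n2) for y in (50, 80, 120, 200, 400)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_large_counts_do_not_overflow(self):
        p = dge_pvalue(500_000, 2_760_574, 400_000, 2_714_441)
        assert 0.0 <= p <= 1.0

    def test_null_distribution_normalizes(self):
        # sum_y P(y|x) accumulated far past the mode reaches 1 to < 1e-12
        from dgetag.diff_expression import _NullModel

        model = _NullModel(40, 1_000_000.0, 1_200_000.0)
        lower = model.lower_tail(5_000)
        assert lower == pytest.approx(1.0, abs=1e-12)

    def test_minlike_convention_matches_enumeration(self):
        x, n1, y, n2 = 10, 50_000, 30, 50_000
        r = Fraction(n2, n1)
        pmf = lambda j: r**j * Fraction(math.comb(x + j, j), 1) / (1 + r) ** (x + j + 1)
        p_obs = pmf(y)
        total = sum(pmf(j) for j in range(0, 4_000) if pmf(j) <= p_obs)
        assert dge_pvalue(x, n1, y, n2, method="minlike") == pytest.approx(
            float(total), rel=1e-9
        )

    def test_agrees_with_negative_binomial_formulation(self):
        # independent route: Y|x ~ NB(x+1, N1/(N1+N2))
        for x, y in [(3, 9), (20, 5), (0, 0), (7, 7)]:
            n1, n2 = 800_000, 600_000
            lo = nbinom.cdf(y, x + 1, n1 / (n1 + n2))
            up = nbinom.sf(y - 1, x + 1, n1 / (n1 + n2))
            expected = min(1.0, 2 * min(lo, up))
            assert dge_pvalue(x, n1, y, n2) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("bad", [(-1, 10, 0, 10), (0, 0, 0, 10), (0, 10, 2, 0)])
    def test_invalid_arguments_rejected(self, bad):
        with pytest.raises(ValueError):
            dge_pvalue(*bad)


class TestByFdr:
    def test_single_p_unchanged(self):
        assert by_fdr([0.01]) == pytest.approx([0.01])

    def test_three_p_hand_computation(self):
        # m=3, c(3)=11/6, m*c(m)=5.5: all three adjust to 0.055
        assert by_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.055, 0.055, 0.055])

    def test_all_ones_stay_one(self):
        assert by_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            by_fdr([0.5, 1.5])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_adjusted_dominates_raw_and_is_monotone(self, ps):
        adj = by_fdr(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        assert all(a <= 1.0 + 1e-12 for a in adj)
        order = np.argsort(ps)
        sorted_adj = np.array(adj)[order]
        assert all(b >= a - 1e-12 for a, b in zip(sorted_adj, sorted_adj[1:]))


def expr(gene, count, total, lib):
    return GeneExpression(gene, count, count / total * 1e6, lib)


class TestClassification:
    def make(self, counts, n=10**6, thresholds=None):
        ste = [expr(g, x, n, "Ste") for g, (x, _) in counts.items()]
        fer = [expr(g, y, n, "Fer") for g, (_, y) in counts.items()]
        return {r.gene_id: r for r in classify_degs(ste, fer, n, n, thresholds)}

    def test_fer_specific_gene(self):
        recs = self.make({"g1": (0, 500), "g2": (100, 100)})
        assert recs["g1"].deg_class == "fer_specific"
        assert recs["g1"].log2_ratio == math.inf

    def test_ste_specific_gene(self):
        recs = self.make({"g1": (500, 0), "g2": (100, 100)})
        assert recs["g1"].deg_class == "ste_specific"

    def test_small_fold_change_is_unchanged_regardless_of_p(self):
        recs = self.make({"g1": (100_000, 130_000)})
        assert abs(recs["g1"].log2_ratio) < 1
        assert recs["g1"].deg_class == "unchanged"

    def test_both_zero_is_unchanged_with_p_one(self):
        recs = self.make({"g1": (0, 0), "g2": (10, 900)})
        assert recs["g1"].deg_class == "unchanged"
        assert recs["g1"].p_value == 1.0
        assert recs["g2"].deg_class == "up_in_fer"

    def test_mismatched_universe_rejected(self):
        n = 10**6
        with pytest.raises(ValueError):
            classify_degs([expr("g1", 1, n, "Ste")], [expr("g2", 1, n, "Fer")], n, n)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            DEThresholds(max_fdr=0.0)
        with pytest.raises(ValueError):
            DEThresholds(min_abs_log2=-1.0)

    def test_type_one_error_control_under_global_null(self):
        # equal-proportion libraries: fraction with p <= alpha stays near alpha
        rng = np.random.default_rng(2024)
        n_genes, depth = 400, 200_000
        props = rng.dirichlet(np.full(n_genes, 0.5))
        xs = rng.multinomial(depth, props)
        ys = rng.multinomial(depth, props)
        alpha = 0.05
        ps = np.array([dge_pvalue(int(x), depth, int(y), depth) for x, y in zip(xs, ys)])
        frac = float(np.mean(ps <= alpha))
        se = math.sqrt(alpha * (1 - alpha) / n_genes)
        assert frac <= alpha + 3 * se

    def test_planted_log2_recovered_from_tpm_ratio(self):
        # 4-fold genes at counts >= 50: ratio estimate within +/-0.2 log2
        rng = np.random.default_rng(7)
        depth = 500_000
        base = np.full(60, 200.0)
        other = np.full(440, 1000.0)
        props = np.concatenate([base, other])
        props /= props.sum()
        fer_props = props.copy()
        fer_props[:60] *= 4.0
        fer_props /= fer_props.sum()
        xs = rng.multinomial(depth, props)
        ys = rng.multinomial(depth, fer_props)
        keep = (xs[:60] >= 50) & (ys[:60] >= 50)
        x_k, y_k = xs[:60][keep], ys[:60][keep]
        est = np.log2((y_k / depth) / (x_k / depth))
        # the renormalisation of fer_props shifts all genes by a common
        # offset; compare to the realised median shift of the null genes
        null_shift = np.median(np.log2((ys[60:] + 1) / (xs[60:] + 1)))
        dev = est - null_shift - 2.0
        # per-gene counting noise: SE(log2 ratio) = sqrt(1/x + 1/y)/ln 2
        se = np.sqrt(1.0 / x_k + 1.0 / y_k) / np.log(2)
        assert np.all(np.abs(dev) <= np.maximum(0.3, 3 * se))
        assert abs(dev.mean()) <= 0.2


def test_log2_ratio_sentinels():
    assert log2_tpm_ratio(0, 10, 5, 10) == math.inf
    assert log2_tpm_ratio(5, 10, 0, 10) == -math.inf
    assert log2_tpm_ratio(0, 10, 0, 10) == 0.0
    assert log2_tpm_ratio(10, 100, 40, 200) == pytest.approx(1.0)
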