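import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fiberatlas.data_io import ExpressionMatrix, SampleSheet, ValidationError
from fiberatlas.diffexpr import (
    bh_adjust,
    call_degs,
    call_direction,
    differential_expression,
    log2_fold_change,
    pool_groups,
    two_group_test,
)


def _sheet(samples):
    rows = [
        {"sample_id": s, "tissue": t, "dpa": "", "cultivar": "c"}
        for s, t in samples
    ]
    return SampleSheet(pd.DataFrame(rows))


class TestPoolGroups:
    def test_mean_of_two_samples(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"o1": [2.0], "o2": [4.0], "l1": [1.0]}, index=["g"])
        )
        sheet = _sheet([("o1", "ovule"), ("o2", "fiber"), ("l1", "leaf")])
        pooled = pool_groups(expr, sheet, method="mean")
        assert pooled.values.at["g", "OF"] == 3.0
        assert pooled.values.at["g", "LRS"] == 1.0

    def test_single_sample_groups_identity(self):
        expr = ExpressionMatrix(pd.DataFrame({"a": [5.0], "b": [7.0]}, index=["g"]))
        sheet = _sheet([("a", "fiber"), ("b", "root")])
        pooled = pool_groups(expr, sheet)
        assert pooled.values.at["g", "OF"] == 5.0
        assert pooled.values.at["g", "LRS"] == 7.0

    def test_missing_excluded_from_mean(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"o1": [np.nan], "o2": [4.0], "l1": [0.0]}, index=["g"])
        )
        sheet = _sheet([("o1", "ovule"), ("o2", "ovule"), ("l1", "leaf")])
        pooled = pool_groups(expr, sheet)
        assert pooled.values.at["g", "OF"] == 4.0

    def test_all_missing_stays_missing(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"o1": [np.nan], "l1": [1.0]}, index=["g"])
        )
        sheet = _sheet([("o1", "fiber"), ("l1", "leaf")])
        for method in ("mean", "sum"):
            assert np.isnan(pool_groups(expr, sheet, method).values.at["g", "OF"])

    def test_empty_group_raises(self):
        expr = ExpressionMatrix(pd.DataFrame({"a": [1.0]}, index=["g"]))
        sheet = _sheet([("a", "fiber")])
        with pytest.raises(ValidationError):
            pool_groups(expr, sheet)


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "of,lrs,expected",
        [(3.0, 3.0, 0.0), (8.0, 2.0, np.log2(3.0)), (0.0, 0.0, 0.0)],
    )
    def test_values(self, of, lrs, expected):
        assert log2_fold_change(of, lrs) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            log2_fold_change(-1.0, 1.0)


class TestTwoGroupTest:
    def test_identical_groups_p_one(self):
        assert two_group_test([0, 1], [0, 1]) == pytest.approx(1.0)
        assert two_group_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == pytest.approx(1.0)

    def test_zero_variance_separated_groups_extreme(self):
        p = two_group_test([5.0, 5.0, 5.0], [0.0, 0.0, 0.0])
        assert p < 1e-6

    def test_too_few_values_missing(self):
        assert np.isnan(two_group_test([1.0], [1.0, 2.0]))
        assert np.isnan(two_group_test([1.0, np.nan], [1.0, 2.0]))

    def test_matches_scipy_welch_when_variances_positive(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 2, rng.integers(3, 12))
            expected = stats.ttest_ind(a, b, equal_var=False).pvalue
            assert two_group_test(a, b) == pytest.approx(expected, rel=1e-10)


def _bh_oracle(pvals):
    """Independent brute-force step-up: q_(i) = min_{j>=i} p_(j) * n / j."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    for rank_pos, i in enumerate(order):
        candidates = [
            pvals[order[j]] * n / (j + 1) for j in range(rank_pos, n)
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestBHAdjust:
    def test_step_up_example(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_ties(self):
        assert bh_adjust([1.0])[0] == 1.0
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_missing_propagates(self):
        got = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(got[1])
        # n counted over present values only
        assert np.allclose(got[[0, 2]], _bh_oracle([0.01, 0.02]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10)
    )
    def test_matches_brute_force_oracle(self, pvals):
        assert np.allclose(bh_adjust(pvals), _bh_oracle(pvals), atol=1e-12)


class TestCallDegs:
    @pytest.mark.parametrize(
        "fdr,lfc,expected",
        [(0.001, 3.0, "up"), (0.001, -3.0, "down"), (0.01, 5.0, "ns"),
         (0.001, 1.5, "ns"), (np.nan, 5.0, "ns")],
    )
    def test_direction_rule(self, fdr, lfc, expected):
        assert call_direction(fdr, lfc, alpha=0.005, tau=2.0) == expected

    def _table(self):
        rng = np.random.default_rng(3)
        n = 60
        return pd.DataFrame(
            {
                "feature_id": [f"Ghir_{'AD'[i % 2]}{(i % 9) + 1:02d}G{i:06d}" for i in range(n)],
                "log2fc": rng.normal(0, 3, n),
                "fdr": rng.uniform(0, 0.02, n),
                "subgenome": ["At" if i % 2 == 0 else "Dt" for i in range(n)],
            }
        )

    def test_partition_complete_and_subgenome_sums(self):
        counts = call_degs(self._table())
        assert counts.up + counts.down + counts.ns == 60
        assert counts.by_subgenome["up"].sum() == counts.up
        assert counts.by_subgenome["down"].sum() == counts.down

    def test_raising_tau_never_increases_calls(self):
        table = self._table()
        prev_up, prev_down = np.inf, np.inf
        for tau in (0.5, 1.0, 2.0, 4.0, 8.0):
            c = call_degs(table, tau=tau)
            assert c.up <= prev_up and c.down <= prev_down
            prev_up, prev_down = c.up, c.down


class TestPlantedRecovery:
    def test_fiber_specific_genes_recovered(self, sim):
        """Planted OF-upregulated module genes are recalled at >= 0.95 with
        false-discovery proportion <= 2 * alpha."""
        de = differential_expression(sim.gene_expr, sim.sheet)
        counts = call_degs(de)
        truth = sim.truth["modules"]
        planted_up = set(truth.loc[truth["module"] != "unassigned", "gene_id"])
        called_up = set(de.loc[de["direction"] == "up", "feature_id"])
        recall = len(called_up & planted_up) / len(planted_up)
        fdp = len(called_up - planted_up) / max(len(called_up), 1)
        assert recall >= 0.95
        assert fdp <= 0.01
        assert counts.up + counts.down + counts.ns == len(de)
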