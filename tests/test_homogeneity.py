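"""The neutrosophic chi-square statistic, its pieces, and the decision rule."""

import numpy as np
import pytest
from scipy import stats

from neutrochi import (
    CountTable,
    IndeterminacyInterval,
    NeutrosophicCountTable,
    TestConfig,
    critical_value,
    degrees_of_freedom,
    estimate_pooled_probabilities,
    expected_counts,
    general_interval_statistic,
    neutrosophic_statistic,
    pearson_statistic,
    run_test,
)

from conftest import random_count_table


def two_by_two(a, b, c, d):
    return CountTable(("g1", "g2"), ("c1", "c2"), np.array([[a, b], [c, d]]))


def closed_form_2x2(a, b, c, d):
    """Pearson chi-square for a 2x2 table: N(ad-bc)^2 / (row and column
    product), the standard closed form."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestPooledEstimates:
    def test_brca2_pooled_proportions(self, brca2_table):
        est = estimate_pooled_probabilities(
            NeutrosophicCountTable.degenerate(brca2_table)
        )
        assert est.lower[0] == pytest.approx(77064 / 254252)
        assert est.lower[0] == pytest.approx(0.303101, abs=5e-7)
        assert est.lower.sum() == pytest.approx(1.0, abs=1e-12)
        assert est.upper.sum() == pytest.approx(1.0, abs=1e-12)
        assert est.source_totals == (77064, 49266, 51385, 76537)

    def test_single_group_even_split(self):
        table = CountTable(("g1",), ("c1", "c2"), np.array([[10, 10]]))
        est = estimate_pooled_probabilities(NeutrosophicCountTable.degenerate(table))
        assert est.lower.tolist() == [0.5, 0.5]

    def test_interval_tables_give_interval_probabilities(self, brca2_table):
        upper = CountTable(
            brca2_table.group_labels,
            brca2_table.category_labels,
            brca2_table.counts * 2,
        )
        est = estimate_pooled_probabilities(
            NeutrosophicCountTable(brca2_table, upper)
        )
        # doubling every count leaves proportions unchanged
        np.testing.assert_allclose(est.lower, est.upper)

    def test_all_zero_table_rejected(self):
        table = CountTable(("g1",), ("c1", "c2"), np.zeros((1, 2), int))
        with pytest.raises(ValueError):
            estimate_pooled_probabilities(NeutrosophicCountTable.degenerate(table))


class TestExpectedCounts:
    def test_brca2_first_cell(self, brca2_table):
        p = brca2_table.category_totals / brca2_table.grand_total
        expected = expected_counts(brca2_table, p)
        assert expected[0, 0] == pytest.approx(127079 * 77064 / 254252)
        assert expected[0, 0] == pytest.approx(38517.75, abs=0.01)
        np.testing.assert_allclose(expected.sum(axis=1), brca2_table.group_totals)

    def test_uniform_probabilities(self):
        table = CountTable(("g1",), ("a", "b", "c", "d"), np.array([[40, 20, 20, 20]]))
        np.testing.assert_allclose(
            expected_counts(table, [0.25] * 4), [[25.0] * 4]
        )

    def test_zero_probability_rejected(self):
        table = CountTable(("g1",), ("a", "b"), np.array([[5, 5]]))
        with pytest.raises(ValueError, match="degenerate"):
            expected_counts(table, [1.0, 0.0])

    def test_unnormalized_probabilities_rejected(self):
        table = CountTable(("g1",), ("a", "b"), np.array([[5, 5]]))
        with pytest.raises(ValueError, match="sum"):
            expected_counts(table, [0.6, 0.5])

    def test_small_expected_cells_warn(self):
        table = CountTable(("g1",), ("a", "b"), np.array([[4, 4]]))
        with pytest.warns(UserWarning, match="below"):
            expected_counts(table, [0.5, 0.5])


class TestPearsonStatistic:
    def test_brca2_statistic_and_first_contribution(self, brca2_table):
        p = brca2_table.category_totals / brca2_table.grand_total
        q, contrib = pearson_statistic(brca2_table, p)
        assert q == pytest.approx(0.00664, abs=5e-6)
        assert contrib[0, 0] == pytest.approx(0.000365921, abs=1e-9)
        assert contrib.sum() == pytest.approx(q)
        assert (contrib >= 0).all()

    def test_zero_when_observed_equals_expected(self):
        table = CountTable(("g1", "g2"), ("a", "b"), np.array([[50, 50], [30, 30]]))
        q, _ = pearson_statistic(table, [0.5, 0.5])
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_2x2_closed_form(self):
        table = two_by_two(30, 10, 10, 30)
        p = table.category_totals / table.grand_total
        q, _ = pearson_statistic(table, p)
        assert q == pytest.approx(20.0, rel=1e-12)
        assert q == pytest.approx(closed_form_2x2(30, 10, 10, 30), rel=1e-12)

    def test_matches_scipy_contingency_oracle(self):
        """Independent cross-check: with pooled estimates the statistic is
        the standard contingency-table chi-square (no correction)."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            table = random_count_table(rng, h=int(rng.integers(2, 5)))
            # scipy requires all row/col sums positive
            table = CountTable(
                table.group_labels, table.category_labels, table.counts + 1
            )
            p = table.category_totals / table.grand_total
            q, _ = pearson_statistic(table, p)
            ref = stats.chi2_contingency(table.counts, correction=False).statistic
            assert q == pytest.approx(ref, rel=1e-10)


class TestNeutrosophicStatistic:
    @pytest.mark.parametrize(
        "q,iu,expected_upper",
        [(0.00664, 0.05, 0.006972), (0.00664, 0.2, 0.007968), (3.2, 0.0, 3.2)],
    )
    def test_multiplicative_upper_endpoint(self, q, iu, expected_upper):
        v = neutrosophic_statistic(q, IndeterminacyInterval(0.0, iu))
        assert v.lower == pytest.approx(q)
        assert v.upper == pytest.approx(expected_upper, rel=1e-9)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            neutrosophic_statistic(-1.0, IndeterminacyInterval.classical())


class TestGeneralIntervalStatistic:
    def test_degenerate_matches_multiplicative_form(self, brca2_table):
        data = NeutrosophicCountTable.degenerate(brca2_table)
        est = estimate_pooled_probabilities(data)
        interval = IndeterminacyInterval(0.0, 0.05)
        general = general_interval_statistic(data, est, interval)
        simplified = neutrosophic_statistic(general.determinate_part, interval)
        assert general.lower == pytest.approx(simplified.lower)
        assert general.upper == pytest.approx(simplified.upper)
        assert general.upper == pytest.approx(0.006972, abs=5e-6)

    def test_zero_indeterminacy_collapses(self, brca2_table):
        data = NeutrosophicCountTable.degenerate(brca2_table)
        est = estimate_pooled_probabilities(data)
        v = general_interval_statistic(data, est, IndeterminacyInterval.classical())
        assert v.lower == v.upper

    def test_doubled_upper_table_triples_upper_endpoint(self, brca2_table):
        """Pearson Q scales linearly under uniform count scaling, so with
        upper = 2x lower and I = [0, 1] the upper endpoint is
        Q_L + (2 Q_L) * 1 = 3 Q_L."""
        upper = CountTable(
            brca2_table.group_labels,
            brca2_table.category_labels,
            brca2_table.counts * 2,
        )
        data = NeutrosophicCountTable(brca2_table, upper)
        est = estimate_pooled_probabilities(data)
        v = general_interval_statistic(data, est, IndeterminacyInterval(0.0, 1.0))
        assert v.upper == pytest.approx(3.0 * v.determinate_part, rel=1e-9)


class TestDegreesOfFreedomAndCriticalValue:
    @pytest.mark.parametrize(
        "h,k,mode,expected",
        [
            (2, 4, "homogeneity", 3),
            (2, 4, "goodness_of_fit", 6),
            (1, 2, "goodness_of_fit", 1),
            (3, 5, "homogeneity", 8),
        ],
    )
    def test_df(self, h, k, mode, expected):
        assert degrees_of_freedom(h, k, mode) == expected

    def test_homogeneity_needs_two_groups(self):
        with pytest.raises(ValueError):
            degrees_of_freedom(1, 4, "homogeneity")

    def test_quantile_and_override(self):
        assert critical_value(0.05, 3, override=9.35) == 9.35
        assert critical_value(0.05, 3) == pytest.approx(7.8147, abs=1e-3)
        assert critical_value(0.05, 1) == pytest.approx(3.8415, abs=1e-3)
        # alpha -> 1 sends the threshold to 0
        assert critical_value(0.9999, 3) < 0.01

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            critical_value(0.0, 3)
        with pytest.raises(ValueError):
            critical_value(0.05, 0)


class TestRunTest:
    def test_brca2_worked_example(self, brca2_table):
        cfg = TestConfig(
            indeterminacy=IndeterminacyInterval(0.0, 0.05),
            critical_value_override=9.35,
        )
        result = run_test(brca2_table, cfg)
        assert result.statistic.lower == pytest.approx(0.00664, abs=5e-6)
        assert result.statistic.upper == pytest.approx(0.006972, abs=5e-6)
        assert result.degrees_of_freedom == 3
        assert result.decision == "do_not_reject"
        assert result.cell_contributions.sum() == pytest.approx(
            result.statistic.determinate_part
        )

    def test_strong_association_rejects(self):
        result = run_test(two_by_two(30, 10, 10, 30), TestConfig())
        assert result.statistic.lower == pytest.approx(20.0)
        assert result.degrees_of_freedom == 1
        assert result.critical_value == pytest.approx(3.8415, abs=1e-3)
        assert result.decision == "reject"

    def test_indeterminate_when_interval_straddles_critical(self):
        # Q_L = 5 < 7.81 < Q_U at large I_U for a 2x4 table near the line
        table = CountTable(
            ("g1", "g2"), ("a", "b", "c", "d"),
            np.array([[58, 42, 50, 50], [42, 58, 50, 50]]),
        )
        q, _ = pearson_statistic(table, table.category_totals / table.grand_total)
        crit = critical_value(0.05, 3)
        assert q < crit < 2 * q  # straddles at I_U = 1
        result = run_test(
            table, TestConfig(indeterminacy=IndeterminacyInterval(0.0, 1.0))
        )
        assert result.decision == "indeterminate"

    def test_goodness_of_fit_mode(self):
        table = CountTable(("g1",), ("a", "b", "c", "d"), np.array([[30, 20, 25, 25]]))
        result = run_test(
            table, TestConfig(mode="goodness_of_fit", probabilities=(0.25,) * 4)
        )
        assert result.degrees_of_freedom == 3
        q, _ = pearson_statistic(table, [0.25] * 4)
        assert result.statistic.lower == pytest.approx(q)

    def test_gof_mode_requires_probabilities(self):
        with pytest.raises(ValueError):
            TestConfig(mode="goodness_of_fit")

    def test_label_permutation_invariance(self, brca2_table):
        base = run_test(brca2_table, TestConfig()).statistic.lower
        for permuted in (
            brca2_table.permute_groups([1, 0]),
            brca2_table.permute_categories([3, 1, 0, 2]),
        ):
            assert run_test(permuted, TestConfig()).statistic.lower == pytest.approx(
                base, rel=1e-12
            )

    def test_upper_endpoint_monotone_in_indeterminacy(self, brca2_table):
        uppers = [
            run_test(
                brca2_table,
                TestConfig(indeterminacy=IndeterminacyInterval(0.0, iu)),
            ).statistic.upper
            for iu in (0.0, 0.1, 0.5, 1.0)
        ]
        assert uppers == sorted(uppers)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_trichotomy_is_total_and_consistent(self):
        """Exactly one decision state, determined by where the interval sits
        relative to the critical value."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            table = random_count_table(rng, h=2)
            table = CountTable(
                table.group_labels, table.category_labels, table.counts + 1
            )
            result = run_test(
                table, TestConfig(indeterminacy=IndeterminacyInterval(0.0, 0.5))
            )
            s, crit = result.statistic, result.critical_value
            expected = (
                "do_not_reject" if s.upper <= crit
                else "reject" if s.lower > crit
                else "indeterminate"
            )
            assert result.decision == expected

    def test_interval_table_input(self, brca2_table):
        upper = CountTable(
            brca2_table.group_labels,
            brca2_table.category_labels,
            brca2_table.counts + 50,
        )
        result = run_test(
            NeutrosophicCountTable(brca2_table, upper),
            TestConfig(indeterminacy=IndeterminacyInterval(0.0, 0.05)),
        )
        assert result.statistic.lower == pytest.approx(0.00664, abs=5e-6)
        assert result.statistic.upper >= result.statistic.lower

    def test_report_serialization(self, brca2_table):
        import json

        result = run_test(brca2_table, TestConfig(critical_value_override=9.35))
        payload = json.loads(result.to_json())
        assert payload["decision"] == "do_not_reject"
        assert payload["critical_value"] == 9.35
        assert len(payload["cell_contributions"]) == 2
        text = result.to_text()
        assert "Step 1" in text and "Step 4" in text
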