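"""Count-table transforms, agreement statistics, clustering, dichotomisation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tmaquant.stats import (
    CountTable,
    aggregate_cores,
    coexpression_cluster,
    log2_transform,
    median_split,
    ordinal_agreement,
    spearman,
)


def table(values, index=None, sample_of=None, **kw):
    df = pd.DataFrame(values, index=index)
    return CountTable(data=df, sample_of=sample_of, **kw)


class TestLog2Transform:
    def test_closed_form_values(self):
        t = log2_transform(table({"m": [0, 255, 7]}))
        assert list(t.data["m"]) == pytest.approx([0.0, 8.0, 3.0])
        assert t.is_log2

    def test_double_transform_rejected(self):
        t = log2_transform(table({"m": [1, 2]}))
        with pytest.raises(ValueError, match="already"):
            log2_transform(t)

    def test_strictly_monotone(self):
        t = log2_transform(table({"m": [3, 10, 200]}))
        assert t.data["m"].is_monotonic_increasing

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            table({"m": [-1, 2]})


class TestAggregateCores:
    sample_of = {"S1|1": "S1", "S1|2": "S1", "S2|1": "S2", "S2|2": "S2"}

    def test_mean_of_two_cores(self):
        t = table({"m": [100.0, 300.0, 5.0, 7.0]}, index=list(self.sample_of), sample_of=self.sample_of)
        agg = aggregate_cores(t)
        assert agg.data.loc["S1", "m"] == 200.0

    def test_flagged_core_skipped(self):
        t = table({"m": [np.nan, 150.0, 5.0, 7.0]}, index=list(self.sample_of), sample_of=self.sample_of)
        agg = aggregate_cores(t)
        assert agg.data.loc["S1", "m"] == 150.0

    def test_fully_flagged_sample_dropped(self):
        t = table({"m": [np.nan, np.nan, 5.0, 7.0]}, index=list(self.sample_of), sample_of=self.sample_of)
        agg = aggregate_cores(t)
        assert list(agg.data.index) == ["S2"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cores(CountTable(data=pd.DataFrame(), sample_of={}))

    def test_aggregation_precedes_log_by_contract(self):
        """Mean-then-log differs from log-then-mean; the pipeline fixes the former."""
        t = table({"m": [10.0, 1000.0, 5.0, 7.0]}, index=list(self.sample_of), sample_of=self.sample_of)
        mean_then_log = log2_transform(aggregate_cores(t)).data.loc["S1", "m"]
        log_then_mean = aggregate_cores(log2_transform(t)).data.loc["S1", "m"]
        assert mean_then_log == pytest.approx(np.log2(506))
        assert mean_then_log != pytest.approx(log_then_mean)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([3.0, 1.0, 7.0, 5.0])
        assert spearman(x, 2 * x + 1) == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman(x, x[::-1]) == pytest.approx(-1.0)

    def test_printed_fixture_against_rank_formula(self):
        """x=(1..5), y=(1,3,2,5,4): rho = 1 - 6*4/(5*24) = 0.8."""
        assert spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]) == pytest.approx(0.8)

    def test_constant_vector_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            rho = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho)

    def test_missing_pairs_removed(self):
        rho = spearman([1, 2, np.nan, 4, 5, 6], [2, 4, 9, 8, np.nan, 12])
        assert rho == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [1.0, 2.0])


def bruteforce_two_clusters(X):
    """Naive complete-linkage agglomeration stopped at two clusters."""
    clusters = [frozenset([i]) for i in range(len(X))]

    def complete(a, b):
        return max(np.linalg.norm(X[i] - X[j]) for i in a for j in b)

    while len(clusters) > 2:
        best = min(
            ((complete(a, b), i, j) for (i, a), (j, b) in itertools.combinations(enumerate(clusters), 2)),
        )
        _, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return frozenset(clusters)


class TestCoexpressionCluster:
    def test_two_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        high = rng.normal(10.0, 0.2, (6, 4))
        low = rng.normal(2.0, 0.2, (5, 4))
        df = pd.DataFrame(np.vstack([high, low]))
        _, labels = coexpression_cluster(df)
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicated_rows_stay_together(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0], [1.0, 2.0]])
        _, labels = coexpression_cluster(df)
        assert labels[0] == labels[1] == labels[3]

    def test_outlier_isolated_under_complete_linkage(self):
        df = pd.DataFrame([[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [8.0, 8.0]])
        _, labels = coexpression_cluster(df)
        assert (labels == labels[3]).sum() == 1

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_bruteforce_on_small_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        X = rng.normal(0, 1, (n, int(rng.integers(1, 5))))
        _, labels = coexpression_cluster(pd.DataFrame(X))
        got = frozenset(
            frozenset(np.flatnonzero(labels == k)) for k in np.unique(labels)
        )
        assert got == bruteforce_two_clusters(X)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            coexpression_cluster(pd.DataFrame([[1.0, 2.0]]))

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            coexpression_cluster(pd.DataFrame([[1.0, np.nan], [2.0, 3.0]]))


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert list(labels) == ["low", "low", "high", "high"]

    def test_median_tie_goes_low(self):
        labels = median_split(pd.Series([1.0, 2.0, 3.0]))
        assert list(labels) == ["low", "low", "high"]

    def test_all_equal_all_low_with_warning(self):
        with pytest.warns(UserWarning):
            labels = median_split(pd.Series([5.0, 5.0, 5.0]))
        assert set(labels) == {"low"}

    def test_group_sizes_balanced_up_to_ties(self):
        values = pd.Series([1.0, 2.0, 2.5, 2.5, 3.0, 4.0])
        labels = median_split(values)
        n_tied = int((values == values.median()).sum())
        assert abs((labels == "high").sum() - (labels == "low").sum()) <= n_tied


class TestOrdinalAgreement:
    def test_strictly_increasing_counts_give_rho_one(self):
        counts = [1, 10, 50, 90]
        scores = [0, 1, 2, 3]
        summary, rho = ordinal_agreement(counts, scores)
        assert rho == pytest.approx(1.0)
        assert list(summary["n"]) == [1, 1, 1, 1]

    def test_permuted_scores_match_spearman_internally(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 500, 60)
        scores = rng.integers(0, 4, 60)
        _, rho = ordinal_agreement(counts, scores)
        assert rho == pytest.approx(spearman(counts, scores))

    def test_single_level_gives_summary_only(self):
        summary, rho = ordinal_agreement([5, 8, 9], ["brisk"] * 3)
        assert np.isnan(rho)
        assert summary.shape[0] == 1
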