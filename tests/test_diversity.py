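import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rivercoherence.datatypes import JoinError, OtuTable
from rivercoherence.diversity import (
    collector_curve,
    mpd,
    rarefy,
    reach_contrast,
    shannon,
)


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self):
        table = OtuTable(["a", "b"], ["s"], np.array([[600], [400]]))
        res = rarefy(table, 1000, seed=0)
        assert res.table.counts[:, 0].tolist() == [600, 400]

    def test_shallow_samples_dropped_and_reported(self):
        table = OtuTable(
            ["a", "b"], ["deep", "shallow"], np.array([[600, 500], [400, 499]])
        )
        res = rarefy(table, 1000, seed=0)
        assert res.dropped_samples == ["shallow"]
        assert res.table.sample_ids == ["deep"]

    def test_columns_sum_to_depth(self, default_bundle):
        res = rarefy(default_bundle.table, 1000, seed=3)
        assert (res.table.sample_sums() == 1000).all()

    def test_identical_seed_identical_output(self, default_bundle):
        a = rarefy(default_bundle.table, 1000, seed=11).table
        b = rarefy(default_bundle.table, 1000, seed=11).table
        assert np.array_equal(a.counts, b.counts)

    def test_hypergeometric_expectation(self):
        counts = np.array([[40], [25], [20], [10], [5]])
        table = OtuTable(list("abcde"), ["s"], counts)
        total, depth, reps = 100, 10, 1000
        draws = np.stack(
            [rarefy(table, depth, seed=k).table.counts[:, 0] for k in range(reps)]
        )
        p = counts[:, 0] / total
        expect = depth * p
        # hypergeometric variance with finite-population correction
        var = depth * p * (1 - p) * (total - depth) / (total - 1)
        se = np.sqrt(var / reps)
        assert (np.abs(draws.mean(axis=0) - expect) < 3 * se + 1e-9).all()

    def test_bad_depth_rejected(self, toy_table):
        with pytest.raises(ValueError, match="positive"):
            rarefy(toy_table, 0, seed=0)

    def test_all_samples_below_depth_rejected(self, toy_table):
        with pytest.raises(ValueError, match="fewer than"):
            rarefy(toy_table, 10**6, seed=0)


class TestShannon:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([5, 5, 5, 5], math.log(4)),
            ([7], 0.0),
            ([2, 1, 1], 1.0397),  # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
        ],
    )
    def test_known_values(self, counts, expected):
        assert shannon(np.array(counts)) == pytest.approx(expected, abs=1e-4)

    def test_base_two(self):
        assert shannon(np.array([1, 1]), base="2") == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon(np.array([0, 0]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=20))
    def test_permutation_invariant_and_bounded(self, counts):
        counts = np.array(counts)
        if counts.sum() == 0:
            return
        h = shannon(counts)
        assert h == pytest.approx(shannon(counts[::-1].copy()), abs=1e-12)
        richness = (counts > 0).sum()
        assert -1e-12 <= h <= math.log(richness) + 1e-12


class TestMpd:
    def test_star_tree_unit_branches(self, star_tree):
        assert mpd({"A", "B", "C"}, star_tree) == pytest.approx(2.0)

    def test_two_tips_patristic(self, caterpillar_tree):
        # A and C: 1 + 1 + 2 = 4... use A,B at distance 2 and check a pair
        assert mpd({"A", "B"}, caterpillar_tree) == pytest.approx(2.0)

    def test_caterpillar_three_tips(self, caterpillar_tree):
        # pairwise distances: AB = 2, AC = BC = 4
        assert mpd({"A", "B", "C"}, caterpillar_tree) == pytest.approx(10 / 3)

    def test_single_taxon_missing(self, star_tree):
        assert mpd({"A"}, star_tree) is None

    def test_unknown_taxon_join_error(self, star_tree):
        with pytest.raises(JoinError, match="ZZ"):
            mpd({"A", "ZZ"}, star_tree)

    def test_weighted_equal_abundances_matches_unweighted(self, caterpillar_tree):
        taxa = ["A", "B", "C"]
        uw = mpd(taxa, caterpillar_tree)
        w = mpd(taxa, caterpillar_tree, weighted=True, abundances=np.array([5, 5, 5]))
        assert w == pytest.approx(uw)

    def test_weighted_skews_toward_abundant_pair(self, caterpillar_tree):
        taxa = ["A", "B", "C"]
        w = mpd(
            taxa, caterpillar_tree, weighted=True, abundances=np.array([100, 100, 1])
        )
        assert w < mpd(taxa, caterpillar_tree)  # AB pair (distance 2) dominates


class TestCollectorCurve:
    def test_single_otu_constant(self):
        table = OtuTable(["a"], ["s1", "s2"], np.array([[30, 20]]))
        curve = collector_curve(table, grain=10, reps=5, seed=0)
        assert all(v == 1.0 for _, v in curve)

    def test_final_point_is_observed_richness(self, toy_table):
        curve = collector_curve(toy_table, grain=3, reps=10, seed=0)
        n, v = curve[-1]
        assert n == toy_table.grand_total()
        assert v == (toy_table.otu_sums() > 0).sum()

    def test_monotone_nondecreasing(self, small_bundle):
        curve = collector_curve(small_bundle.table, grain=2000, reps=3, seed=0)
        vals = [v for _, v in curve]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestReachContrast:
    @staticmethod
    def _records(up_vals, down_vals):
        rows = []
        for i, v in enumerate(up_vals):
            rows.append({"sample_id": f"U{i+1}_a", "metric": v})
        for i, v in enumerate(down_vals):
            rows.append({"sample_id": f"D{i+1}_a", "metric": v})
        return pd.DataFrame(rows)

    @staticmethod
    def _frames(n_up, n_down):
        from rivercoherence.datatypes import SampleFrame

        rows = []
        order = 0
        for prefix, reach, n in (("U", "upstream", n_up), ("R", "reservoir", 1), ("D", "downstream", n_down)):
            for i in range(n):
                order += 1
                rows.append(
                    {
                        "sample_id": f"{prefix}{i+1}_a",
                        "site_id": f"{prefix}{i+1}",
                        "reach": reach,
                        "flow_order": order,
                        "campaign": "a",
                    }
                )
        return SampleFrame(pd.DataFrame(rows))

    def test_upstream_higher_positive_ratio(self):
        c = reach_contrast(
            self._records([4, 4], [2, 2]), self._frames(2, 2), "metric"
        )
        assert c.signed_ratio == pytest.approx(2.0)

    def test_downstream_higher_negative_ratio(self):
        c = reach_contrast(
            self._records([2, 2], [4, 4]), self._frames(2, 2), "metric"
        )
        assert c.signed_ratio == pytest.approx(-2.0)

    def test_identical_groups_boundary(self):
        c = reach_contrast(
            self._records([3, 3], [3, 3]), self._frames(2, 2), "metric"
        )
        assert c.signed_ratio == pytest.approx(1.0)
        assert c.anova_p == pytest.approx(1.0)

    def test_matches_scipy_anova(self):
        from scipy.stats import f_oneway

        up, down = [4.0, 5.5, 3.2], [2.0, 2.5, 3.1]
        c = reach_contrast(self._records(up, down), self._frames(3, 3), "metric")
        assert c.anova_p == pytest.approx(f_oneway(up, down).pvalue)
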