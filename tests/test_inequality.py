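import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ancineq.variables as V
from ancineq.inequality import (
    analyze,
    cix_by_group,
    cix_significance,
    concentration_curve,
    concentration_index,
    corrected_index,
    fractional_rank,
)

from conftest import cix_double_sum


class TestFractionalRank:
    def test_four_distinct_equal_weights(self):
        ranked = fractional_rank([10, 20, 30, 40], np.ones(4))
        np.testing.assert_allclose(ranked.rank, [0.125, 0.375, 0.625, 0.875])

    def test_single_record(self):
        ranked = fractional_rank([5], [2.0])
        assert ranked.rank[0] == 0.5

    def test_permutation_leaves_ranks_attached(self, rng):
        values = rng.integers(1, 6, 50)
        w = rng.uniform(0.5, 2, 50)
        ranked = fractional_rank(values, w)
        perm = rng.permutation(50)
        ranked_p = fractional_rank(values[perm], w[perm])
        np.testing.assert_allclose(ranked_p.rank, ranked.rank[perm])

    def test_tied_block_shares_midrank(self):
        ranked = fractional_rank([1, 1, 2], np.ones(3))
        np.testing.assert_allclose(ranked.rank, [1 / 3, 1 / 3, 2.5 / 3])

    def test_constant_stratifier_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fractional_rank([3, 3, 3], np.ones(3))

    @given(
        st.lists(st.integers(1, 5), min_size=2, max_size=40).filter(
            lambda v: len(set(v)) > 1
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_weighted_mean_rank_is_half(self, values):
        rng = np.random.default_rng(abs(hash(tuple(values))) % 2**32)
        w = rng.uniform(0.1, 3, len(values))
        ranked = fractional_rank(values, w)
        assert (w * ranked.rank).sum() / w.sum() == pytest.approx(0.5, abs=1e-10)


class TestConcentrationCurve:
    def test_constant_outcome_on_diagonal(self):
        ranked = fractional_rank([1, 2, 3, 4], np.ones(4), y=np.ones(4))
        curve = concentration_curve(ranked)
        np.testing.assert_allclose(
            curve["cum_outcome_share"], curve["cum_pop_share"], atol=1e-12
        )

    def test_endpoints(self, rng):
        y = rng.integers(0, 2, 30).astype(float)
        y[0] = 1
        ranked = fractional_rank(rng.integers(1, 6, 30), np.ones(30), y=y)
        curve = concentration_curve(ranked)
        np.testing.assert_allclose(curve.iloc[0], [0.0, 0.0], atol=1e-15)
        np.testing.assert_allclose(curve.iloc[-1], [1.0, 1.0], atol=1e-12)

    def test_monotone_coordinates(self, rng):
        y = (rng.random(100) < 0.3).astype(float)
        y[:2] = 1
        ranked = fractional_rank(rng.integers(1, 6, 100), np.ones(100), y=y)
        curve = concentration_curve(ranked)
        assert (curve.diff().dropna() >= -1e-12).all().all()

    def test_top_block_concentration_below_diagonal(self):
        y = np.array([0.0, 0, 0, 1, 1])
        ranked = fractional_rank([1, 2, 3, 4, 4], np.ones(5), y=y)
        curve = concentration_curve(ranked)
        interior = curve.iloc[1:-1]
        assert (interior["cum_outcome_share"] < interior["cum_pop_share"]).all()

    def test_zero_outcome_rejected(self):
        ranked = fractional_rank([1, 2], np.ones(2), y=np.zeros(2))
        with pytest.raises(ValueError):
            concentration_curve(ranked)


class TestConcentrationIndex:
    def test_constant_outcome_zero(self):
        ranked = fractional_rank([1, 2, 3], np.ones(3), y=np.full(3, 2.0))
        assert concentration_index(ranked) == pytest.approx(0.0, abs=1e-15)

    def test_linear_outcome_quarter(self):
        ranked = fractional_rank([1, 2, 3, 4], np.ones(4), y=[1.0, 2, 3, 4])
        assert concentration_index(ranked) == pytest.approx(0.25)

    def test_binary_top_half(self):
        ranked = fractional_rank([1, 2, 3, 4], np.ones(4), y=[0.0, 0, 1, 1])
        assert concentration_index(ranked) == pytest.approx(0.5)

    def test_reversed_stratifier_negates(self, rng):
        values = rng.integers(1, 6, 80)
        y = (rng.random(80) < 0.3).astype(float)
        y[0] = 1
        w = rng.uniform(0.5, 2, 80)
        c = concentration_index(fractional_rank(values, w, y=y))
        c_rev = concentration_index(fractional_rank(-values, w, y=y))
        assert c_rev == pytest.approx(-c, abs=1e-12)

    def test_zero_mean_rejected(self):
        ranked = fractional_rank([1, 2], np.ones(2), y=np.zeros(2))
        with pytest.raises(ValueError):
            concentration_index(ranked)

    @pytest.mark.parametrize("n", [10, 57, 200])
    def test_matches_double_sum_oracle(self, n, rng):
        values = rng.integers(1, 6, n).astype(float)
        y = rng.poisson(2.0, n).astype(float) + (np.arange(n) == 0)
        w = rng.uniform(0.2, 3.0, n)
        c = concentration_index(fractional_rank(values, w, y=y))
        assert c == pytest.approx(cix_double_sum(y, values, w), abs=1e-10)

    def test_rank_of_itself_approaches_third(self, rng):
        n = 100_000
        values = rng.random(n)
        ranked = fractional_rank(values, np.ones(n))
        ranked.y = ranked.rank  # outcome IS the rank
        assert concentration_index(ranked) == pytest.approx(1 / 3, abs=0.01)

    def test_binary_upper_bound(self, rng):
        # for binary y, C <= 1 - mu (+ small-sample slack)
        for n in (200, 2000):
            x = rng.random(n)
            y = (x > np.quantile(x, 0.9)).astype(float)  # extreme pro-rich
            c = concentration_index(fractional_rank(x, np.ones(n), y=y))
            mu = y.mean()
            assert c <= 1 - mu + 2.0 / n

    def test_curve_area_consistency(self, rng):
        # C ~ 1 - 2 * area under the curve for a continuous stratifier
        n = 5000
        x = rng.random(n)
        y = (rng.random(n) < 0.1 + 0.5 * x).astype(float)
        ranked = fractional_rank(x, np.ones(n), y=y)
        c = concentration_index(ranked)
        curve = concentration_curve(ranked)
        area = np.trapezoid(curve["cum_outcome_share"], curve["cum_pop_share"])
        assert c == pytest.approx(1 - 2 * area, abs=0.01)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 60)
        values = rng.integers(1, 8, n)
        if len(np.unique(values)) < 2:
            return
        y = rng.exponential(1.0, n) + 1e-9
        w = rng.uniform(0.1, 5, n)
        c = concentration_index(fractional_rank(values, w, y=y))
        assert -1 <= c <= 1


class TestCorrectedIndices:
    def test_wagstaff_and_erreygers_scale(self):
        ranked = fractional_rank([1, 2, 3, 4], np.ones(4), y=[0.0, 0, 1, 1])
        c = concentration_index(ranked)
        assert corrected_index(ranked, "wagstaff") == pytest.approx(c / 0.5)
        assert corrected_index(ranked, "erreygers") == pytest.approx(4 * 0.5 * c)

    def test_unknown_kind_rejected(self):
        ranked = fractional_rank([1, 2], np.ones(2), y=[0.0, 1])
        with pytest.raises(ValueError):
            corrected_index(ranked, "nope")


class TestSignificance:
    def test_slope_equals_index(self, rng):
        values = rng.integers(1, 6, 300)
        y = (rng.random(300) < 0.2).astype(float)
        y[0] = 1
        w = rng.uniform(0.5, 2, 300)
        ranked = fractional_rank(values, w, y=y)
        se, p = cix_significance(ranked)
        assert 0 < se < 1 and 0 <= p <= 1

    def test_strong_gradient_highly_significant(self, pooled_records):
        res = analyze(
            pooled_records["wealth_quintile"].to_numpy(),
            pooled_records[V.OUTCOME].to_numpy(dtype=float),
            pooled_records[V.WEIGHT_POOLED].to_numpy(),
            name="wealth_quintile",
        )
        assert res.cix > 0
        assert res.p_value < 1e-4
        assert res.p_value_text() == "< 0.0001"

    def test_se_scales_inverse_sqrt_n(self):
        rng = np.random.default_rng(1234)
        sizes = [500, 2000, 8000]
        mean_se = []
        for n in sizes:
            ses = []
            for _ in range(30):
                x = rng.random(n)
                y = (rng.random(n) < 0.2).astype(float)
                y[0] = 1
                se, _ = cix_significance(fractional_rank(x, np.ones(n), y=y))
                ses.append(se)
            mean_se.append(np.mean(ses))
        slope = np.polyfit(np.log(sizes), np.log(mean_se), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_too_few_records_rejected(self):
        ranked = fractional_rank([1, 2, 3], np.ones(3), y=[0.0, 1, 1])
        with pytest.raises(ValueError):
            cix_significance(ranked)


class TestByGroup:
    def _records(self, rng, n=400, sign=+1, country="AA"):
        x = rng.integers(1, 6, n)
        p = 0.05 + 0.03 * (x if sign > 0 else 6 - x)
        return pd.DataFrame(
            {
                V.COUNTRY: country,
                "wealth_quintile": x,
                V.OUTCOME: (rng.random(n) < p).astype(float),
                V.WEIGHT_POOLED: rng.uniform(0.5, 2, n),
            }
        )

    def test_single_group_equals_pooled(self, rng):
        records = self._records(rng)
        results = cix_by_group(records, "wealth_quintile")
        assert len(results) == 2
        assert results[0].cix == pytest.approx(results[1].cix, abs=1e-12)
        assert results[1].group == "pooled"

    def test_identical_groups_identical_index(self, rng):
        a = self._records(rng, country="AA")
        b = a.copy()
        b[V.COUNTRY] = "BB"
        results = cix_by_group(pd.concat([a, b], ignore_index=True),
                               "wealth_quintile")
        by_group = {r.group: r.cix for r in results}
        assert by_group["AA"] == pytest.approx(by_group["BB"], abs=1e-12)

    def test_opposite_gradients_opposite_signs(self, rng):
        a = self._records(rng, n=3000, sign=+1, country="AA")
        b = self._records(rng, n=3000, sign=-1, country="BB")
        results = cix_by_group(pd.concat([a, b], ignore_index=True),
                               "wealth_quintile")
        by_group = {r.group: r.cix for r in results}
        assert by_group["AA"] > 0 > by_group["BB"]

    def test_zero_outcome_group_skipped_with_warning(self, rng):
        a = self._records(rng, country="AA")
        b = self._records(rng, country="BB")
        b[V.OUTCOME] = 0.0
        with pytest.warns(UserWarning, match="BB"):
            results = cix_by_group(pd.concat([a, b], ignore_index=True),
                                   "wealth_quintile")
        assert {r.group for r in results} == {"AA", "pooled"}
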