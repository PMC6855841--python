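"""TAI arithmetic, hourglass permutation test, per-stratum summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phylotx as px

from test_preprocess import make_dataset


def ages_for(data, strata):
    return pd.Series(strata, index=data.gene_ids, name="stratum")


class TestComputeTai:
    def test_equal_expression_averages_ages(self):
        data = make_dataset([[1.0], [1.0]], [0], [1])
        tai = px.compute_tai(data, ages_for(data, [1, 10]))
        assert tai["tai"].iloc[0] == pytest.approx(5.5)

    def test_weighted_two_gene_example(self):
        data = make_dataset([[9.0], [1.0]], [0], [1])
        tai = px.compute_tai(data, ages_for(data, [1, 10]))
        assert tai["tai"].iloc[0] == pytest.approx(1.9)

    def test_constant_age_identity(self):
        rng = np.random.default_rng(0)
        data = make_dataset(rng.exponential(1, (20, 4)) + 0.01,
                            [0, 6, 0, 6], [1, 1, 2, 2])
        tai = px.compute_tai(data, ages_for(data, [3] * 20))
        np.testing.assert_allclose(tai["tai"], 3.0)

    def test_scale_invariance_is_exact(self):
        rng = np.random.default_rng(1)
        vals = rng.exponential(1, (30, 3)) + 0.01
        data = make_dataset(vals, [0, 6, 12], [1, 1, 1])
        strata = rng.integers(1, 11, 30)
        t1 = px.compute_tai(data, ages_for(data, strata))
        scaled = make_dataset(vals * np.array([1.0, 2.0**9, 2.0**-30]), [0, 6, 12], [1, 1, 1])
        t2 = px.compute_tai(scaled, ages_for(scaled, strata))
        assert (t1["tai"] == t2["tai"]).all()
        arb = make_dataset(vals * np.array([1.0, 977.5, 1e-3]), [0, 6, 12], [1, 1, 1])
        t3 = px.compute_tai(arb, ages_for(arb, strata))
        np.testing.assert_allclose(t3["tai"], t1["tai"], rtol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounded_by_stratum_range(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.exponential(1, (15, 4)) + 1e-9
        data = make_dataset(vals, [0, 6, 12, 18], [1, 1, 1, 1])
        strata = rng.integers(1, 11, 15)
        tai = px.compute_tai(data, ages_for(data, strata))
        assert (tai["tai"] >= strata.min() - 1e-12).all()
        assert (tai["tai"] <= strata.max() + 1e-12).all()

    def test_dominant_gene_pulls_tai_to_its_age(self):
        data = make_dataset([[1e9], [1.0]], [0], [1])
        tai = px.compute_tai(data, ages_for(data, [7, 1]))
        assert tai["tai"].iloc[0] == pytest.approx(7.0, abs=1e-6)

    def test_missing_age_rejected(self):
        data = make_dataset([[1.0], [1.0]], [0], [1])
        ages = pd.Series([2], index=[data.gene_ids[0]], name="stratum")
        with pytest.raises(ValueError, match="without an age"):
            px.compute_tai(data, ages)

    def test_zero_sample_rejected(self):
        data = make_dataset([[0.0, 1.0], [0.0, 1.0]], [0, 6], [1, 1])
        with pytest.raises(ValueError, match="zero total"):
            px.compute_tai(data, ages_for(data, [1, 2]))


class TestHourglassTest:
    phases = px.PhasePartition.from_counts((2, 4, 4), 10)

    def _sim(self, delta, seed, n=2000, noise=0.2):
        rng = np.random.default_rng(seed)
        genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")
        ages = pd.Series(rng.integers(1, 11, n), index=genes, name="stratum")
        p = px.ExprSimParams(hourglass_delta=delta, noise_sigma=noise,
                             rng_seed=int(rng.integers(2**31)))
        data, _ = px.simulate_expression(ages, p)
        return px.filter_low_expression(data, 0.5), ages

    def test_constant_age_transcriptome_is_degenerate(self):
        rng = np.random.default_rng(2)
        vals = rng.exponential(1, (50, 20)) + 0.01
        data = make_dataset(vals, list(range(0, 60, 6)) * 2,
                            [1] * 10 + [2] * 10)
        ages = ages_for(data, [4] * 50)
        res = px.reductive_hourglass_test(data, ages, self.phases,
                                          n_permutations=100, seed=0)
        for r in res.values():
            assert abs(r.D_statistic) < 1e-12
            assert r.p_empirical == 1.0
            assert r.degenerate_null
            assert r.p_value is None

    def test_planted_hourglass_is_detected(self):
        data, ages = self._sim(delta=0.5, seed=7, noise=0.1)
        res = px.reductive_hourglass_test(data, ages, self.phases,
                                          n_permutations=1000, seed=7)
        for r in res.values():
            assert r.D_statistic > 0
            assert r.p_empirical < 0.01

    def test_inverse_pattern_is_not_called_hourglass(self):
        data, ages = self._sim(delta=-0.5, seed=8, noise=0.1)
        res = px.reductive_hourglass_test(data, ages, self.phases,
                                          n_permutations=300, seed=8)
        for r in res.values():
            assert r.D_statistic < 0
            assert r.p_empirical > 0.5

    def test_deterministic_under_seed(self):
        data, ages = self._sim(delta=0.3, seed=9)
        r1 = px.reductive_hourglass_test(data, ages, self.phases, 200, seed=5)
        r2 = px.reductive_hourglass_test(data, ages, self.phases, 200, seed=5)
        assert r1[1].p_empirical == r2[1].p_empirical
        assert r1[2].null_mean == r2[2].null_mean

    def test_gaussian_and_empirical_p_shrink_with_effect_size(self):
        """Both p-values decrease (allowing floor ties in the empirical
        one) as the planted effect grows, so they agree in ranking."""
        ps_gauss, ps_emp = [], []
        for delta in (0.0, 0.15, 0.3, 0.6):
            data, ages = self._sim(delta=delta, seed=12, n=1000)
            r = px.reductive_hourglass_test(data, ages, self.phases,
                                            n_permutations=300, seed=3)[1]
            ps_gauss.append(r.p_value)
            ps_emp.append(r.p_empirical)
        assert all(a >= b for a, b in zip(ps_gauss, ps_gauss[1:]))
        assert all(a >= b for a, b in zip(ps_emp, ps_emp[1:]))

    def test_phase_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            px.PhasePartition(early=(0, 1), mid=(1, 2), late=(3,))
        data, ages = self._sim(delta=0.0, seed=1, n=1000)
        bad = px.PhasePartition(early=(0,), mid=(5,), late=(40,))
        with pytest.raises(ValueError, match="out of range"):
            px.reductive_hourglass_test(data, ages, bad, 100, seed=0)


class TestStratumSummaries:
    def test_constant_gene_has_zero_cv(self):
        data = make_dataset([[2.0, 2.0, 2.0]], [0, 6, 12], [1, 1, 1])
        cv = px.cv_by_stratum(data, ages_for(data, [1]))
        assert cv["cv"].iloc[0] == 0.0

    def test_two_point_cv_arithmetic(self):
        data = make_dataset([[1.0, 3.0]], [0, 6], [1, 1])
        cv = px.cv_by_stratum(data, ages_for(data, [1]))
        assert cv["cv"].iloc[0] == pytest.approx(np.sqrt(2) / 2)

    def test_young_amplitude_boost_raises_cv_with_rank(self):
        """Planting amplitude proportional to stratum rank makes the
        median CV non-decreasing in the rank."""
        rng = np.random.default_rng(3)
        n = 3000
        strata = rng.integers(1, 11, n)
        t = np.arange(10.0)
        amp = 0.3 * (strata - 1) / 9.0
        mean = 10.0 * (1.0 + amp[:, None] * np.sin(t / 9 * 2 * np.pi)[None, :])
        vals = mean * np.exp(rng.normal(0, 0.05, mean.shape))
        data = make_dataset(vals, list(range(0, 60, 6)), [1] * 10)
        cv = px.cv_by_stratum(data, ages_for(data, strata))
        med = cv.groupby("stratum")["cv"].median()
        assert (med.diff().dropna() >= -1e-3).all()

    def test_mean_expression_ordering_preserved(self):
        data = make_dataset([[10.0, 10.0], [1.0, 1.0]], [0, 6], [1, 1])
        me = px.mean_expression_by_stratum(data, ages_for(data, [1, 2]))
        summary = px.stratum_summary(me, "mean_tpm")
        assert summary.loc[1, "mean"] > summary.loc[2, "mean"]

    def test_old_high_young_low_trend_recovered(self):
        rng = np.random.default_rng(4)
        n = 2000
        strata = rng.integers(1, 11, n)
        base = 100.0 * 0.7 ** (strata - 1)
        vals = base[:, None] * np.exp(rng.normal(0, 0.3, (n, 8)))
        data = make_dataset(vals, list(range(0, 48, 6)), [1] * 8)
        me = px.mean_expression_by_stratum(data, ages_for(data, strata))
        summary = px.stratum_summary(me, "mean_tpm")
        assert (summary["median"].diff().dropna() < 0).all()
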