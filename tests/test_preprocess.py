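"""Filtering, replicate alignment, sample clustering, normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

import phylotx as px


def make_dataset(values, timepoints, replicates):
    cols = [f"s{i}" for i in range(len(timepoints))]
    vals = pd.DataFrame(values, columns=cols)
    vals.index = pd.Index([f"g{i}" for i in range(len(vals))], name="gene_id")
    meta = pd.DataFrame(
        {"timepoint": timepoints, "replicate": replicates},
        index=pd.Index(cols, name="sample_id"),
    )
    return px.ExpressionDataset(vals, meta)


class TestFilter:
    def test_strict_threshold_semantics(self):
        # means 0.4, 0.5, 2.0: only the strictly-below gene is removed
        data = make_dataset(
            [[0.4, 0.4], [0.5, 0.5], [2.0, 2.0]], [0, 6], [1, 1]
        )
        kept = px.filter_low_expression(data, 0.5)
        assert list(kept.gene_ids) == ["g1", "g2"]

    def test_zero_threshold_is_identity(self):
        data = make_dataset([[0.0, 0.1], [5.0, 1.0]], [0, 6], [1, 1])
        kept = px.filter_low_expression(data, 0.0)
        assert list(kept.gene_ids) == ["g0", "g1"]

    def test_filtering_preserves_values_and_order(self):
        rng = np.random.default_rng(0)
        data = make_dataset(rng.exponential(1, (50, 4)), [0, 6, 0, 6], [1, 1, 2, 2])
        kept = px.filter_low_expression(data, 0.5)
        pd.testing.assert_frame_equal(kept.values, data.values.loc[kept.gene_ids])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        genes = pd.Index([f"g{i:04d}" for i in range(1000)], name="gene_id")
        ages = pd.Series(rng.integers(1, 11, 1000), index=genes)
        p = px.ExprSimParams(frac_low_expression=0.4, rng_seed=seed)
        data, _ = px.simulate_expression(ages, p)
        kept = px.filter_low_expression(data, 0.5)
        # independent recount: plain python loop over rows
        n_expected = 0
        for g in data.gene_ids:
            row = data.values.loc[g].tolist()
            if sum(row) / len(row) >= 0.5:
                n_expected += 1
        assert len(kept.gene_ids) == n_expected


class TestAlignReplicates:
    def test_zero_shift_is_identity(self):
        data = make_dataset([[1, 2, 3, 4]], [0, 6, 0, 6], [1, 1, 2, 2])
        out = px.align_replicates(data, 0.0)
        pd.testing.assert_frame_equal(out.values, data.values)

    def test_six_hour_shift_moves_one_slot(self):
        tps = [6, 12, 18, 6, 12, 18]
        data = make_dataset([[1, 2, 3, 4, 5, 6]], tps, [1, 1, 1, 2, 2, 2])
        out = px.align_replicates(data, 6.0)
        rep2 = out.meta[out.meta["replicate"] == 2]
        assert sorted(rep2["timepoint"]) == [6, 12]
        # replicate-2 samples outside the common window are dropped
        assert len(out.sample_ids) == 4

    def test_non_multiple_shift_rejected(self):
        data = make_dataset([[1, 2, 3, 4]], [6, 12, 6, 12], [1, 1, 2, 2])
        with pytest.raises(ValueError, match="multiple"):
            px.align_replicates(data, 4.0)

    def test_alignment_improves_replicate_agreement(self):
        """On data simulated with a one-slot replicate lag, correcting
        the labels raises the between-replicate profile correlation."""
        rng = np.random.default_rng(1)
        genes = pd.Index([f"g{i:04d}" for i in range(600)], name="gene_id")
        ages = pd.Series(rng.integers(1, 11, 600), index=genes)
        p = px.ExprSimParams(cluster_sizes=(150, 150), frac_low_expression=0.0,
                             noise_sigma=0.1, background_sigma=0.0,
                             replicate_shift=1, rng_seed=4)
        data, _ = px.simulate_expression(ages, p)

        def mean_corr(d):
            common = sorted(set(d.timepoints(1)) & set(d.timepoints(2)))
            a = np.log1p(d.replicate_matrix(1)[common].to_numpy())
            b = np.log1p(d.replicate_matrix(2)[common].to_numpy())
            cors = [np.corrcoef(a[i], b[i])[0, 1] for i in range(len(a))
                    if a[i].std() > 0 and b[i].std() > 0]
            return np.mean(cors)

        before = mean_corr(data)
        after = mean_corr(px.align_replicates(data, 6.0))
        assert after > before


class TestSampleClustering:
    def test_identical_samples_merge_first(self):
        rng = np.random.default_rng(0)
        base = rng.exponential(1, 30)
        vals = np.column_stack([base, base, rng.exponential(1, 30)])
        data = make_dataset(vals, [0, 6, 12], [1, 1, 1])
        dendro = px.sample_correlation_clustering(data)
        first = dendro.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == 0.0

    def test_rank_identical_samples_merge_before_reversed(self):
        x = np.arange(1.0, 21.0)
        vals = np.column_stack([x, x**2, x[::-1]])  # s0, s1 rank-identical
        data = make_dataset(vals, [0, 6, 12], [1, 1, 1])
        dendro = px.sample_correlation_clustering(data)
        first = dendro.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_two_planted_phases_separate(self):
        """Growth vs late-activation programs put early and late samples
        in different arms of the dendrogram."""
        rng = np.random.default_rng(2)
        genes = pd.Index([f"g{i:04d}" for i in range(800)], name="gene_id")
        ages = pd.Series(rng.integers(1, 11, 800), index=genes)
        p = px.ExprSimParams(frac_low_expression=0.3, noise_sigma=0.2, rng_seed=6)
        data, _ = px.simulate_expression(ages, p)
        filt = px.filter_low_expression(data, 0.5)
        dendro = px.sample_correlation_clustering(filt)
        groups = dendro.cut(2)
        tp = filt.meta["timepoint"]
        # each of the two groups spans a contiguous time range
        g1 = sorted(tp[groups == 1].unique())
        g2 = sorted(tp[groups == 2].unique())
        assert max(g1) < min(g2) or max(g2) < min(g1)

    def test_permutation_invariance_of_merge_heights(self):
        rng = np.random.default_rng(3)
        vals = rng.exponential(1, (100, 6))
        data = make_dataset(vals, [0, 6, 12, 18, 24, 30], [1] * 6)
        perm = [3, 0, 5, 1, 4, 2]
        data_p = px.ExpressionDataset(
            data.values.iloc[:, perm].copy(),
            data.meta.iloc[perm].assign(timepoint=data.meta["timepoint"].to_numpy()).copy(),
        )
        d1 = px.sample_correlation_clustering(data)
        d2 = px.sample_correlation_clustering(data_p)
        np.testing.assert_allclose(
            np.sort(d1.linkage[:, 2]), np.sort(d2.linkage[:, 2]), rtol=1e-9
        )


class TestNormalize:
    def test_zscore_invariants(self):
        rng = np.random.default_rng(4)
        data = make_dataset(rng.exponential(5, (40, 6)),
                            [0, 6, 12, 0, 6, 12], [1, 1, 1, 2, 2, 2])
        norm = px.normalize(data)
        z = norm.values.to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)

    def test_constant_gene_excluded(self):
        data = make_dataset([[2.0, 2.0, 2.0], [1.0, 2.0, 4.0]], [0, 6, 12], [1, 1, 1])
        norm = px.normalize(data)
        assert norm.excluded == ["g0"]
        assert list(norm.values.index) == ["g1"]

    def test_two_point_algebra(self):
        # tpm (0, 3) -> log2 (0, 2) -> symmetric z-scores
        data = make_dataset([[0.0, 3.0]], [0, 6], [1, 1])
        norm = px.normalize(data)
        np.testing.assert_allclose(norm.values.to_numpy(), [[-1.0, 1.0]])

    def test_scale_invariance_without_offset(self):
        rng = np.random.default_rng(5)
        vals = rng.exponential(5, (30, 6)) + 0.1
        data = make_dataset(vals, [0, 6, 12, 18, 24, 30], [1] * 6)
        scaled = make_dataset(vals * 37.0, [0, 6, 12, 18, 24, 30], [1] * 6)
        n1 = px.normalize(data, offset=0.0)
        n2 = px.normalize(scaled, offset=0.0)
        np.testing.assert_allclose(n1.values.to_numpy(), n2.values.to_numpy(),
                                   rtol=1e-9, atol=1e-9)

    def test_per_replicate_mode(self):
        rng = np.random.default_rng(6)
        data = make_dataset(rng.exponential(5, (20, 6)),
                            [0, 6, 12, 0, 6, 12], [1, 1, 1, 2, 2, 2])
        norm = px.normalize(data, per_replicate=True)
        for rep in (1, 2):
            cols = norm.meta.index[norm.meta["replicate"] == rep]
            z = norm.values[cols].to_numpy()
            np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
            np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)
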