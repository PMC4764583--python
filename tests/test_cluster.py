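"""Profile/sample clustering and Jaccard stability."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from polysome.cluster import (
    ProfileClusterer,
    SampleClusterer,
    cluster_samples,
    cut_to_clusters,
    hcluster,
    jaccard_stability,
    linkage_to_newick,
    meta_profiles,
    spearman_distance_matrix,
)
from polysome.quantify import FRACTIONS
from polysome.simulate import make_archetypes, simulate_counts


class TestSpearmanDistance:
    def test_identical_rows_distance_zero(self):
        d = spearman_distance_matrix(np.array([[1.0, 2, 3], [1.0, 2, 3]]))
        assert d[0, 1] == pytest.approx(0.0)

    def test_reversed_ranks_distance_two(self):
        d = spearman_distance_matrix(np.array([[1.0, 2, 3], [3.0, 2, 1]]))
        assert d[0, 1] == pytest.approx(2.0)

    def test_hand_computed_case(self):
        # brute-force rank correlation of (1,2,3) vs (1,3,2) is 0.5
        assert spearmanr([1, 2, 3], [1, 3, 2]).statistic == pytest.approx(0.5)
        d = spearman_distance_matrix(np.array([[1.0, 2, 3], [1.0, 3, 2]]))
        assert d[0, 1] == pytest.approx(0.5)

    def test_constant_row_flagged_with_unit_distance(self):
        with pytest.warns(UserWarning, match="constant"):
            d = spearman_distance_matrix(np.array([[1.0, 1, 1], [1.0, 2, 3]]))
        assert d[0, 1] == 1.0
        assert d[0, 0] == 0.0

    def test_symmetric_zero_diagonal_bounded(self):
        rng = np.random.default_rng(3)
        x = rng.random((30, 9))
        d = spearman_distance_matrix(x)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 2).all()

    def test_invariant_under_monotone_row_transform(self):
        rng = np.random.default_rng(4)
        x = rng.random((10, 9))
        d1 = spearman_distance_matrix(x)
        d2 = spearman_distance_matrix(np.exp(3 * x))
        np.testing.assert_allclose(d1, d2, atol=1e-12)


class TestHcluster:
    def test_two_points_merge_at_their_distance(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        z = hcluster(d, "complete")
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(0.7)

    def test_near_pair_merges_first(self):
        # brute force over merge orders: {0,1} at 0.1 beats anything with 2
        d = np.array([[0.0, 0.1, 5.0], [0.1, 0.0, 5.0], [5.0, 5.0, 0.0]])
        z = hcluster(d, "complete")
        assert set(z[0, :2].astype(int)) == {0, 1}

    def test_row_permutation_gives_same_partition(self):
        rng = np.random.default_rng(5)
        x = rng.random((20, 9))
        d = spearman_distance_matrix(x)
        labels = cut_to_clusters(hcluster(d, "ward"), k=4).labels
        perm = rng.permutation(20)
        d_p = spearman_distance_matrix(x[perm])
        labels_p = cut_to_clusters(hcluster(d_p, "ward"), k=4).labels
        assert adjusted_rand_score(labels[perm], labels_p) == pytest.approx(1.0)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            hcluster(np.zeros((3, 4)))


class TestCutToClusters:
    def _tree(self, n=8, seed=6):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 9))
        return hcluster(spearman_distance_matrix(x), "ward"), x

    def test_k_equals_n_gives_singletons(self):
        z, x = self._tree()
        res = cut_to_clusters(z, k=len(x))
        assert res.k == len(x)
        assert len(set(res.labels)) == len(x)

    def test_k_one_gives_single_cluster(self):
        z, _ = self._tree()
        assert set(cut_to_clusters(z, k=1).labels) == {1}

    def test_k_beyond_n_rejected(self):
        z, x = self._tree()
        with pytest.raises(ValueError):
            cut_to_clusters(z, k=len(x) + 1)

    def test_labels_contiguous_from_one(self):
        z, _ = self._tree(n=20)
        labels = cut_to_clusters(z, k=5).labels
        assert sorted(set(labels)) == [1, 2, 3, 4, 5]

    def test_planted_two_archetypes_recovered_perfectly(self):
        arcs = make_archetypes(2)
        counts, truth = simulate_counts(
            arcs, n_genes=20, isoforms_per_gene={2: 1.0}, depth=1e6,
            dispersion=50.0, seed=11,
        )
        avg = counts.T.groupby(
            counts.columns.map(lambda c: c.rsplit("_", 1)[0])
        ).mean().T.drop(columns="cyto")
        est = ProfileClusterer(n_clusters=2).fit(avg)
        assert adjusted_rand_score(truth["archetype"], est.labels_) == 1.0

    def test_refine_mode_separates_distinguishable_profiles(self, synth_normalized):
        _, rel, _ = synth_normalized
        sub = rel.iloc[:400]
        res = cut_to_clusters(
            ProfileClusterer(n_clusters=2).fit(sub).linkage_matrix_,
            matrix=sub, refine=True, rho_threshold=0.95,
        )
        profiles = meta_profiles(sub, res.assignments)
        means = np.vstack([p.mean.to_numpy() for p in profiles])
        rho = 1.0 - spearman_distance_matrix(means)
        np.fill_diagonal(rho, -1)
        assert rho.max() < 0.95


class TestMetaProfiles:
    def test_identical_rows_zero_spread(self):
        m = pd.DataFrame([[0.2, 0.8], [0.2, 0.8]], index=["a", "b"])
        p = meta_profiles(m, pd.Series([1, 1], index=["a", "b"]))[0]
        np.testing.assert_allclose(p.mean, [0.2, 0.8])
        np.testing.assert_allclose(p.sd, 0.0)

    def test_two_member_hand_computation(self):
        m = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"])
        p = meta_profiles(m, pd.Series([1, 1], index=["a", "b"]))[0]
        np.testing.assert_allclose(p.mean, [0.5, 0.5])
        np.testing.assert_allclose(p.sd, [0.7071, 0.7071], atol=1e-4)

    def test_missing_members_rejected(self):
        m = pd.DataFrame([[0.0, 1.0]], index=["a"])
        with pytest.raises(KeyError):
            meta_profiles(m, pd.Series([1, 2], index=["a", "zz"]))


class TestJaccardStability:
    @staticmethod
    def _clusterer(k):
        def run(x):
            return ProfileClusterer(
                n_clusters=k, metric="euclidean", linkage="complete"
            ).fit_predict(x)

        return run

    def _separated_data(self, seed=0):
        rng = np.random.default_rng(seed)
        return np.vstack(
            [rng.normal(c, 0.05, size=(12, 5)) for c in (0.0, 5.0, 10.0)]
        )

    def test_zero_jitter_is_identity(self):
        x = self._separated_data()
        rep = jaccard_stability(
            x, self._clusterer(3), schemes=("jitter",), n_resamples=5,
            seed=1, jitter_scale=0.0,
        )
        assert (rep.per_cluster.to_numpy() == 1.0).all()

    def test_single_cluster_reference(self):
        x = self._separated_data()
        rep = jaccard_stability(
            x, self._clusterer(1), schemes=("jitter", "noise"), n_resamples=5, seed=1
        )
        assert (rep.per_cluster.to_numpy() == 1.0).all()

    def test_well_separated_clusters_stable_under_all_schemes(self):
        x = self._separated_data()
        rep = jaccard_stability(x, self._clusterer(3), n_resamples=50, seed=2)
        assert rep.per_cluster.min().min() >= 0.75
        assert rep.stable.all().all()

    def test_coefficients_bounded(self, synth_normalized):
        v, _, _ = synth_normalized
        rep = jaccard_stability(
            v.T.to_numpy(), self._clusterer(4), n_resamples=20, seed=3
        )
        vals = rep.per_cluster.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_invalid_resample_count_rejected(self):
        with pytest.raises(ValueError):
            jaccard_stability(np.zeros((4, 2)), self._clusterer(2), n_resamples=0)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            jaccard_stability(
                self._separated_data(), self._clusterer(3), schemes=("magic",)
            )


class TestClusterSamples:
    def test_duplicated_column_merges_at_height_zero(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.random((50, 3)), columns=["a", "b", "c"])
        m["a2"] = m["a"]
        res = cluster_samples(m, k=3)
        assert res.assignments["a"] == res.assignments["a2"]
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_two_columns_single_merge(self):
        m = pd.DataFrame(np.random.default_rng(8).random((10, 2)), columns=["x", "y"])
        res = cluster_samples(m, k=2)
        assert res.linkage_matrix.shape == (1, 4)

    def test_gradient_subgroups_on_synthetic_data(self, synth_normalized):
        """Cutting into 4 groups separates cyto, 80S, low and high polysomes."""
        v, _, _ = synth_normalized
        res = cluster_samples(v, k=4)
        groups = {
            frozenset(res.assignments.index[res.assignments == lab])
            for lab in set(res.assignments)
        }
        expected = {
            frozenset({"cyto_rep1", "cyto_rep2"}),
            frozenset({"mono_rep1", "mono_rep2"}),
            frozenset({f"p{i}_rep{r}" for i in (2, 3, 4) for r in (1, 2)}),
            frozenset(
                {f"p{i}_rep{r}" for i in (5, 6, 7) for r in (1, 2)}
                | {"p8plus_rep1", "p8plus_rep2"}
            ),
        }
        assert groups == expected

    def test_sample_clusterer_estimator_contract(self, synth_normalized):
        v, _, _ = synth_normalized
        est = SampleClusterer(n_clusters=4)
        labels = est.fit_predict(v)
        assert len(labels) == v.shape[1]
        assert est.get_params()["n_clusters"] == 4


class TestNewick:
    def test_round_trips_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(9)
        x = rng.random((6, 9))
        z = hcluster(spearman_distance_matrix(x), "ward")
        nwk = linkage_to_newick(z, [f"iso{i}" for i in range(6)])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == [
            f"iso{i}" for i in range(6)
        ]
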