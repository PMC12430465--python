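import numpy as np
import pytest

import roplsda.split as split_mod
from roplsda import (
    FeatureTable, RecursiveOPLSDA, SplitConfig, embed, pairwise_grid,
    propose_split, recursive_fit, validate_split,
)


@pytest.fixture
def fast_cfg():
    # fewer permutations/restarts than the defaults, but t-SNE stays fully
    # converged: truncated runs leave lobes diffuse and distort silhouettes
    return SplitConfig(n_perm=99, kmeans_restarts=10, seed=0)


def planted_table(rng, n_per_group=30, d=50, n_inf=20, effect=3.0):
    """Two groups, `n_inf` features shifted by `effect` sd in group B."""
    Z = rng.normal(5.0, 1.0, size=(2 * n_per_group, d))
    Z[n_per_group:, :n_inf] += effect
    ids = [f"s{i}" for i in range(2 * n_per_group)]
    truth = np.array([0] * n_per_group + [1] * n_per_group)
    return FeatureTable(ids, [f"f{j}" for j in range(d)], np.exp(Z), "raw"), truth


class TestConfig:
    def test_min_node_floor(self):
        with pytest.raises(ValueError, match="min_node"):
            SplitConfig(min_node=4)

    def test_threshold_ranges(self):
        with pytest.raises(ValueError):
            SplitConfig(alpha=1.5)
        with pytest.raises(ValueError):
            SplitConfig(silhouette_threshold=2.0)


class TestEmbed:
    def test_auto_perplexity_clipping(self, fast_cfg):
        # n=10: floor((10-1)/3) = 3, below the cap
        from roplsda.split import _auto_perplexity
        assert _auto_perplexity(10) == 3
        assert _auto_perplexity(1000) == 8

    def test_shape_and_determinism(self, rng, fast_cfg):
        X = rng.normal(size=(20, 6))
        E1 = embed(X, fast_cfg, seed=5)
        E2 = embed(X, fast_cfg, seed=5)
        assert E1.shape == (20, 3)
        np.testing.assert_array_equal(E1, E2)

    def test_duplicate_rows_stay_close(self, rng, fast_cfg):
        X = rng.normal(size=(15, 6))
        X[7] = X[3]  # duplicated sample
        E = embed(X, fast_cfg, seed=1)
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(E))
        dup = D[3, 7]
        assert dup <= np.percentile(pdist(E), 10)

    def test_too_small_node_rejected(self, rng, fast_cfg):
        with pytest.raises(ValueError, match="too small"):
            embed(rng.normal(size=(3, 4)), fast_cfg)


class TestProposeSplit:
    def test_two_point_masses_perfect_silhouette(self, fast_cfg):
        E = np.vstack([np.zeros((5, 3)), np.full((5, 3), 10.0)])
        E += np.random.default_rng(0).normal(0, 1e-6, E.shape)
        labels, sil = propose_split(E, fast_cfg)
        assert sil > 0.999
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_identical_points_rejected(self, fast_cfg):
        labels, sil = propose_split(np.ones((8, 3)), fast_cfg)
        assert sil == -1.0

    def test_single_blob_fails_gate_most_seeds(self, rng, fast_cfg):
        # one isotropic cluster should not look like two
        fails = 0
        for s in range(10):
            E = rng.normal(size=(60, 3))
            _, sil = propose_split(E, fast_cfg, seed=s)
            fails += sil < fast_cfg.silhouette_threshold
        assert fails >= 9


class TestValidateSplit:
    def test_planted_two_class_recovery(self, rng, fast_cfg):
        table, truth = planted_table(rng)
        from roplsda import log_transform
        logged = log_transform(table)
        report, markers = validate_split(logged.values, truth, fast_cfg, seed=0,
                                         feature_ids=table.feature_ids,
                                         X_raw=table.values)
        assert report.p_perm < 0.05
        sig = {m.feature_id for m in markers if m.significant}
        planted = {f"f{j}" for j in range(20)}
        assert len(sig & planted) / 20 >= 0.8

    def test_random_labels_rejected(self, rng, fast_cfg):
        X = rng.normal(size=(30, 20))
        labels = np.array([0, 1] * 15)
        report, _ = validate_split(X, labels, fast_cfg, seed=1)
        assert report.p_perm >= 0.05

    def test_identical_rows_give_nonpositive_q2(self, fast_cfg):
        X = np.tile(np.arange(10.0), (24, 1))
        labels = np.array([0] * 12 + [1] * 12)
        report, _ = validate_split(X, labels, fast_cfg, seed=2)
        assert report.q2 <= 0
        assert report.p_perm >= 0.05

    def test_tiny_cluster_refused(self, rng, fast_cfg):
        X = rng.normal(size=(20, 5))
        labels = np.array([0] * 2 + [1] * 18)
        with pytest.raises(ValueError, match=">= 3"):
            validate_split(X, labels, fast_cfg)


class TestRecursiveFit:
    def test_planted_split_found_and_leaves_partition(self, rng, fast_cfg):
        table, truth = planted_table(rng, n_per_group=20, d=40, n_inf=15)
        tree = recursive_fit(table, fast_cfg)
        assert tree.n_accepted >= 1
        # leaves partition the samples exactly
        leaf_ids = [s for leaf in tree.leaves() for s in leaf.sample_ids]
        assert sorted(leaf_ids) == sorted(table.sample_ids)
        # first split matches the planted structure
        from sklearn.metrics import adjusted_rand_score
        first = tree.accepted_splits[0]
        assert adjusted_rand_score(truth[first.sample_indices],
                                   first.child_assignment) == 1.0

    def test_seed_determinism(self, rng, fast_cfg):
        table, _ = planted_table(rng, n_per_group=15, d=30, n_inf=10)
        t1 = recursive_fit(table, fast_cfg)
        t2 = recursive_fit(table, fast_cfg)
        assert t1.n_accepted == t2.n_accepted
        for n1, n2 in zip(t1.nodes(), t2.nodes()):
            assert n1.sample_ids == n2.sample_ids
            assert n1.rejection_reason == n2.rejection_reason
            if n1.report:
                assert n1.report.q2 == n2.report.q2
                assert n1.report.p_perm == n2.report.p_perm

    def test_no_oplsda_fitted_when_silhouette_gate_fails(self, rng, fast_cfg,
                                                         monkeypatch):
        # homogeneous data: every node dies at the silhouette gate, so the
        # engine must never reach the validation stage
        calls = []
        orig = split_mod.validate_split

        def counting(*args, **kwargs):
            calls.append(1)
            return orig(*args, **kwargs)

        monkeypatch.setattr(split_mod, "validate_split", counting)
        Z = rng.normal(5.0, 1.0, size=(40, 30))
        table = FeatureTable([f"s{i}" for i in range(40)],
                             [f"f{j}" for j in range(30)], np.exp(Z), "raw")
        tree = recursive_fit(table, fast_cfg)
        if tree.n_accepted == 0 and all(
                n.rejection_reason == "low_silhouette" for n in tree.leaves()
                if n.n_samples >= fast_cfg.min_node):
            assert calls == []

    def test_accepted_children_partition_parent(self, rng, fast_cfg):
        table, _ = planted_table(rng, n_per_group=20, d=40, n_inf=15)
        tree = recursive_fit(table, fast_cfg)
        for node in tree.nodes():
            if node.children:
                a, b = node.children
                assert set(a.sample_ids) | set(b.sample_ids) == set(node.sample_ids)
                assert not set(a.sample_ids) & set(b.sample_ids)
                assert a.n_samples >= b.n_samples  # larger child first


class TestPairwiseGrid:
    def test_eight_classes_enumerate_28_pairs(self, rng):
        n_cls, per = 8, 4
        Z = rng.normal(5, 1, size=(n_cls * per, 10))
        labels = np.repeat([f"c{i}" for i in range(n_cls)], per)
        table = FeatureTable([f"s{i}" for i in range(n_cls * per)],
                             [f"f{j}" for j in range(10)], np.exp(Z), "raw")
        cfg = SplitConfig(n_perm=19, seed=0)
        grid = pairwise_grid(table, labels, cfg)
        assert len(grid) == 28
        assert all(a < b for a, b in grid)  # each unordered pair once

    def test_small_class_pair_skipped(self, rng):
        Z = rng.normal(5, 1, size=(10, 5))
        labels = ["a"] * 6 + ["b"] * 2 + ["c"] * 2
        table = FeatureTable([f"s{i}" for i in range(10)],
                             [f"f{j}" for j in range(5)], np.exp(Z), "raw")
        grid = pairwise_grid(table, labels, SplitConfig(n_perm=19, seed=0))
        assert grid[("a", "b")] is None and grid[("b", "c")] is None
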