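"""Screening, Z-scoring, bootstrap clustering and driver-metric ranking."""

import numpy as np
import pandas as pd
import pytest

from phenoflux.clustering import (
    PhenotypeAssignment,
    bootstrap_cluster,
    cut_phenotypes,
    kept_metrics,
    rank_driver_metrics,
    screen_metrics,
    to_newick,
    zscore_matrix,
)


def two_group_matrix(rng, n_per=10, n_metrics=30, shift=0.0):
    X = rng.standard_normal((2 * n_per, n_metrics))
    X[n_per:, :] += shift
    idx = [f"s{i:02d}" for i in range(2 * n_per)]
    groups = pd.Series(["a"] * n_per + ["b"] * n_per, index=idx)
    return pd.DataFrame(X, index=idx), groups


class TestScreen:
    def test_planted_shift_always_kept(self):
        kept = 0
        for seed in range(50):
            wide, groups = two_group_matrix(np.random.default_rng(seed),
                                            n_metrics=1, shift=5.0)
            res = screen_metrics(wide, groups)
            kept += res[0].kept
        assert kept == 50  # 5 pooled SDs at n=10/group: power ~ 1

    def test_null_keep_rate_near_alpha(self):
        wide, groups = two_group_matrix(np.random.default_rng(0), n_metrics=300)
        res = screen_metrics(wide, groups)
        rate = np.mean([r.kept for r in res])
        assert 0.01 <= rate <= 0.10

    def test_constant_metric_dropped(self):
        wide, groups = two_group_matrix(np.random.default_rng(1), n_metrics=3)
        wide["const"] = 1.0
        res = {r.metric: r for r in screen_metrics(wide, groups)}
        assert not res["const"].kept
        assert res["const"].reason == "constant"

    def test_requires_two_groups(self):
        wide, groups = two_group_matrix(np.random.default_rng(2))
        with pytest.raises(ValueError):
            screen_metrics(wide, pd.Series("a", index=wide.index))

    def test_test_selection_by_normality(self):
        rng = np.random.default_rng(3)
        wide, groups = two_group_matrix(rng, n_per=25, n_metrics=1)
        wide["skewed"] = np.exp(3 * rng.standard_normal(50))
        res = {r.metric: r for r in screen_metrics(wide, groups)}
        assert res[0].test == "anova"
        assert res["skewed"].test == "kruskal"


class TestZScore:
    def test_moments(self, rng):
        wide = pd.DataFrame(rng.normal(5, 3, size=(20, 4)))
        z = zscore_matrix(wide)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=0), 1, rtol=1e-12)

    def test_affine_invariance(self, rng):
        wide = pd.DataFrame(rng.standard_normal((20, 4)))
        z1 = zscore_matrix(wide)
        z2 = zscore_matrix(wide * 3.7 - 12.0)
        pd.testing.assert_frame_equal(z1, z2)

    def test_missing_values_retained(self, rng):
        wide = pd.DataFrame(rng.standard_normal((10, 2)))
        wide.iloc[0, 0] = np.nan
        z = zscore_matrix(wide)
        assert np.isnan(z.iloc[0, 0])
        assert z[0].std(ddof=0) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        wide = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1, 2, 3.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_matrix(wide)


def separated_z(rng, n_per=10, n_metrics=40, shift=6.0):
    """Two groups with anti-correlated metric patterns (clear in 1-Pearson)."""
    wide, _ = two_group_matrix(rng, n_per=n_per, n_metrics=n_metrics, shift=0.0)
    wide.iloc[n_per:, : n_metrics // 2] += shift
    wide.iloc[n_per:, n_metrics // 2:] -= shift
    return zscore_matrix(wide)


class TestBootstrapCluster:
    def test_separated_groups_get_high_support(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            z = separated_z(np.random.default_rng(seed))
            res = bootstrap_cluster(z, n_boot=200, seed=seed)
            # the two children of the root are the planted groups
            top = res.support.sort_values("n_leaves").iloc[-3:-1]
            if (top["au"] >= 0.95).all():
                hits += 1
        assert hits == n_seeds

    def test_null_support_stays_low(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            z = zscore_matrix(pd.DataFrame(
                rng.standard_normal((12, 60)),
                index=[f"s{i}" for i in range(12)],
            ))
            res = bootstrap_cluster(z, n_boot=1000, seed=seed)
            interior = res.support[res.support["n_leaves"] < 12]
            if interior["au"].max() < 0.95:
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_duplicated_sample_merges_at_height_zero(self, rng):
        z = zscore_matrix(pd.DataFrame(rng.standard_normal((6, 20)),
                                       index=list("abcdef")))
        z.loc["f"] = z.loc["a"]
        res = bootstrap_cluster(z, n_boot=100, seed=0)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        z = separated_z(rng)
        a = bootstrap_cluster(z, n_boot=120, seed=5)
        b = bootstrap_cluster(z, n_boot=120, seed=5)
        pd.testing.assert_frame_equal(a.support, b.support)

    def test_sample_order_invariance(self, rng):
        z = separated_z(rng)
        shuffled = z.sample(frac=1.0, random_state=1)
        a = cut_phenotypes(bootstrap_cluster(z, n_boot=100, seed=0), k=2)
        b = cut_phenotypes(bootstrap_cluster(shuffled, n_boot=100, seed=0), k=2)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_missing_dominated_sample_excluded(self, rng):
        z = pd.DataFrame(rng.standard_normal((8, 20)),
                         index=[f"s{i}" for i in range(8)])
        z.iloc[0, :10] = np.nan
        with pytest.warns(UserWarning, match="missing-dominated"):
            res = bootstrap_cluster(zscore_matrix(z), n_boot=100, seed=0)
        assert res.excluded == ["s0"]
        assert len(res.sample_ids) == 7

    def test_too_few_bootstraps_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_cluster(separated_z(rng), n_boot=50)


class TestCutPhenotypes:
    def test_k_equals_n_gives_singletons(self, rng):
        z = separated_z(rng)
        res = bootstrap_cluster(z, n_boot=100, seed=0)
        assign = cut_phenotypes(res, k=len(z))
        assert assign.labels.nunique() == len(z)

    def test_k_one_single_phenotype(self, rng):
        res = bootstrap_cluster(separated_z(rng), n_boot=100, seed=0)
        assert cut_phenotypes(res, k=1).labels.nunique() == 1

    def test_k_above_leaves_rejected(self, rng):
        res = bootstrap_cluster(separated_z(rng), n_boot=100, seed=0)
        with pytest.raises(ValueError):
            cut_phenotypes(res, k=21)

    def test_labels_ordered_by_size(self, rng):
        wide, _ = two_group_matrix(rng, n_per=6, n_metrics=30)
        wide.iloc[:8, :15] += 8.0  # group of 8 vs group of 4
        res = bootstrap_cluster(zscore_matrix(wide), n_boot=100, seed=0)
        labels = cut_phenotypes(res, k=2).labels
        sizes = labels.value_counts()
        assert sizes.loc[1] == 8 and sizes.loc[2] == 4

    def test_contiguous_label_invariant(self, rng):
        with pytest.raises(ValueError):
            PhenotypeAssignment(
                labels=pd.Series([1, 3], index=["a", "b"]), k=2
            )


class TestDriverMetrics:
    def _assignment(self, index, labels):
        return PhenotypeAssignment(labels=pd.Series(labels, index=index), k=len(set(labels)))

    def test_planted_family_ranks_first(self, rng):
        n = 20
        idx = [f"s{i}" for i in range(n)]
        cols = [f"NPQ_{w}_1" for w in (420, 442)] + [f"qP_{w}_1" for w in (420, 442)]
        X = pd.DataFrame(rng.standard_normal((n, 4)), index=idx, columns=cols)
        X.iloc[10:, :2] += 6.0  # only the NPQ family separates the groups
        assign = self._assignment(idx, [1] * 10 + [2] * 10)
        _, fam = rank_driver_metrics(zscore_matrix(X), assign)
        assert fam.iloc[0]["family"] == "NPQ"
        assert fam.iloc[0]["informative"]

    def test_single_phenotype_rejected(self, rng):
        idx = ["a", "b", "c"]
        X = pd.DataFrame(rng.standard_normal((3, 2)), index=idx)
        with pytest.raises(ValueError):
            rank_driver_metrics(X, self._assignment(idx, [1, 1, 1]))

    def test_identical_phenotypes_flagged_uninformative(self, rng):
        idx = [f"s{i}" for i in range(40)]
        X = pd.DataFrame(rng.standard_normal((40, 3)),
                         index=idx, columns=["A_1_1", "A_1_2", "A_1_3"])
        assign = self._assignment(idx, [1, 2] * 20)
        per, fam = rank_driver_metrics(zscore_matrix(X), assign)
        # exchangeable data: occasionally one metric dips under alpha, but
        # the family should not be systematically informative
        assert fam["n_significant"].sum() <= 1

    def test_no_position_bias_under_exchangeability(self):
        """With exchangeable metrics, average rank is uniform over columns."""
        n_shuffles = 100
        ranks = np.zeros(6)
        idx = [f"s{i}" for i in range(24)]
        for seed in range(n_shuffles):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((24, 6)), index=idx,
                             columns=[f"M{j}_1_1" for j in range(6)])
            assign = self._assignment(idx, [1] * 12 + [2] * 12)
            per, _ = rank_driver_metrics(zscore_matrix(X), assign)
            for rank, m in enumerate(per["metric"]):
                ranks[int(m[1])] += rank
        mean_rank = ranks / n_shuffles
        assert np.ptp(mean_rank) < 1.0  # no column systematically first


class TestNewick:
    def test_round_trip_leaf_names(self, rng):
        import dendropy

        z = separated_z(rng)
        res = bootstrap_cluster(z, n_boot=100, seed=0)
        nwk = to_newick(res)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        assert leaves == set(res.sample_ids)
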