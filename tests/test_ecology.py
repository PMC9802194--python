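"""Community-statistics tests with independent oracles (scikit-bio, closed forms)."""

import io

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb
from skbio import TreeNode

from bioturb import (
    DistanceMatrix,
    cap,
    pcoa,
    permanova,
    rarefy,
    richness,
    unifrac,
)
from conftest import make_table


def euclidean_dm(points, ids=None):
    d = squareform(pdist(np.asarray(points, float)))
    return DistanceMatrix(d, ids or [f"s{i}" for i in range(len(points))])


class TestRarefy:
    def test_exhaustive_draw_unchanged(self, small_table):
        total = int(small_table.counts.sum(axis=1).min())
        r = rarefy(small_table, total, seed=0)
        sid = small_table.counts.sum(axis=1).idxmin()
        assert (r.counts.loc[sid] == small_table.counts.loc[sid]).all()

    def test_richness_never_increases(self, small_table):
        r = rarefy(small_table, 50, seed=1)
        pre = richness(small_table)
        post = richness(r)
        assert (post <= pre[post.index]).all()

    def test_depth_and_determinism(self, small_table):
        r1 = rarefy(small_table, 100, seed=7)
        r2 = rarefy(small_table, 100, seed=7)
        assert (r1.counts.sum(axis=1) == 100).all()
        assert r1.counts.equals(r2.counts)

    def test_shallow_samples_dropped(self, small_table):
        totals = small_table.counts.sum(axis=1)
        depth = int(totals.median())
        r = rarefy(small_table, depth, seed=0)
        assert set(r.counts.index) == set(totals[totals >= depth].index)

    def test_invalid_depth(self, small_table):
        with pytest.raises(ValueError):
            rarefy(small_table, 0)

    def test_hypergeometric_expectation(self):
        """Mean rarefied richness matches the closed-form expectation.

        For a sample with counts n_i summing to N rarefied to d, expected
        richness is sum_i [1 - C(N - n_i, d) / C(N, d)].
        """
        counts = np.array([[100, 100]])
        table = make_table(counts)
        d, n_draws = 50, 4000
        vals = [richness(rarefy(table, d, seed=s)).iloc[0] for s in range(n_draws)]
        n_tot = counts.sum()
        expected = sum(
            1 - comb(n_tot - ni, d, exact=True) / comb(n_tot, d, exact=True)
            for ni in counts[0]
        )
        se = np.std(vals, ddof=1) / np.sqrt(n_draws)
        assert abs(np.mean(vals) - expected) < 3 * max(se, 1e-12)


class TestUnifrac:
    def test_identical_samples_zero(self, two_tip_star_tree):
        t = make_table(np.array([[5, 5], [10, 10]]))
        for weighted in (True, False):
            d = unifrac(t, two_tip_star_tree, weighted=weighted)
            assert d.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_samples_complete_turnover(self, two_tip_star_tree):
        """Samples on different tips of a star tree are at distance 1."""
        t = make_table(np.array([[7, 0], [0, 3]]))
        for weighted in (True, False):
            d = unifrac(t, two_tip_star_tree, weighted=weighted)
            assert d.data[0, 1] == pytest.approx(1.0)

    def test_matches_skbio_oracle(self):
        rng = np.random.default_rng(8)
        t = make_table(rng.integers(0, 50, (6, 10)) + 1)
        tree = skbio.TreeNode.read(
            io.StringIO(
                "(((t0:0.3,(t1:0.2,t2:0.1):0.4):0.2,((t3:0.5,t4:0.1):0.1,"
                "(t5:0.2,(t6:0.3,t7:0.1):0.2):0.3):0.1):0.05,(t8:0.4,t9:0.6):0.2);"
            )
        )
        ours_w = unifrac(t, tree, weighted=True)
        ours_u = unifrac(t, tree, weighted=False)
        ref_w = skbio.diversity.beta_diversity(
            "weighted_unifrac", t.counts.to_numpy(), ids=t.sample_ids,
            tree=tree, taxa=t.taxon_ids, normalized=True,
        )
        ref_u = skbio.diversity.beta_diversity(
            "unweighted_unifrac", t.counts.to_numpy(), ids=t.sample_ids,
            tree=tree, taxa=t.taxon_ids,
        )
        assert np.allclose(ours_w.data, ref_w.data, atol=1e-10)
        assert np.allclose(ours_u.data, ref_u.data, atol=1e-10)

    def test_absent_taxon_invariance(self, small_table):
        """Adding a taxon absent from every sample leaves distances unchanged."""
        rng = np.random.default_rng(9)
        t = make_table(rng.integers(0, 30, (5, 4)) + 1)
        tree = TreeNode.read(io.StringIO("((t0:0.1,t1:0.2):0.3,(t2:0.2,t3:0.1):0.2);"))
        d1 = unifrac(t, tree, weighted=True)
        counts2 = t.counts.copy()
        counts2["t4"] = 0
        t2 = make_table(counts2.to_numpy())
        tree2 = TreeNode.read(
            io.StringIO("((t0:0.1,t1:0.2):0.3,((t2:0.2,t3:0.1):0.2,t4:0.9):0.0);")
        )
        d2 = unifrac(t2, tree2, weighted=True)
        assert np.allclose(d1.data, d2.data, atol=1e-12)

    def test_missing_taxon_raises(self, small_table, two_tip_star_tree):
        with pytest.raises(ValueError, match="t2"):
            unifrac(make_table(np.ones((3, 3), int)), two_tip_star_tree)

    def test_weighted_bounded(self):
        rng = np.random.default_rng(10)
        t = make_table(rng.integers(0, 40, (6, 4)) + 1)
        tree = TreeNode.read(io.StringIO("((t0:0.1,t1:0.2):0.3,(t2:0.2,t3:0.1):0.2);"))
        d = unifrac(t, tree, weighted=True)
        assert np.all((d.data >= 0) & (d.data <= 1))


class TestPcoa:
    def test_euclidean_self_consistency(self):
        """Embedding of distances from planar points reproduces the distances."""
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(12, 2))
        res = pcoa(euclidean_dm(pts))
        emb = res.coordinates.to_numpy()
        d_emb = squareform(pdist(emb))
        assert np.allclose(d_emb, squareform(pdist(pts)), atol=1e-8)

    def test_all_zero_distances(self):
        d = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        res = pcoa(d)
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0.0)

    def test_proportions_sum_leq_one(self, small_table):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(9, 5))
        res = pcoa(euclidean_dm(pts))
        assert res.proportions.sum() <= 1 + 1e-9
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)

    def test_matches_skbio_oracle(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(10, 4))
        dm = euclidean_dm(pts)
        ours = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dm.data, dm.ids))
        k = ours.coordinates.shape[1]
        for j in range(min(4, k)):
            ours_ax = ours.coordinates.iloc[:, j].to_numpy()
            ref_ax = ref.samples.iloc[:, j].to_numpy()
            assert np.allclose(np.abs(ours_ax), np.abs(ref_ax), atol=1e-8)
        assert np.allclose(
            ours.proportions[:4], ref.proportion_explained[:4], atol=1e-10
        )

    def test_asymmetric_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(m, ["a", "b"])


class TestPermanova:
    def test_separated_clouds_saturate(self):
        """Two well-separated clouds give the minimum p at 999 permutations."""
        rng = np.random.default_rng(14)
        pts = np.vstack([rng.normal(0, 0.1, (8, 2)), rng.normal(5, 0.1, (8, 2))])
        groups = ["a"] * 8 + ["b"] * 8
        res = permanova(euclidean_dm(pts), groups, n_permutations=999, seed=0)
        assert res.p_value == pytest.approx(0.001)
        assert res.r_squared > 0.9

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(size=(10, 3))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        dm = euclidean_dm(pts)
        f1 = permanova(dm, groups, n_permutations=9, seed=0).pseudo_f
        perm = rng.permutation(10)
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)], [dm.ids[i] for i in perm])
        f2 = permanova(dm2, groups[perm], n_permutations=9, seed=0).pseudo_f
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_matches_skbio_pseudo_f(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(size=(12, 3))
        groups = ["a"] * 6 + ["b"] * 6
        dm = euclidean_dm(pts)
        ours = permanova(dm, groups, n_permutations=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, dm.ids), grouping=groups, permutations=99
        )
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_singleton_group_rejected(self):
        pts = np.eye(4)
        with pytest.raises(ValueError):
            permanova(euclidean_dm(pts), ["a", "a", "a", "b"])


class TestCap:
    def test_constraining_on_pco1_is_exact(self):
        """Environment = PCo1 itself: CAP1 reproduces PCo1 and its share."""
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(20, 4)) * np.array([3.0, 1.5, 0.8, 0.3])
        dm = euclidean_dm(pts)
        ord_res = pcoa(dm)
        env = pd.DataFrame({"v": ord_res.coordinates["PCo1"]}, index=dm.ids)
        res = cap(dm, env, seed=0)
        r = np.corrcoef(
            res.coordinates["CAP1"], ord_res.coordinates["PCo1"]
        )[0, 1]
        assert abs(r) > 0.999
        assert res.explained_total == pytest.approx(ord_res.proportions[0], abs=1e-6)

    def test_duplicated_variable_span_invariance(self):
        rng = np.random.default_rng(18)
        pts = rng.normal(size=(15, 3))
        dm = euclidean_dm(pts)
        driver = pts[:, 0] + 0.1 * rng.normal(size=15)
        env1 = pd.DataFrame({"v": driver}, index=dm.ids)
        env2 = pd.DataFrame({"v": driver, "v2": driver * 2.0 + 1.0}, index=dm.ids)
        r1 = cap(dm, env1, seed=0, prefilter=False)
        r2 = cap(dm, env2, seed=0, prefilter=False)
        assert r1.explained_total == pytest.approx(r2.explained_total, abs=1e-9)

    def test_null_variable_retention_rate(self):
        """A pure-noise variable passes the marginal test ~5% of the time."""
        rng = np.random.default_rng(19)
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            pts = rng.normal(size=(14, 3))
            dm = euclidean_dm(pts)
            env = pd.DataFrame({"noise": rng.normal(size=14)}, index=dm.ids)
            try:
                res = cap(dm, env, seed=rep, n_permutations=199)
                hits += 1
            except ValueError:
                pass
        # binomial(60, 0.05): central band
        assert hits <= 9

    def test_too_many_variables_rejected(self):
        rng = np.random.default_rng(20)
        pts = rng.normal(size=(5, 2))
        dm = euclidean_dm(pts)
        env = pd.DataFrame(rng.normal(size=(5, 6)), index=dm.ids)
        with pytest.raises(ValueError):
            cap(dm, env)

    def test_explained_does_not_increase_when_variable_dropped(self):
        rng = np.random.default_rng(21)
        pts = rng.normal(size=(16, 3))
        dm = euclidean_dm(pts)
        env = pd.DataFrame(
            {"a": pts[:, 0], "b": pts[:, 1] + rng.normal(size=16)}, index=dm.ids
        )
        full = cap(dm, env, seed=0, prefilter=False)
        reduced = cap(dm, env[["a"]], seed=0, prefilter=False)
        assert reduced.explained_total <= full.explained_total + 1e-9
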