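"""Network tests: Spearman oracle equivalence, clustering, distance correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from bioturb import (
    TaxonMatrix,
    aggregate_to_class,
    distance_correlation,
    extract_clusters,
    interdomain_dcor,
    spearman_network,
)
from conftest import make_table


def brute_force_spearman(a, b):
    """Independent oracle: Pearson formula applied to mid-ranks by hand."""
    def midranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    ra, rb = midranks(np.asarray(a, float)), midranks(np.asarray(b, float))
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def brute_force_dcor(x, y):
    """Independent oracle: explicit double-centering double sums."""
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    n = x.shape[0]
    a = np.zeros((n, n))
    b = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a[i, j] = np.sqrt(((x[i] - x[j]) ** 2).sum())
            b[i, j] = np.sqrt(((y[i] - y[j]) ** 2).sum())
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = a[i, j] - a[i].mean() - a[:, j].mean() + a.mean()
            B[i, j] = b[i, j] - b[i].mean() - b[:, j].mean() + b.mean()
    dcov2 = (A * B).mean()
    return np.sqrt(max(dcov2, 0.0) / np.sqrt((A * A).mean() * (B * B).mean()))


def random_matrix(rng, n=20, k=6):
    x = rng.dirichlet(np.ones(k) * 2, size=n)
    return TaxonMatrix(abundances=pd.DataFrame(x, columns=[f"c{i}" for i in range(k)]))


class TestAggregateToClass:
    def test_class_sums(self):
        counts = np.array([[30, 70, 100], [10, 10, 180]])
        t = make_table(counts, classes=["A", "A", "B"])
        m = aggregate_to_class(t)
        assert m.abundances.loc["s0", "A"] == pytest.approx(0.5)
        assert m.abundances.loc["s0", "B"] == pytest.approx(0.5)

    def test_single_class_column_of_ones(self):
        t = make_table(np.array([[5, 5], [1, 9]]), classes=["A", "A"])
        m = aggregate_to_class(t)
        assert np.allclose(m.abundances.to_numpy(), 1.0)

    def test_row_sum_conservation(self, small_table):
        m = aggregate_to_class(small_table)
        assert np.allclose(m.abundances.sum(axis=1), 1.0)

    def test_unclassified_uses_phylum(self):
        t = make_table(np.array([[5, 5], [2, 8]]), classes=["unclassified", "A"])
        m = aggregate_to_class(t)
        assert any(c.startswith("phylum_") for c in m.abundances.columns)


class TestSpearmanNetwork:
    def test_monotone_pairs(self):
        n = 12
        base = np.linspace(0.01, 0.1, n)
        x = np.column_stack([base, base**2, 0.11 - base])
        x = x / x.sum(axis=1, keepdims=True) * 0.9
        m = TaxonMatrix(abundances=pd.DataFrame(x, columns=["a", "b", "c"]))
        net = spearman_network(m)
        assert net.rho.loc["a", "b"] == 1.0
        assert net.rho.loc["a", "c"] == -1.0

    def test_oracle_equivalence_with_ties(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            a = rng.integers(0, 5, 15).astype(float)
            b = rng.integers(0, 5, 15).astype(float)
            if np.var(a) == 0 or np.var(b) == 0:
                continue
            x = np.column_stack([a, b]) / 100.0
            m = TaxonMatrix(abundances=pd.DataFrame(x, columns=["a", "b"]))
            net = spearman_network(m)
            assert net.rho.loc["a", "b"] == pytest.approx(
                brute_force_spearman(a, b), abs=1e-12
            )

    def test_zero_variance_classes_excluded(self):
        rng = np.random.default_rng(24)
        x = rng.dirichlet([1, 1, 1], size=10) * 0.5
        x = np.column_stack([x, np.full(10, 0.1)])
        m = TaxonMatrix(abundances=pd.DataFrame(x, columns=["a", "b", "c", "flat"]))
        net = spearman_network(m)
        assert "flat" in net.excluded_classes
        assert "flat" not in net.rho.columns

    def test_alpha_nesting(self):
        rng = np.random.default_rng(25)
        m = random_matrix(rng, n=25, k=8)
        strict = spearman_network(m, alpha=0.01)
        loose = spearman_network(m, alpha=0.05)
        assert (strict.significant.to_numpy() <= loose.significant.to_numpy()).all()

    def test_too_few_samples(self):
        rng = np.random.default_rng(26)
        with pytest.raises(ValueError):
            spearman_network(random_matrix(rng, n=4))


class TestExtractClusters:
    def planted_matrix(self, rng, n=40, per_block=4, noise=0.05):
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        cols = {}
        for i in range(per_block):
            cols[f"s{i}"] = f1 + noise * rng.normal(size=n)
        for i in range(per_block):
            cols[f"d{i}"] = f2 + noise * rng.normal(size=n)
        x = np.exp(pd.DataFrame(cols).to_numpy())
        x = x / x.sum(axis=1, keepdims=True)
        return TaxonMatrix(abundances=pd.DataFrame(x, columns=list(cols)))

    def test_planted_partition_recovery(self):
        rng = np.random.default_rng(27)
        m = self.planted_matrix(rng)
        net = spearman_network(m)
        labels = net.clusters
        s_labels = {labels[f"s{i}"] for i in range(4)}
        d_labels = {labels[f"d{i}"] for i in range(4)}
        assert len(s_labels) == 1 and len(d_labels) == 1
        assert s_labels != d_labels

    def test_singletons_at_k_equals_classes(self):
        rng = np.random.default_rng(28)
        m = random_matrix(rng, n=20, k=5)
        net = spearman_network(m)
        labels = extract_clusters(net, k=len(net.rho))
        assert labels.nunique() == len(net.rho)

    def test_order_invariance(self):
        rng = np.random.default_rng(29)
        m = self.planted_matrix(rng)
        net1 = spearman_network(m)
        perm_cols = list(m.abundances.columns)[::-1]
        m2 = TaxonMatrix(abundances=m.abundances[perm_cols])
        net2 = spearman_network(m2)
        co1 = {
            (a, b): net1.clusters[a] == net1.clusters[b]
            for a in perm_cols for b in perm_cols
        }
        co2 = {
            (a, b): net2.clusters[a] == net2.clusters[b]
            for a in perm_cols for b in perm_cols
        }
        assert co1 == co2

    def test_k_too_large(self):
        rng = np.random.default_rng(30)
        net = spearman_network(random_matrix(rng, n=15, k=4))
        with pytest.raises(ValueError):
            extract_clusters(net, k=10)


class TestDistanceCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=(20, 3))
        df = pd.DataFrame(x, index=[f"s{i}" for i in range(20)])
        res = interdomain_dcor(df, df, n_resamples=99, seed=0)
        assert res.dcor_r == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1 / 100)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=(30, 4))
        y = x[:, :2] + 0.5 * rng.normal(size=(30, 2))
        assert distance_correlation(x, y) == pytest.approx(
            brute_force_dcor(x, y), abs=1e-10
        )

    def test_orthogonal_invariance(self):
        """dcor is invariant to rotation plus scaling of a block."""
        rng = np.random.default_rng(33)
        x = rng.normal(size=(25, 3))
        y = rng.normal(size=(25, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert distance_correlation(x, y) == pytest.approx(
            distance_correlation(x, 2.5 * y @ q), abs=1e-12
        )

    def test_sample_mismatch_rejected(self):
        a = pd.DataFrame(np.eye(10), index=[f"s{i}" for i in range(10)])
        b = pd.DataFrame(np.eye(10), index=[f"x{i}" for i in range(10)])
        with pytest.raises(ValueError):
            interdomain_dcor(a, b)

    def test_sign_hint(self):
        rng = np.random.default_rng(34)
        base = rng.uniform(0.1, 1.0, 20)
        a = pd.DataFrame({"x": base}, index=[f"s{i}" for i in range(20)])
        b = pd.DataFrame({"y": 1.0 - base * 0.5}, index=[f"s{i}" for i in range(20)])
        res = interdomain_dcor(a, b, n_resamples=49, seed=0)
        assert res.sign_hint == -1
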