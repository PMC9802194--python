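"""Class-level co-occurrence networks and interdomain distance correlation.

Within each domain, pairwise Spearman correlations between taxonomic
classes (over all samples and time points) define a network whose
modules are extracted by average-linkage hierarchical clustering on
1 - rho.  Between domains, the dependence of one cluster's multivariate
abundance block on another's is quantified by the distance correlation
(dcor R, in [0, 1]) with a permutation null for significance.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .ecology import ZOTUTable

__all__ = [
    "TaxonMatrix",
    "CorrelationNetwork",
    "ClusterCorrelation",
    "aggregate_to_class",
    "spearman_network",
    "extract_clusters",
    "interdomain_dcor",
    "distance_correlation",
]


@dataclass
class TaxonMatrix:
    """Samples x taxon-class relative abundances for one domain."""

    abundances: pd.DataFrame  # samples x classes
    domain: str = ""
    sample_metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.abundances.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError("abundances must be >= 0")
        if np.any(vals.sum(axis=1) > 1 + 1e-9):
            raise ValueError("rows must sum to <= 1 (relative abundances)")


@dataclass
class CorrelationNetwork:
    """Spearman network over classes with significance and clusters."""

    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean mask at the declared alpha
    clusters: pd.Series  # class -> cluster label
    linkage_record: np.ndarray  # scipy linkage matrix
    alpha: float
    n_tests: int
    excluded_classes: list[str]


@dataclass
class ClusterCorrelation:
    """Interdomain cluster-cluster distance correlation."""

    cluster_a: str
    cluster_b: str
    dcor_r: float
    p_value: float
    n_resamples: int
    seed: int
    sign_hint: int  # sign of Pearson corr of aggregate cluster abundances
    significant: bool
    bootstrap_ci: tuple[float, float] | None = None


def aggregate_to_class(table: ZOTUTable) -> TaxonMatrix:
    """Sum ZOTU counts within each taxonomic class, as relative abundances.

    Where the class rank is "unclassified" the phylum is used instead
    (recorded in the column name as ``phylum_<name>``).
    """
    if table.taxonomy.empty or "class" not in table.taxonomy.columns:
        raise ValueError("taxonomy with a class rank is required")
    cls = table.taxonomy.loc[table.taxon_ids, "class"].astype(str).copy()
    unclassified = cls.str.lower().isin(["unclassified", "nan", ""])
    if unclassified.any() and "phylum" in table.taxonomy.columns:
        cls[unclassified] = "phylum_" + table.taxonomy.loc[
            table.taxon_ids, "phylum"
        ].astype(str)[unclassified]
    rel = table.relative_abundance()
    agg = rel.T.groupby(cls.values).sum().T
    return TaxonMatrix(
        abundances=agg, domain=table.domain, sample_metadata=table.sample_metadata
    )


# ---------------------------------------------------------------------------
# Spearman network


def _spearman_matrix(x: np.ndarray) -> np.ndarray:
    """Spearman rho as Pearson correlation of mid-ranks (average ties)."""
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    return np.corrcoef(ranks, rowvar=False)


def _spearman_p(rho: np.ndarray, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Two-sided p-values via the t-approximation (n >= 10)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1 - rho * rho, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.minimum(p, 1.0)


def _spearman_p_exact(x: np.ndarray, rho_obs: np.ndarray, seed: int, n_perm: int = 2000):
    """Permutation p-values for small n (< 10), column pair by pair."""
    rng = np.random.default_rng(seed)
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            obs = abs(rho_obs[i, j])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                r = np.corrcoef(ranks[:, i], ranks[perm, j])[0, 1]
                if abs(r) >= obs - 1e-12:
                    count += 1
            p[i, j] = p[j, i] = (1 + count) / (1 + n_perm)
    return p


def spearman_network(
    matrix: TaxonMatrix, alpha: float = 0.05, seed: int = 0, k: int | None = None
) -> CorrelationNetwork:
    """Build the within-domain class co-occurrence network.

    Spearman rho (mid-rank Pearson) over all samples; two-sided p by the
    t-approximation (exact permutation when n < 10); significance mask at
    ``p < alpha`` with no multiple-testing correction (the number of
    tests is recorded).  Clusters come from an average-linkage cut of the
    1 - rho dendrogram (see :func:`extract_clusters`).
    """
    x = matrix.abundances.to_numpy(dtype=float)
    n, _ = x.shape
    if n < 5:
        raise ValueError("need >= 5 samples")
    keep = x.max(axis=0) > x.min(axis=0)  # exact: constant columns excluded
    excluded = [c for c, k_ in zip(matrix.abundances.columns, keep) if not k_]
    cols = [c for c, k_ in zip(matrix.abundances.columns, keep) if k_]
    x = x[:, keep]
    rho = _spearman_matrix(x)
    np.fill_diagonal(rho, 1.0)
    if n >= 10:
        p = _spearman_p(rho, n)
    else:
        p = _spearman_p_exact(x, rho, seed)
    np.fill_diagonal(p, 0.0)
    sig = p < alpha
    m = len(cols)
    n_tests = m * (m - 1) // 2
    # average-linkage clustering on 1 - rho
    diss = squareform(np.clip(1.0 - rho, 0.0, 2.0), checks=False)
    linkage = hierarchy.linkage(diss, method="average")
    net = CorrelationNetwork(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        significant=pd.DataFrame(sig, index=cols, columns=cols),
        clusters=pd.Series(index=cols, dtype=object),
        linkage_record=linkage,
        alpha=alpha,
        n_tests=n_tests,
        excluded_classes=excluded,
    )
    net.clusters = extract_clusters(net, k=k)
    return net


def extract_clusters(network: CorrelationNetwork, k: int | None = None) -> pd.Series:
    """Cut the average-linkage dendrogram into k clusters.

    Automatic k maximizes (mean within-cluster rho) - (mean
    between-cluster rho) over k in [2, 8].
    """
    if network.linkage_record is None:
        raise ValueError("network has no linkage record")
    classes = list(network.rho.index)
    m = len(classes)
    if k is not None:
        if k > m:
            raise ValueError("k cannot exceed the number of classes")
        labels = hierarchy.fcluster(network.linkage_record, t=k, criterion="maxclust")
        return pd.Series(labels, index=classes)
    rho = network.rho.to_numpy()
    iu = np.triu_indices(m, 1)
    best_k, best_score = 2, -np.inf
    for kk in range(2, min(8, m) + 1):
        labels = hierarchy.fcluster(network.linkage_record, t=kk, criterion="maxclust")
        same = labels[iu[0]] == labels[iu[1]]
        if same.all() or not same.any():
            continue
        score = rho[iu][same].mean() - rho[iu][~same].mean()
        if score > best_score:
            best_k, best_score = kk, score
    labels = hierarchy.fcluster(network.linkage_record, t=best_k, criterion="maxclust")
    return pd.Series(labels, index=classes)


# ---------------------------------------------------------------------------
# distance correlation


def _double_center(d: np.ndarray) -> np.ndarray:
    return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation (Szekely's dcor R) of two blocks.

    Doubly-centred Euclidean distance matrices; dCov^2 = mean(A * B);
    R = dCov / sqrt(dVar_x dVar_y), in [0, 1], zero at independence
    (population level).
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    if x.shape[0] == 1:
        x = x.T
    if y.shape[0] == 1:
        y = y.T
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks must have the same number of samples")
    a = _double_center(squareform(pdist(x)))
    b = _double_center(squareform(pdist(y)))
    dcov2 = (a * b).mean()
    dvar_x = (a * a).mean()
    dvar_y = (b * b).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def interdomain_dcor(
    cluster_a: pd.DataFrame,
    cluster_b: pd.DataFrame,
    n_resamples: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    name_a: str = "A",
    name_b: str = "B",
    bootstrap_ci: bool = False,
) -> ClusterCorrelation:
    """Distance correlation between two cluster abundance blocks.

    Significance by permuting the sample rows of block b:
    p = (1 + #{dcor_perm >= dcor_obs}) / (1 + n_resamples).  The sign
    hint is the sign of the Pearson correlation of the clusters'
    aggregate (row-sum) abundances, for "positively/negatively
    correlated" reporting.  ``bootstrap_ci`` adds a percentile 95% CI
    from resampling samples with replacement.
    """
    if not cluster_a.index.equals(cluster_b.index):
        raise ValueError("blocks must share the same samples in the same order")
    xa = cluster_a.to_numpy(dtype=float)
    xb = cluster_b.to_numpy(dtype=float)
    n = xa.shape[0]
    if n < 8:
        raise ValueError("need >= 8 samples")
    a = _double_center(squareform(pdist(xa)))
    b = _double_center(squareform(pdist(xb)))
    dvar_a = (a * a).mean()
    dvar_b = (b * b).mean()
    denom = np.sqrt(dvar_a * dvar_b)
    obs = float(np.sqrt(max((a * b).mean(), 0.0) / denom)) if denom > 0 else 0.0
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        r = np.sqrt(max((a * bp).mean(), 0.0) / denom) if denom > 0 else 0.0
        if r >= obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_resamples)
    agg_a = xa.sum(axis=1)
    agg_b = xb.sum(axis=1)
    if agg_a.std() > 0 and agg_b.std() > 0:
        sign = int(np.sign(np.corrcoef(agg_a, agg_b)[0, 1]))
    else:
        sign = 0
    ci = None
    if bootstrap_ci:
        boots = []
        for _ in range(n_resamples):
            idx = rng.integers(0, n, n)
            boots.append(distance_correlation(xa[idx], xb[idx]))
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return ClusterCorrelation(
        cluster_a=name_a, cluster_b=name_b, dcor_r=obs, p_value=float(p),
        n_resamples=n_resamples, seed=seed, sign_hint=sign,
        significant=p < alpha, bootstrap_ci=ci,
    )
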