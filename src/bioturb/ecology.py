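"""Community-structure statistics, implemented from first principles.

Rarefaction and observed richness, weighted/unweighted UniFrac over a
phylogenetic tree, classical PCoA, PERMANOVA with label permutations, and
CAP (canonical analysis of principal coordinates) against environmental
drivers.  scikit-bio supplies only the tree container and distance-matrix
plumbing; every statistic here is computed by this module (the
scikit-bio equivalents serve as independent cross-checks in the test
suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from skbio import TreeNode

__all__ = [
    "ZOTUTable",
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "CapResult",
    "rarefy",
    "richness",
    "unifrac",
    "pcoa",
    "permanova",
    "cap",
]

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class ZOTUTable:
    """Samples x taxa integer count table with taxonomy and metadata.

    ``counts`` rows are samples, columns ZOTU identifiers; ``taxonomy``
    is indexed by ZOTU with rank columns (domain..genus, possibly
    "unclassified"); ``sample_metadata`` is indexed by sample with at
    least depth/treatment/zone/time_point; ``domain`` records which
    marker gene the table represents (bac16S / arc16S / euk18S).
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    sample_metadata: pd.DataFrame
    domain: str = ""

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError("every sample must have total count > 0")
        missing = set(self.counts.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"taxa missing taxonomy: {sorted(missing)[:5]}")
        if not self.counts.index.isin(self.sample_metadata.index).all():
            raise ValueError("every sample needs metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def relative_abundance(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with labels."""

    data: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and >= 0")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.data = 0.5 * (d + d.T)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates, eigenvalues, variance proportions."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportions: np.ndarray  # share of positive-eigenvalue variance per kept axis
    negative_eigenvalue_note: str = ""


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class CapResult:
    """Constrained ordination of PCoA axes on environmental variables."""

    coordinates: pd.DataFrame  # samples x CAP axes
    variable_scores: pd.DataFrame  # variables x CAP axes (correlations)
    explained_total: float  # share of total positive PCoA variance
    explained_per_axis: np.ndarray
    marginal_explained: pd.Series  # per-variable marginal share
    retained_axes: int
    retained_variables: list[str]


# ---------------------------------------------------------------------------
# rarefaction & richness


def rarefy(table: ZOTUTable, depth: int, seed: int = 0) -> ZOTUTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer reads than ``depth`` are dropped (a multivariate
    hypergeometric draw needs at least ``depth`` reads).  Deterministic
    given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    rows = []
    for sid in keep:
        row = table.counts.loc[sid].to_numpy()
        rows.append(rng.multivariate_hypergeometric(row, depth))
    counts = pd.DataFrame(rows, index=keep, columns=table.counts.columns)
    return ZOTUTable(
        counts=counts,
        taxonomy=table.taxonomy,
        sample_metadata=table.sample_metadata.loc[keep],
        domain=table.domain,
    )


def richness(table: ZOTUTable) -> pd.Series:
    """Observed ZOTU count (taxa with count > 0) per sample."""
    return (table.counts > 0).sum(axis=1).rename("observed_zotus")


# ---------------------------------------------------------------------------
# UniFrac


def _branch_matrix(tree: TreeNode, taxon_ids: Sequence[str]):
    """Branch lengths and tip-membership indicator per non-root node.

    Returns (lengths (m,), membership (m, n_taxa) boolean) where row j of
    ``membership`` marks the taxa descending through branch j.
    """
    tip_index = {t: i for i, t in enumerate(taxon_ids)}
    tips = {tip.name for tip in tree.tips()}
    missing = set(taxon_ids) - tips
    if missing:
        raise ValueError(f"taxon missing from tree: {sorted(missing)[0]}")
    lengths = []
    members = []
    for node in tree.postorder(include_self=False):
        bl = node.length or 0.0
        if bl < 0:
            raise ValueError("negative branch length in tree")
        mask = np.zeros(len(taxon_ids), dtype=bool)
        for tip in node.tips(include_self=True):
            idx = tip_index.get(tip.name)
            if idx is not None:
                mask[idx] = True
        lengths.append(bl)
        members.append(mask)
    return np.asarray(lengths), np.asarray(members)


def unifrac(table: ZOTUTable, tree: TreeNode, weighted: bool = True) -> DistanceMatrix:
    """UniFrac distances between all sample pairs.

    Weighted (normalized):  sum_b L_b |A_b - B_b| / sum_b L_b (A_b + B_b),
    with A_b, B_b the relative-abundance fractions of each sample
    descending through branch b; bounded in [0, 1].  Unweighted:
    sum_b L_b XOR(presence) / sum_b L_b OR(presence).
    """
    lengths, members = _branch_matrix(tree, table.taxon_ids)
    if weighted:
        prof = table.relative_abundance().to_numpy()  # samples x taxa
    else:
        prof = (table.counts.to_numpy() > 0).astype(float)
    # per-branch mass per sample: (branches x samples)
    branch_mass = members.astype(float) @ prof.T
    n = prof.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        a = branch_mass[:, i]
        for j in range(i + 1, n):
            b = branch_mass[:, j]
            if weighted:
                num = lengths @ np.abs(a - b)
                den = lengths @ (a + b)
            else:
                pa, pb = a > 0, b > 0
                num = lengths @ (pa ^ pb)
                den = lengths @ (pa | pb)
            d[i, j] = d[j, i] = num / den if den > 0 else 0.0
    return DistanceMatrix(data=d, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# ordination


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(distances: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Eigendecomposition of the double-centred Gower matrix; axes with
    positive eigenvalues carry coordinates scaled by sqrt(eigenvalue);
    negative eigenvalues (non-Euclidean distances) are reported but
    excluded from the variance proportions.  No Lingoes/Cailliez
    correction by default.
    """
    d = distances.data
    b = _gower_center(d * d)
    evals, evecs = linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10 * max(abs(evals[0]), 1.0), 0.0)
    pos = evals > tol
    n_pos = int(pos.sum())
    keep = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = evecs[:, :keep] * np.sqrt(np.maximum(evals[:keep], 0.0))
    total_pos = evals[pos].sum() if n_pos else 1.0
    proportions = evals[:keep] / total_pos if n_pos else np.zeros(0)
    note = ""
    n_neg = int((evals < -tol).sum())
    if n_neg:
        note = (
            f"{n_neg} negative eigenvalues (min {evals.min():.3g}); "
            "excluded from variance proportions, no correction applied"
        )
    cols = [f"PCo{i + 1}" for i in range(keep)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=distances.ids, columns=cols),
        eigenvalues=evals,
        proportions=np.asarray(proportions),
        negative_eigenvalue_note=note,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_f(d2: np.ndarray, onehot: np.ndarray, counts: np.ndarray):
    """Pseudo-F and R^2 from the squared-distance partition.

    ``onehot`` is the n x a group indicator; within-group SS for group g
    is (g^T D2 g) / (2 n_g), the Anderson partition.
    """
    n = d2.shape[0]
    a = onehot.shape[1]
    ss_total = d2.sum() / (2 * n)
    ss_within = float(np.sum((onehot * (d2 @ onehot)).sum(axis=0) / (2 * counts)))
    ss_among = ss_total - ss_within
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    return f, ss_among / ss_total


def permanova(
    distances: DistanceMatrix,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F from the distance-based SS partition.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations), permuting group
    labels freely (no strata).
    """
    groups = np.asarray(groups)
    d = distances.data
    if len(groups) != d.shape[0]:
        raise ValueError("group labels must match distance matrix")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs >= 2 samples")
    d2 = d * d
    codes = np.searchsorted(uniq, groups)
    onehot = np.zeros((len(groups), len(uniq)))
    onehot[np.arange(len(groups)), codes] = 1.0
    f_obs, r2 = _permanova_f(d2, onehot, counts.astype(float))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(groups))
        f_p, _ = _permanova_f(d2, onehot[perm], counts.astype(float))
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs), r_squared=float(r2), p_value=float(p),
        n_permutations=n_permutations, seed=seed,
    )


def _dbrda_marginal_p(
    d2: np.ndarray, x: np.ndarray, n_permutations: int, rng
) -> float:
    """Marginal dbRDA permutation test of one (standardized) variable.

    McArdle-Anderson pseudo-F: F = tr(H G H) / tr((I-H) G (I-H)) with G
    the Gower matrix and H the hat matrix of [1, x]; rows of x permuted.
    """
    g = _gower_center(d2)
    n = len(x)

    def f_stat(xv):
        xm = np.column_stack([np.ones(n), xv])
        h = xm @ np.linalg.pinv(xm)
        num = np.trace(h @ g @ h)
        resid = np.eye(n) - h
        den = np.trace(resid @ g @ resid)
        return num / den if den > 0 else np.inf

    f_obs = f_stat(x)
    count = 0
    for _ in range(n_permutations):
        f_p = f_stat(x[rng.permutation(n)])
        if f_p >= f_obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_permutations)


def cap(
    distances: DistanceMatrix,
    environment: pd.DataFrame,
    n_retained_axes: int | None = None,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int = 0,
    prefilter: bool = True,
) -> CapResult:
    """Canonical analysis of principal coordinates.

    PCoA on the distances, retention of the leading non-negative axes
    covering >= 95% of positive-eigenvalue variance (or a user-set
    count), then a constrained least-squares projection (redundancy
    step) of the retained coordinates onto the standardized environment
    space.  Variables are pre-filtered by a marginal dbRDA permutation
    test at ``alpha`` unless ``prefilter=False``.  Explained proportions
    are relative to the total positive-eigenvalue PCoA variance.
    """
    env = environment.loc[distances.ids].dropna(axis=0)
    if len(env) < len(distances.ids):
        keep = [i for i, sid in enumerate(distances.ids) if sid in env.index]
        d = DistanceMatrix(distances.data[np.ix_(keep, keep)], list(env.index))
    else:
        d = distances
    n = d.shape[0]
    if environment.shape[1] > n - 1:
        raise ValueError("more environmental variables than samples - 1")
    x = env.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)

    rng = np.random.default_rng(seed)
    d2 = d.data * d.data
    variables = list(env.columns)
    if prefilter:
        retained_vars = [
            v for j, v in enumerate(variables)
            if _dbrda_marginal_p(d2, x[:, j], n_permutations, rng) < alpha
        ]
    else:
        retained_vars = variables
    if not retained_vars:
        raise ValueError("no environmental variable passed the marginal test")
    xr = x[:, [variables.index(v) for v in retained_vars]]

    ord_full = pcoa(d)
    evals = ord_full.eigenvalues
    pos = evals > max(1e-10 * max(abs(evals[0]), 1.0), 0.0)
    total_pos = evals[pos].sum()
    if n_retained_axes is None:
        cum = np.cumsum(evals[pos]) / total_pos
        m = int(np.searchsorted(cum, 0.95) + 1)
    else:
        m = min(n_retained_axes, int(pos.sum()))
    q = ord_full.coordinates.to_numpy()[:, :m]  # retained PCo coordinates

    # redundancy step: project retained coordinates onto env span
    beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), xr]), q, rcond=None)
    fitted = np.column_stack([np.ones(n), xr]) @ beta
    # constrained axes: eigen-decomposition of fitted covariance
    u, s, vt = np.linalg.svd(fitted - fitted.mean(axis=0), full_matrices=False)
    n_cap = min(xr.shape[1], m, int((s > 1e-10 * max(s[0], 1.0)).sum()))
    cap_coords = (u * s)[:, :n_cap]
    explained_per_axis = (s[:n_cap] ** 2) / total_pos
    explained_total = float((s**2).sum() / total_pos)

    # variable scores: correlation of each retained variable with CAP axes
    def _corr(a, b):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    scores = np.array(
        [[_corr(xr[:, j], cap_coords[:, k]) for k in range(n_cap)] for j in range(xr.shape[1])]
    )
    # marginal explained share per variable (alone)
    marginal = {}
    for j, v in enumerate(retained_vars):
        xm = np.column_stack([np.ones(n), xr[:, j]])
        bj, *_ = np.linalg.lstsq(xm, q, rcond=None)
        fj = xm @ bj
        marginal[v] = float(((fj - fj.mean(axis=0)) ** 2).sum() / total_pos)

    cap_cols = [f"CAP{i + 1}" for i in range(n_cap)]
    return CapResult(
        coordinates=pd.DataFrame(cap_coords, index=d.ids, columns=cap_cols),
        variable_scores=pd.DataFrame(scores, index=retained_vars, columns=cap_cols),
        explained_total=explained_total,
        explained_per_axis=explained_per_axis,
        marginal_explained=pd.Series(marginal),
        retained_axes=m,
        retained_variables=retained_vars,
    )
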