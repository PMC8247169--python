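"""Gene-module discovery by graph autocorrelation (Moran's I).

Genes whose expression varies smoothly over a cell kNN graph — high
Moran's I, low q — are grouped into modules of co-regulated genes, the
procedure that yields the granule-lineage state programs.  Moran's I for
gene x over a symmetric binary weight matrix W is

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z = x - mean(x)

with S0 = sum_ij w_ij.  Significance uses the analytic normal
approximation under the randomization assumption, with a seeded
permutation test available for verification; q-values are
Benjamini-Hochberg.  Passing genes are clustered by average linkage on
1 - Pearson correlation between their cell-cluster-averaged profiles,
and modules can be merged into a requested number of main modules by
Ward clustering of their per-cell score vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .core_io import NormMatrix
from .signatures import ScoreMatrix

__all__ = [
    "KnnGraph",
    "ModuleTable",
    "morans_i",
    "find_gene_modules",
    "select_representatives",
    "merge_to_main_modules",
]

logger = logging.getLogger(__name__)


@dataclass
class KnnGraph:
    """Symmetric binary kNN graph over cells.

    Built from any low-dimensional embedding; edges are symmetrized by
    union, self-edges removed.
    """

    weights: sp.csr_matrix  # n x n, binary, symmetric, zero diagonal
    cell_ids: np.ndarray
    k: int

    def __post_init__(self) -> None:
        w = sp.csr_matrix(self.weights)
        w.setdiag(0)
        w.eliminate_zeros()
        if (w != w.T).nnz:
            raise ValueError("weight matrix must be symmetric")
        deg = np.asarray((w > 0).sum(axis=1)).ravel()
        if (deg == 0).any():
            raise ValueError(f"{int((deg == 0).sum())} node(s) have degree 0")
        self.weights = w

    @classmethod
    def from_embedding(cls, embedding: np.ndarray, cell_ids: np.ndarray,
                       k: int = 15) -> "KnnGraph":
        n = len(embedding)
        nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(embedding)
        a = nn.kneighbors_graph(embedding, mode="connectivity")
        a.setdiag(0)
        a.eliminate_zeros()
        w = ((a + a.T) > 0).astype(float)  # union symmetrization
        return cls(sp.csr_matrix(w), np.asarray(cell_ids, dtype=object), k)

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]


def _morans_i_stat(z: np.ndarray, w: sp.csr_matrix, s0: float) -> float:
    n = len(z)
    return float(n / s0 * (z @ (w @ z)) / (z @ z))


def _analytic_p(i_obs: float, z: np.ndarray, w: sp.csr_matrix, s0: float) -> float:
    """Upper-tail normal p under the randomization assumption."""
    n = len(z)
    if n < 4:  # randomization variance undefined below 4 observations
        return 1.0
    wd = w.toarray() if n <= 2000 else None
    if wd is not None:
        s1 = float(((wd + wd.T) ** 2).sum()) / 2.0
        row = wd.sum(axis=1)
        col = wd.sum(axis=0)
    else:  # pragma: no cover - large-graph path
        wt = w + w.T
        s1 = float((wt.multiply(wt)).sum()) / 2.0
        row = np.asarray(w.sum(axis=1)).ravel()
        col = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(((row + col) ** 2).sum())
    e_i = -1.0 / (n - 1)
    b2 = n * (z ** 4).sum() / ((z ** 2).sum() ** 2)
    num = n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2) - b2 * (
        (n ** 2 - n) * s1 - 2 * n * s2 + 6 * s0 ** 2
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0 ** 2
    var_i = num / den - e_i ** 2
    if var_i <= 0:
        return 1.0
    zscore = (i_obs - e_i) / np.sqrt(var_i)
    return float(stats.norm.sf(zscore))


def morans_i(
    x: np.ndarray | pd.Series,
    g: KnnGraph,
    permutations: int = 0,
    seed: int = 0,
) -> tuple[float, float]:
    """Moran's I of one per-cell variable and its upper-tail p-value.

    ``permutations=0`` uses the analytic randomization-assumption normal
    approximation; ``permutations=m`` returns the seeded permutation p
    ``(1 + #{I_perm >= I_obs}) / (1 + m)`` instead.
    """
    v = np.asarray(x, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("Moran's I needs at least 2 cells")
    if v.var() == 0:
        raise ValueError("zero-variance variable")
    w = g.weights
    s0 = float(w.sum())
    z = v - v.mean()
    i_obs = _morans_i_stat(z, w, s0)
    if permutations:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutations):
            zp = rng.permutation(z)
            if _morans_i_stat(zp, w, s0) >= i_obs:
                hits += 1
        return i_obs, (1 + hits) / (1 + permutations)
    return i_obs, _analytic_p(i_obs, z, w, s0)


@dataclass
class ModuleTable:
    """Per-gene autocorrelation results and module membership."""

    table: pd.DataFrame  # gene, morans_i, p, q, module_id (NaN if unassigned)
    skipped: list[str]  # zero-variance genes

    def modules(self) -> dict[int, list[str]]:
        passed = self.table.dropna(subset=["module_id"])
        return {
            int(m): t["gene"].tolist()
            for m, t in passed.groupby("module_id", observed=True)
        }


def find_gene_modules(
    x: NormMatrix,
    g: KnnGraph,
    i_min: float = 0.1,
    q_max: float = 0.05,
    cell_clusters: pd.Series | np.ndarray | None = None,
    corr_height: float = 0.7,
    seed: int = 0,
) -> ModuleTable:
    """Moran's I per gene, BH q-values, then module grouping.

    Genes with I > ``i_min`` and q < ``q_max`` are clustered into modules
    by average-linkage hierarchical clustering of 1 - Pearson r between
    their cell-cluster-averaged expression profiles, cutting the tree at
    ``corr_height``.  ``cell_clusters`` default to a KMeans partition of
    graph-degree-free profile space (20 clusters or n/10, whichever is
    smaller).
    """
    if g.n_cells != x.n_cells:
        raise ValueError("graph and expression matrix cover different cells")
    dense = x.dense()
    w = g.weights
    s0 = float(w.sum())
    n = x.n_cells
    variances = dense.var(axis=0)
    skipped = [str(g_) for g_ in x.gene_ids[variances == 0]]
    keep = np.flatnonzero(variances > 0)

    z = dense[:, keep] - dense[:, keep].mean(axis=0)
    wz = w @ z
    i_vals = n / s0 * (z * wz).sum(axis=0) / (z * z).sum(axis=0)
    pvals = np.array(
        [_analytic_p(i_vals[j], z[:, j], w, s0) for j in range(len(keep))]
    )
    qvals = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": x.gene_ids[keep],
            "morans_i": i_vals,
            "p": pvals,
            "q": qvals,
            "module_id": np.nan,
        }
    )
    passing = (i_vals > i_min) & (qvals < q_max)
    if not passing.any():
        raise ValueError(
            "no gene passes the module thresholds "
            f"(I quartiles: {np.percentile(i_vals, [25, 50, 75]).round(3)})"
        )

    if cell_clusters is None:
        n_clust = max(2, min(20, n // 10))
        cell_clusters = KMeans(n_clusters=n_clust, n_init=4, random_state=seed).fit(
            dense
        ).labels_
    labels = np.asarray(cell_clusters)
    uniq = np.unique(labels)
    profiles = np.vstack(
        [dense[labels == c][:, keep[passing]].mean(axis=0) for c in uniq]
    ).T  # passing genes x clusters
    if profiles.shape[0] == 1:
        module_ids = np.array([1])
    else:
        corr = np.corrcoef(profiles)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.maximum((dist + dist.T) / 2.0, 0.0)
        condensed = dist[np.triu_indices_from(dist, k=1)]
        tree = linkage(condensed, method="average")
        module_ids = fcluster(tree, t=corr_height, criterion="distance")
    table.loc[np.flatnonzero(passing), "module_id"] = module_ids
    logger.info(
        "%d genes pass, %d modules", int(passing.sum()), len(np.unique(module_ids))
    )
    return ModuleTable(table=table, skipped=skipped)


def select_representatives(
    mt: ModuleTable, x: NormMatrix, top_n: int = 50
) -> dict[int, list[str]]:
    """Per module, the top-``top_n`` genes by dataset-mean expression."""
    mean_expr = pd.Series(
        np.asarray(x.dense()).mean(axis=0), index=x.gene_ids
    )
    out = {}
    for mod, genes in mt.modules().items():
        ranked = mean_expr.loc[genes].sort_values(ascending=False)
        out[mod] = ranked.index[: min(top_n, len(ranked))].tolist()
    return out


def merge_to_main_modules(
    scores: ScoreMatrix, n_main: int = 4
) -> pd.Series:
    """Group module score columns into main modules by Ward clustering.

    ``scores`` holds one per-cell score column per module (computed on the
    representative gene lists); columns are standardized and clustered
    with Ward linkage on Euclidean distance, cutting at ``n_main``.
    Returns module name -> main module id (1-based).
    """
    df = scores.values
    if n_main > df.shape[1]:
        raise ValueError(
            f"requested {n_main} main modules but only {df.shape[1]} modules exist"
        )
    std = (df - df.mean()) / df.std(ddof=0).replace(0, 1.0)
    tree = linkage(std.to_numpy().T, method="ward")
    ids = fcluster(tree, t=n_main, criterion="maxclust")
    return pd.Series(ids, index=df.columns, name="main_module")
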