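"""RNA-velocity estimation and transition-destination quantification.

Velocity is estimated under the classical steady-state model: for each
gene, the degradation/splicing ratio ``gamma`` is fitted by a
through-origin regression of unspliced on spliced counts restricted to
cells in the extreme quantiles of spliced expression (cells presumed at
steady state), and the per-cell velocity is the residual
``v = u - gamma * s``.  A positive residual marks induction, a negative
one repression.

Transitions are then quantified exactly as in the source study: the
transition-matrix element for cell i and neighbor j is the Pearson
correlation between cell i's velocity vector and the expression
difference vector (x_j - x_i) over the velocity genes; a cell's
destination is the neighbor with the highest correlation, and state-level
destination proportions between two conditions are compared with
Pearson's chi-square test on the destination-count contingency table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core_io import NormMatrix
from .signatures import StateAssignment

__all__ = [
    "KineticsMatrix",
    "VelocityField",
    "TransitionSummary",
    "estimate_velocity_steady_state",
    "transition_matrix",
    "assign_destinations",
    "transition_contingency",
    "pearson_chi_square",
]

logger = logging.getLogger(__name__)


@dataclass
class KineticsMatrix:
    """Spliced / unspliced abundance matrices over shared cells and genes."""

    spliced: np.ndarray  # cells x genes, non-negative
    unspliced: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.spliced = np.asarray(self.spliced, dtype=float)
        self.unspliced = np.asarray(self.unspliced, dtype=float)
        if self.spliced.shape != self.unspliced.shape:
            raise ValueError("spliced and unspliced shapes differ")
        if (self.spliced < 0).any() or (self.unspliced < 0).any():
            raise ValueError("kinetics matrices must be non-negative")
        if self.spliced.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("kinetics shape inconsistent with identifiers")

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]


@dataclass
class VelocityField:
    """Per-cell velocity over a gene subset, plus a cell kNN graph."""

    velocity: np.ndarray  # cells x velocity genes
    gene_ids: np.ndarray  # velocity gene subset
    gamma: np.ndarray  # fitted gamma per velocity gene
    cell_ids: np.ndarray
    neighbors: np.ndarray  # cells x k neighbor indices (row-wise)
    embedding: np.ndarray | None = None
    flagged: np.ndarray | None = None  # cells with zero-norm velocity

    def __post_init__(self) -> None:
        if not np.isfinite(self.velocity).all():
            raise ValueError("velocity contains non-finite values")
        if self.flagged is None:
            norms = np.linalg.norm(self.velocity, axis=1)
            self.flagged = norms == 0


def _top_variable_genes(s: np.ndarray, u: np.ndarray, n: int) -> np.ndarray:
    """Indices of the top-n genes by spliced variance (ties by order)."""
    var = s.var(axis=0)
    if n >= s.shape[1]:
        return np.arange(s.shape[1])
    return np.sort(np.argpartition(-var, n)[:n])


def estimate_velocity_steady_state(
    k: KineticsMatrix,
    top_genes: int = 3000,
    min_counts: int = 10,
    quantile: float = 0.05,
    n_neighbors: int | None = 30,
    n_pcs: int = 30,
    embedding: np.ndarray | None = None,
) -> VelocityField:
    """Fit per-gene steady-state ratios and residual velocities.

    Genes must carry at least ``min_counts`` total counts in both the
    spliced and unspliced matrices; of those, the ``top_genes`` most
    variable (by spliced variance) are kept.  Per gene, cells in the upper
    and lower ``quantile`` of spliced expression anchor a through-origin
    regression of u on s whose slope is ``gamma``; velocity is
    ``u - gamma * s``.  The cell kNN graph is built on ``embedding`` if
    given, else on a PCA of log1p spliced expression;
    ``n_neighbors=None`` uses the complete graph (every other cell is a
    potential destination), useful when discrete populations would
    otherwise have no cross-population neighbors.
    """
    if k.n_cells < 50:
        raise ValueError("need at least 50 cells for steady-state estimation")
    s, u = k.spliced, k.unspliced
    keep = (s.sum(axis=0) >= min_counts) & (u.sum(axis=0) >= min_counts)
    if not keep.any():
        raise ValueError("no gene passes the joint minimum-count filter")
    gidx = np.flatnonzero(keep)
    s, u = s[:, gidx], u[:, gidx]
    sub = _top_variable_genes(s, u, top_genes)
    gidx = gidx[sub]
    s, u = s[:, sub], u[:, sub]

    n_cells, n_genes = s.shape
    n_extreme = max(int(np.ceil(quantile * n_cells)), 2)
    order = np.argsort(s, axis=0)
    extreme = np.concatenate([order[:n_extreme], order[-n_extreme:]], axis=0)
    cols = np.broadcast_to(np.arange(n_genes), extreme.shape)
    s_ext = s[extreme, cols]
    u_ext = u[extreme, cols]
    ss = (s_ext * s_ext).sum(axis=0)
    su = (s_ext * u_ext).sum(axis=0)
    ok = ss > 0
    if not ok.all():
        logger.info("dropping %d gene(s) with all-zero spliced extremes", (~ok).sum())
    gamma = np.where(ok, su / np.where(ok, ss, 1.0), np.nan)
    s, u, gamma, gidx = s[:, ok], u[:, ok], gamma[ok], gidx[ok]
    velocity = u - gamma[None, :] * s

    if embedding is None:
        x = np.log1p(s)
        n_comp = min(n_pcs, x.shape[1], n_cells - 1)
        embedding = PCA(n_components=n_comp, random_state=0).fit_transform(x)
    if n_neighbors is None:
        all_idx = np.arange(n_cells)
        neighbors = np.vstack(
            [np.delete(all_idx, i) for i in range(n_cells)]
        )
    else:
        nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, n_cells)).fit(embedding)
        _, idx = nn.kneighbors(embedding)
        neighbors = idx[:, 1:]  # drop self

    return VelocityField(
        velocity=velocity,
        gene_ids=k.gene_ids[gidx],
        gamma=gamma,
        cell_ids=k.cell_ids,
        neighbors=neighbors,
        embedding=embedding,
    )


def transition_matrix(vf: VelocityField, x: NormMatrix) -> sp.csr_matrix:
    """Velocity-based cell transition matrix.

    element(i, j) = Pearson correlation between cell i's velocity vector
    and the expression-difference vector (x_j - x_i), restricted to the
    velocity genes, for each kNN neighbor j of i; zero elsewhere and on
    the diagonal.
    """
    pos = x.gene_index(vf.gene_ids)
    if (pos < 0).any():
        missing = vf.gene_ids[pos < 0][:5]
        raise KeyError(f"velocity genes absent from expression matrix: {missing}")
    dense = x.dense()[:, pos]
    v = vf.velocity
    n, g = v.shape
    vc = v - v.mean(axis=1, keepdims=True)
    vnorm = np.linalg.norm(vc, axis=1)

    if n <= 4000:
        # full pairwise correlation, then mask to the neighbor lists;
        # centering the difference vector is free because vc has zero mean
        gram = dense @ dense.T
        sq = np.einsum("ij,ij->i", dense, dense)
        m = dense.mean(axis=1)
        a = dense @ vc.T  # a[j, i] = x_j . vc_i
        numer = a.T - np.diag(a)[:, None]
        d2 = sq[None, :] + sq[:, None] - 2.0 * gram - g * (m[None, :] - m[:, None]) ** 2
        dnorm = np.sqrt(np.maximum(d2, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r_full = numer / (dnorm * vnorm[:, None])
        r_full = np.nan_to_num(r_full, nan=0.0)
        rows = np.repeat(np.arange(n), vf.neighbors.shape[1])
        cols = vf.neighbors.ravel()
        vals = r_full[rows, cols]
        ok = vnorm[rows] > 0
        tm = sp.csr_matrix((vals[ok], (rows[ok], cols[ok])), shape=(n, n))
        return tm

    rows_l, cols_l, vals_l = [], [], []
    for i in range(n):
        js = vf.neighbors[i]
        if vnorm[i] == 0:
            continue
        diff = dense[js] - dense[i]
        dc = diff - diff.mean(axis=1, keepdims=True)
        dnorm_i = np.linalg.norm(dc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (dc @ vc[i]) / (dnorm_i * vnorm[i])
        r = np.nan_to_num(r, nan=0.0)
        rows_l.extend([i] * len(js))
        cols_l.extend(js.tolist())
        vals_l.extend(r.tolist())
    return sp.csr_matrix((vals_l, (rows_l, cols_l)), shape=(n, n))


def assign_destinations(
    tm: sp.csr_matrix,
    states: StateAssignment | pd.Series,
    flagged: np.ndarray | None = None,
) -> pd.DataFrame:
    """Destination cell and state per cell: the highest-correlation neighbor.

    Cells with a zero-norm velocity (flagged, empty rows) keep their own
    state as destination and are marked ``self_flagged``.
    Returns a frame indexed like ``states`` with columns ``dest_cell``,
    ``dest_state``, ``corr``, ``self_flagged``.
    """
    state = states.state if isinstance(states, StateAssignment) else states
    labels = state.to_numpy(object)
    n = tm.shape[0]
    if n != len(labels):
        raise ValueError("transition matrix and state labels disagree in size")
    dest_cell = np.arange(n)
    dest_state = labels.copy()
    corr = np.zeros(n)
    self_flagged = np.zeros(n, dtype=bool)
    indptr, indices, data = tm.indptr, tm.indices, tm.data
    for i in range(n):
        lo, hi = indptr[i], indptr[i + 1]
        if hi == lo or (flagged is not None and flagged[i]):
            self_flagged[i] = True
            continue
        row = data[lo:hi]
        best = lo + int(np.argmax(row))
        dest_cell[i] = indices[best]
        dest_state[i] = labels[indices[best]]
        corr[i] = data[best]
    if self_flagged.all():
        logger.warning("all cells flagged; destinations default to self-state")
    return pd.DataFrame(
        {
            "dest_cell": state.index.to_numpy(object)[dest_cell],
            "dest_state": dest_state,
            "corr": corr,
            "self_flagged": self_flagged,
        },
        index=state.index,
    )


def pearson_chi_square(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-square statistic, p and dof for a contingency table.

    chi2 = sum (observed - expected)^2 / expected with expected counts
    from the product of the table margins (no continuity correction).
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("contingency counts must be non-negative")
    stat, p, dof, expected = stats.chi2_contingency(t, correction=False)
    if (expected < 5).any():
        logger.warning(
            "%d expected count(s) < 5 in the chi-square table", int((expected < 5).sum())
        )
    return float(stat), float(p), int(dof)


@dataclass
class TransitionSummary:
    """Destination counts/proportions per condition plus the chi-square test."""

    counts: pd.DataFrame  # condition x destination state, integer counts
    proportions: pd.DataFrame  # rows sum to 1
    chi_square: float
    p_value: float
    dof: int
    source_state: str


def transition_contingency(
    dests_a: pd.DataFrame,
    dests_b: pd.DataFrame,
    states_a: pd.Series,
    states_b: pd.Series,
    source_state: str,
    condition_names: tuple[str, str] = ("A", "B"),
    min_cells: int = 20,
) -> TransitionSummary:
    """Compare destination distributions of one source state between conditions.

    ``dests_*`` are outputs of :func:`assign_destinations`; ``states_*``
    the per-cell source-state labels.  Destination categories absent from
    both conditions are dropped (logged).
    """
    rows = {}
    for name, dests, states in (
        (condition_names[0], dests_a, states_a),
        (condition_names[1], dests_b, states_b),
    ):
        mask = states.to_numpy(object) == source_state
        if mask.sum() < min_cells:
            raise ValueError(
                f"condition {name!r} has only {int(mask.sum())} cells in source "
                f"state {source_state!r} (need >= {min_cells})"
            )
        rows[name] = dests.loc[mask, "dest_state"].value_counts()
    counts = pd.DataFrame(rows).T.fillna(0).astype(int)
    empty = counts.columns[(counts.sum(axis=0) == 0)]
    if len(empty):
        logger.info("dropping empty destination categories: %s", list(empty))
        counts = counts.drop(columns=empty)
    props = counts.div(counts.sum(axis=1), axis=0)
    stat, p, dof = pearson_chi_square(counts.to_numpy())
    return TransitionSummary(
        counts=counts,
        proportions=props,
        chi_square=stat,
        p_value=p,
        dof=dof,
        source_state=source_state,
    )
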