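"""Signature scoring with bin-matched control genes, and state assignment.

A cell's score for a gene program is the mean ln-normalized expression of
the program's genes minus the mean of a matched control set: every gene in
the dataset is placed into one of ``n_bins`` equal-frequency bins by its
dataset-average expression, and each signature gene contributes ``n_ctrl``
control genes drawn (seeded, without replacement) from its own bin.  The
subtraction cancels cell-to-cell complexity differences so that scores are
comparable across cells; the scheme is the standard module-score approach
used throughout droplet single-cell work.

Cells are assigned to the state whose signature scores highest, and a
cell-cycle flag is derived by thresholding the combined G1/S / G2-M score
at 2 median absolute deviations above the median.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import NormMatrix, read_gmt

__all__ = [
    "GeneSignature",
    "ScoreMatrix",
    "StateAssignment",
    "score_signature",
    "score_signatures",
    "score_cell_cycle",
    "assign_state_by_max",
    "binarize_by_mad",
    "default_cell_cycle_signatures",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered, duplicate-free gene list with an optional tag."""

    name: str
    genes: tuple[str, ...]
    tag: str | None = None  # state | module | meta-program | cycle-phase

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if not genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ScoreMatrix:
    """Cells x signatures score table, remembering the control-draw seed."""

    values: pd.DataFrame  # index = cell ids, columns = signature names
    seed: int | None = None

    @property
    def cell_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def signature_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class StateAssignment:
    """Max-score state call per cell, plus the winning score and flags."""

    state: pd.Series  # cell -> state label
    score: pd.Series  # cell -> winning score
    tied: pd.Series  # cell -> bool, exact tie broken by column order
    cycling: pd.Series | None = None

    def counts(self) -> pd.Series:
        return self.state.value_counts()


def _mean_expression(x: NormMatrix) -> np.ndarray:
    v = x.values
    if sp.issparse(v):
        return np.asarray(v.mean(axis=0)).ravel()
    return np.asarray(v).mean(axis=0)


def _expression_bins(mean_expr: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per gene, ranked by dataset mean."""
    order = pd.Series(mean_expr).rank(method="first").to_numpy() - 1
    return np.floor(order * n_bins / len(mean_expr)).astype(int)


def score_signatures(
    x: NormMatrix,
    sigs: Sequence[GeneSignature],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int | None = 0,
) -> ScoreMatrix:
    """Score several signatures on a shared binning; returns a ScoreMatrix."""
    mean_expr = _mean_expression(x)
    bins = _expression_bins(mean_expr, n_bins)
    dense = x.dense()
    cols = {}
    for sig in sigs:
        cols[sig.name] = _score_one(x, dense, bins, sig, n_ctrl, seed)
    return ScoreMatrix(pd.DataFrame(cols, index=x.cell_ids), seed=seed)


def score_signature(
    x: NormMatrix,
    sig: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int | None = 0,
) -> pd.Series:
    """Per-cell bin-matched control score for one signature.

    score(cell) = mean over signature genes - mean over the pooled control
    genes.  Deterministic for a fixed ``seed``.  Signature genes absent
    from ``x`` are dropped with a warning; if none remain this is an error.
    """
    mean_expr = _mean_expression(x)
    bins = _expression_bins(mean_expr, n_bins)
    return _score_one(x, x.dense(), bins, sig, n_ctrl, seed)


def _score_one(
    x: NormMatrix,
    dense: np.ndarray,
    bins: np.ndarray,
    sig: GeneSignature,
    n_ctrl: int,
    seed: int | None,
) -> pd.Series:
    idx = pd.Index(x.gene_ids)
    pos = idx.get_indexer(sig.genes)
    missing = [g for g, p in zip(sig.genes, pos) if p < 0]
    if missing:
        warnings.warn(
            f"signature {sig.name!r}: {len(missing)} gene(s) absent, e.g. "
            f"{missing[:3]}",
            stacklevel=3,
        )
    pos = pos[pos >= 0]
    if len(pos) == 0:
        raise ValueError(f"no gene of signature {sig.name!r} present in the data")

    rng = np.random.default_rng(None if seed is None else seed)
    sig_set = set(pos.tolist())
    ctrl_pos: list[np.ndarray] = []
    n_small_bins = 0
    for p in pos:
        candidates = np.flatnonzero(bins == bins[p])
        candidates = candidates[[c not in sig_set for c in candidates]]
        if len(candidates) >= n_ctrl:
            ctrl_pos.append(rng.choice(candidates, size=n_ctrl, replace=False))
        elif len(candidates) == 0:
            logger.warning(
                "signature %s: gene bin has no non-signature candidates", sig.name
            )
        else:
            n_small_bins += 1
            ctrl_pos.append(rng.choice(candidates, size=n_ctrl, replace=True))
    if n_small_bins:
        logger.info(
            "signature %s: %d/%d control bins smaller than n_ctrl=%d, "
            "sampled with replacement",
            sig.name, n_small_bins, len(pos), n_ctrl,
        )
    controls = np.concatenate(ctrl_pos) if ctrl_pos else np.array([], dtype=int)
    sig_mean = dense[:, pos].mean(axis=1)
    ctrl_mean = (
        dense[:, controls].mean(axis=1) if len(controls) else np.zeros(len(dense))
    )
    return pd.Series(sig_mean - ctrl_mean, index=x.cell_ids, name=sig.name)


def score_cell_cycle(
    x: NormMatrix,
    g1s: GeneSignature | None = None,
    g2m: GeneSignature | None = None,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int | None = 0,
) -> pd.DataFrame:
    """G1/S and G2/M scores per cell plus their max as the combined score.

    Defaults to the packaged phase gene lists (43 G1/S, 54 G2/M genes).
    Returns a frame with columns ``g1s``, ``g2m``, ``cycle`` (the max).
    """
    if g1s is None or g2m is None:
        d_g1s, d_g2m = default_cell_cycle_signatures()
        g1s = g1s or d_g1s
        g2m = g2m or d_g2m
    sm = score_signatures(x, [g1s, g2m], n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    out = pd.DataFrame(
        {"g1s": sm.values[g1s.name], "g2m": sm.values[g2m.name]}, index=sm.values.index
    )
    out["cycle"] = out[["g1s", "g2m"]].max(axis=1)
    return out


def default_cell_cycle_signatures() -> tuple[GeneSignature, GeneSignature]:
    """The packaged G1/S (43 genes) and G2/M (54 genes) phase lists."""
    path = resources.files("cbstates.data") / "cell_cycle_mouse.gmt"
    sets = read_gmt(str(path))
    return (
        GeneSignature("G1S", tuple(sets["G1S"]), tag="cycle-phase"),
        GeneSignature("G2M", tuple(sets["G2M"]), tag="cycle-phase"),
    )


def assign_state_by_max(scores: ScoreMatrix) -> StateAssignment:
    """Assign each cell to the signature with the maximum score.

    Exact ties go to the earlier column (flagged).  NaN scores are an
    error naming the offending cell.
    """
    df = scores.values
    if df.shape[1] < 2:
        raise ValueError("state assignment needs at least two signature columns")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"NaN score for cell {bad!r}")
    arr = df.to_numpy()
    win = arr.argmax(axis=1)
    winning = arr[np.arange(len(arr)), win]
    tied = (arr == winning[:, None]).sum(axis=1) > 1
    if tied.any():
        logger.info("%d cell(s) with exact score ties, first column wins", tied.sum())
    labels = np.asarray(df.columns.to_numpy(object))[win]
    return StateAssignment(
        state=pd.Series(labels, index=df.index, name="state"),
        score=pd.Series(winning, index=df.index, name="score"),
        tied=pd.Series(tied, index=df.index, name="tied"),
    )


def binarize_by_mad(values: pd.Series | np.ndarray, k: float = 2.0) -> pd.Series:
    """True where value > median + k * MAD (unscaled median absolute deviation).

    With all-identical values the MAD is 0 and nothing is called positive
    (a warning is emitted).
    """
    v = pd.Series(values)
    if len(v) < 2:
        raise ValueError("need at least two values to binarize")
    med = float(v.median())
    mad = float((v - med).abs().median())
    if mad == 0 and (v == med).all():
        warnings.warn("all values identical; MAD is 0, no positives", stacklevel=2)
    threshold = med + k * mad
    out = v > threshold
    out.attrs["threshold"] = threshold
    return out
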