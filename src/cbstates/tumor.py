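"""Intra-tumor expression programs, inferred CNVs, and lineage similarity.

Per tumor, non-negative matrix factorization (10 factors, multiplicative
updates, seeded) of the centered-and-clipped ln-normalized expression of
malignant cells yields transcriptional programs, each summarized by its
top-50 weight genes.  Factors recurring across tumors are grouped into
meta-programs by Ward clustering with 1 - Pearson correlation of their
per-cell activity scores as the distance.  Meta-programs are related to
developmental cell states by the Jaccard index of their signatures.

Copy-number profiles are inferred from expression alone: genes are
ordered along the genome, per-gene relative expression is clipped and
smoothed with a moving average within each chromosome, each cell is
centered by its own mean, and the mean profile of reference (normal)
cells is subtracted, leaving chromosome-scale deviations that separate
malignant from non-malignant cells.

Lineage similarity projects query (tumor) and reference (developmental)
cells into a shared principal-component space with per-dataset centering
and lets each query cell's k nearest reference cells vote on its label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import NMF, PCA
from sklearn.neighbors import NearestNeighbors

from .core_io import NormMatrix
from .signatures import GeneSignature, score_signatures

__all__ = [
    "FactorModel",
    "MetaProgram",
    "CnvMatrix",
    "nmf_programs",
    "cluster_meta_programs",
    "jaccard_similarity",
    "infer_cnv",
    "knn_similarity",
]

logger = logging.getLogger(__name__)


@dataclass
class FactorModel:
    """Per-sample NMF decomposition with top-gene signatures."""

    sample: str
    w: pd.DataFrame  # genes x factors, non-negative
    h: pd.DataFrame  # factors x cells, non-negative
    top_genes: dict[str, list[str]]  # factor name -> top-n genes by weight
    reconstruction_err: float

    @property
    def factor_names(self) -> list[str]:
        return list(self.w.columns)


def nmf_prepare(x: NormMatrix) -> np.ndarray:
    """Center each gene, clip negatives to zero: the NMF input transform."""
    dense = x.dense()
    return np.clip(dense - dense.mean(axis=0), 0.0, None)


def nmf_programs(
    x: NormMatrix,
    n_factors: int = 10,
    top_n: int = 50,
    seed: int = 0,
    sample: str = "sample",
    max_iter: int = 500,
) -> FactorModel:
    """Seeded multiplicative-update NMF of one tumor's malignant cells.

    Input is the ln-normalized expression, per-gene centered with
    negative values clipped to zero.  Factors are named
    ``{sample}.F{index}``; each carries its ``top_n`` genes by W weight.
    """
    if x.n_cells < 100:
        raise ValueError("NMF programs need at least 100 malignant cells")
    mat = nmf_prepare(x)
    if mat.max() == 0:
        raise ValueError("all-zero matrix after centering and clipping")
    model = NMF(
        n_components=n_factors,
        solver="mu",
        init="random",
        random_state=seed,
        max_iter=max_iter,
        tol=1e-4,
    )
    h_cells = model.fit_transform(mat)  # cells x factors
    w_genes = model.components_.T  # genes x factors
    names = [f"{sample}.F{j}" for j in range(n_factors)]
    w = pd.DataFrame(w_genes, index=x.gene_ids, columns=names)
    h = pd.DataFrame(h_cells.T, index=names, columns=x.cell_ids)
    top = {
        f: w[f].sort_values(ascending=False).index[:top_n].tolist() for f in names
    }
    return FactorModel(
        sample=sample,
        w=w,
        h=h,
        top_genes=top,
        reconstruction_err=float(model.reconstruction_err_),
    )


@dataclass
class MetaProgram:
    """A cluster of NMF factors recurring across tumors."""

    id: int
    members: list[tuple[str, str]]  # (sample, factor name)
    signature: list[str]  # consensus top genes, padded to 50
    scores: pd.Series | None = None  # per-cell activity


def cluster_meta_programs(
    models: list[FactorModel],
    x: NormMatrix,
    n_meta: int = 4,
    top_n: int = 50,
    seed: int = 0,
    robust_min_genes: int | None = 10,
) -> list[MetaProgram]:
    """Ward clustering of factor activity scores into meta-programs.

    With more factors per tumor than real programs, some factors absorb
    sample-private noise; following the usual recurrent-program
    convention, a factor enters the meta-analysis only if its top-gene
    list shares at least ``robust_min_genes`` genes with some factor of a
    *different* sample (set ``None`` to keep all factors, or when only
    one sample is given).  Every surviving factor's top-gene list is
    scored on the combined cell set (bin-matched control scores); the
    distance between factors is 1 - Pearson r of their score vectors;
    Ward linkage is cut at ``n_meta``.  A meta-program's signature holds
    the genes present in at least half of its member factors' top lists,
    padded to ``top_n`` by aggregate W rank.
    """
    factors: list[tuple[str, str]] = []
    sigs: list[GeneSignature] = []
    for m in models:
        for f in m.factor_names:
            factors.append((m.sample, f))
            sigs.append(GeneSignature(f, tuple(m.top_genes[f]), tag="module"))
    if robust_min_genes is not None and len(models) > 1:
        keep = []
        for i, (si, fi) in enumerate(factors):
            genes_i = set(sigs[i].genes)
            recurrent = any(
                sj != si and len(genes_i & set(sigs[j].genes)) >= robust_min_genes
                for j, (sj, fj) in enumerate(factors)
            )
            if recurrent:
                keep.append(i)
        if keep:
            dropped = len(factors) - len(keep)
            if dropped:
                logger.info("dropping %d non-recurrent factor(s)", dropped)
            factors = [factors[i] for i in keep]
            sigs = [sigs[i] for i in keep]
        else:
            logger.warning("no recurrent factors; keeping all")
    if len(factors) < 2:
        raise ValueError("need at least two factors across samples")
    if n_meta > len(factors):
        raise ValueError(f"n_meta={n_meta} exceeds {len(factors)} factors")
    sm = score_signatures(x, sigs, seed=seed)
    arr = sm.values.to_numpy().T  # factors x cells
    corr = np.corrcoef(arr)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = np.maximum(dist, 0.0)[np.triu_indices_from(dist, k=1)]
    ids = fcluster(linkage(condensed, method="ward"), t=n_meta, criterion="maxclust")

    w_by_sample = {m.sample: m.w for m in models}
    out = []
    for mp in sorted(set(ids)):
        member_idx = np.flatnonzero(ids == mp)
        members = [factors[i] for i in member_idx]
        gene_counts: dict[str, int] = {}
        for i in member_idx:
            for gene in sigs[i].genes:
                gene_counts[gene] = gene_counts.get(gene, 0) + 1
        half = len(members) / 2.0
        core = [g for g, c in gene_counts.items() if c >= half]
        # aggregate W rank for deterministic ordering / padding
        agg = {}
        for sample, f in members:
            w = w_by_sample[sample][f]
            wn = w / max(float(w.max()), 1e-12)
            for gene, val in wn.items():
                agg[gene] = agg.get(gene, 0.0) + float(val)
        ranked = sorted(agg, key=lambda g: -agg[g])
        signature = sorted(core, key=lambda g: -agg.get(g, 0.0))[:top_n]
        for gene in ranked:
            if len(signature) >= top_n:
                break
            if gene not in signature:
                signature.append(gene)
        mean_scores = sm.values.iloc[:, member_idx].mean(axis=1)
        out.append(
            MetaProgram(id=int(mp), members=members, signature=signature,
                        scores=mean_scores)
        )
    return out


def jaccard_similarity(a: set[str], b: set[str]) -> float:
    """|a ∩ b| / |a ∪ b|; both sets must be non-empty."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("Jaccard similarity of an empty set is undefined")
    return len(a & b) / len(a | b)


@dataclass
class CnvMatrix:
    """Cells x genomic-window smoothed relative-expression profiles."""

    values: pd.DataFrame  # index cells, columns window ids
    window_meta: pd.DataFrame  # window id -> chromosome, gene, start
    reference_cells: list[str]

    def aggregate_signal(self) -> pd.Series:
        """Per-cell mean of squared window scores (overall CNV burden)."""
        return (self.values ** 2).mean(axis=1)

    def chromosome_means(self) -> pd.DataFrame:
        """Per-cell mean window score per chromosome."""
        groups = self.window_meta["chromosome"]
        return self.values.T.groupby(groups.to_numpy()).mean().T


def _moving_average_shrunk(mat: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with a symmetric shrunk window.

    At position i of a chromosome with n genes the half-width is
    min((window-1)//2, i, n-1-i), so edge windows stay symmetric; a
    window at least as long as the chromosome reduces every position to
    the full-chromosome mean.
    """
    n = mat.shape[1]
    half = (window - 1) // 2
    if window >= n:  # degenerate chromosome: one full-chromosome average
        return np.repeat(mat.mean(axis=1, keepdims=True), n, axis=1)
    csum = np.zeros((mat.shape[0], n + 1))
    np.cumsum(mat, axis=1, out=csum[:, 1:])
    out = np.empty_like(mat)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[:, i] = (csum[:, i + h + 1] - csum[:, i - h]) / (2 * h + 1)
    return out


def infer_cnv(
    x: NormMatrix,
    gene_meta: pd.DataFrame,
    reference_cells: list[str] | np.ndarray,
    window: int = 101,
    clip: float = 3.0,
    min_genes_per_chrom: int = 5,
    min_mean: float = 0.1,
    exclude_genes: set[str] | None = None,
) -> CnvMatrix:
    """Moving-average inferred CNV profiles relative to reference cells.

    ``gene_meta`` maps gene id -> (chromosome, start); genes without
    annotation are ignored (at least 80% must be annotated).  Pipeline:
    drop genes whose dataset-mean ln-normalized expression is below
    ``min_mean`` (near-zero genes carry dose information too noisy to
    smooth) and any ``exclude_genes`` (conventionally a curated
    cell-cycle list, whose proliferation-driven swings masquerade as
    dose); order the rest by (chromosome, start); clip per-gene
    relative expression to ±``clip`` around the dataset mean;
    moving-average of length ``window`` within each chromosome; center
    each cell by its own mean; subtract the reference cells' per-window
    means from every cell.
    """
    meta = gene_meta.reindex(x.gene_ids).dropna(subset=["chromosome", "start"])
    if len(meta) < 0.8 * x.n_genes:
        raise ValueError(
            f"gene annotation covers only {len(meta)}/{x.n_genes} genes (< 80%)"
        )
    if min_mean > 0:
        gene_means = pd.Series(
            np.asarray(x.dense()).mean(axis=0), index=x.gene_ids
        )
        expressed = gene_means.index[gene_means >= min_mean]
        meta = meta.loc[meta.index.intersection(expressed)]
    if exclude_genes:
        meta = meta.loc[~meta.index.isin(set(exclude_genes))]
    ref = [str(c) for c in reference_cells]
    cell_index = pd.Index(x.cell_ids)
    missing = set(ref) - set(cell_index)
    if missing or not ref:
        raise ValueError("reference cells empty or not all present in the matrix")

    chrom_sizes = meta["chromosome"].value_counts()
    small = chrom_sizes[chrom_sizes < min_genes_per_chrom].index.tolist()
    if small:
        logger.info("excluding chromosomes with < %d genes: %s",
                    min_genes_per_chrom, small)
        meta = meta[~meta["chromosome"].isin(small)]
    meta = meta.sort_values(["chromosome", "start"], kind="stable")

    dense = x.dense()
    gene_pos = pd.Index(x.gene_ids).get_indexer(meta.index)
    rel = dense[:, gene_pos] - dense[:, gene_pos].mean(axis=0)
    np.clip(rel, -clip, clip, out=rel)

    smoothed = np.empty_like(rel)
    col = 0
    for chrom, sub in meta.groupby("chromosome", sort=False):
        n_c = len(sub)
        smoothed[:, col : col + n_c] = _moving_average_shrunk(
            rel[:, col : col + n_c], window
        )
        col += n_c
    smoothed -= smoothed.mean(axis=1, keepdims=True)  # per-cell centering
    ref_rows = cell_index.get_indexer(ref)
    smoothed -= smoothed[ref_rows].mean(axis=0, keepdims=True)

    window_ids = [f"{c}:{g}" for c, g in zip(meta["chromosome"], meta.index)]
    values = pd.DataFrame(smoothed, index=x.cell_ids, columns=window_ids)
    window_meta = pd.DataFrame(
        {
            "chromosome": meta["chromosome"].to_numpy(),
            "gene": meta.index.to_numpy(),
            "start": meta["start"].to_numpy(int),
        },
        index=window_ids,
    )
    return CnvMatrix(values=values, window_meta=window_meta, reference_cells=ref)


def knn_similarity(
    query: NormMatrix,
    reference: NormMatrix,
    ref_labels: pd.Series | np.ndarray,
    k: int = 20,
    n_pcs: int = 30,
    min_shared_genes: int = 200,
) -> tuple[pd.DataFrame, pd.Series]:
    """k-nearest-reference-neighbor label scores for each query cell.

    Both matrices are subset to their common genes and projected with
    shared principal-component loadings fitted on the concatenated,
    per-dataset-centered matrix.  Each query cell's ``k`` nearest
    reference cells vote with one-hot label vectors; the averaged votes
    are per-label scores summing to 1 per cell.  Returns (per-cell score
    frame, per-label mean scores).
    """
    labels = pd.Series(np.asarray(ref_labels, dtype=object),
                       index=reference.cell_ids)
    if k > reference.n_cells:
        raise ValueError(f"k={k} exceeds {reference.n_cells} reference cells")
    shared = sorted(set(query.gene_ids) & set(reference.gene_ids))
    if len(shared) < min_shared_genes:
        raise ValueError(f"only {len(shared)} shared genes (< {min_shared_genes})")
    q = query.subset_genes(shared).dense()
    r = reference.subset_genes(shared).dense()
    q = q - q.mean(axis=0)
    r = r - r.mean(axis=0)
    joint = np.vstack([r, q])
    n_comp = min(n_pcs, joint.shape[1], joint.shape[0] - 1)
    pca = PCA(n_components=n_comp, random_state=0).fit(joint)
    r_pc = pca.transform(r)
    q_pc = pca.transform(q)

    nn = NearestNeighbors(n_neighbors=k).fit(r_pc)
    _, idx = nn.kneighbors(q_pc)
    label_values = labels.to_numpy(object)
    uniq = sorted(set(label_values.tolist()))
    onehot = np.zeros((reference.n_cells, len(uniq)))
    for j, lab in enumerate(uniq):
        onehot[label_values == lab, j] = 1.0
    scores = onehot[idx].mean(axis=1)
    frame = pd.DataFrame(scores, index=query.cell_ids, columns=uniq)
    return frame, frame.mean(axis=0)
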