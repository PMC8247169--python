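"""Data containers, readers/writers, QC filters and log-normalization.

The universal container is :class:`CountMatrix`, a sparse cells x genes
matrix of UMI counts with string identifiers and optional per-gene
annotation (chromosome, start, mito/ribo flags).  Spatial data adds spot
coordinates (:class:`SpotMatrix`).  All tables move through plain-text
formats: Matrix Market (1-based coordinate) plus ``genes.tsv`` /
``barcodes.tsv`` sidecars, GMT for gene sets, TSV everywhere else.

QC mirrors common droplet practice: cells must have strictly more than
500 detected genes and strictly less than 10% mitochondrial counts
(fractions computed on the raw matrix, before any gene removal);
mitochondrial and ribosomal genes are then dropped.  Spots follow the
"fewer than" rules (< 500 genes per spot, genes present in < 15 spots).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "SpotMatrix",
    "NormMatrix",
    "QCReport",
    "filter_cells_qc",
    "filter_spots_qc",
    "lognormalize",
    "read_gmt",
    "write_gmt",
]

MITO_PREFIXES = ("mt-", "MT-", "Mt-")
RIBO_PREFIXES = ("Rps", "Rpl", "RPS", "RPL", "rps", "rpl")


class EmptyResultError(ValueError):
    """A filter removed every cell/spot or gene; carries the counts."""


def _check_ids(ids: np.ndarray, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class CountMatrix:
    """Sparse non-negative integer cells x genes matrix with identifiers.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` sparse (or dense, converted) count matrix.
    cell_ids, gene_ids
        Unique string identifiers, one per row / column.
    gene_meta
        Optional per-gene frame indexed like ``gene_ids`` with columns
        among ``chromosome`` (str), ``start`` (int, bp), ``is_mito``,
        ``is_ribo`` (bool).  Mito/ribo flags default from name prefixes.
    """

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be non-negative")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.gene_meta is not None:
            self.gene_meta = self.gene_meta.reindex(self.gene_ids)

    # -- convenience -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_flags(self) -> tuple[np.ndarray, np.ndarray]:
        """(is_mito, is_ribo) boolean arrays, from meta or name prefixes."""
        names = pd.Index(self.gene_ids.astype(str))
        if self.gene_meta is not None and "is_mito" in self.gene_meta:
            mito = self.gene_meta["is_mito"].fillna(False).to_numpy(bool)
        else:
            mito = np.asarray(names.str.startswith(MITO_PREFIXES))
        if self.gene_meta is not None and "is_ribo" in self.gene_meta:
            ribo = self.gene_meta["is_ribo"].fillna(False).to_numpy(bool)
        else:
            ribo = np.asarray(names.str.startswith(RIBO_PREFIXES))
        return mito, ribo

    def subset(self, cells=None, genes=None) -> "CountMatrix":
        """Positional subset; returns a new matrix sharing no state."""
        ci = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        gi = np.arange(self.n_genes) if genes is None else np.asarray(genes)
        meta = self.gene_meta.iloc[gi] if self.gene_meta is not None else None
        return dataclasses.replace(
            self,
            values=self.values[ci][:, gi],
            cell_ids=self.cell_ids[ci],
            gene_ids=self.gene_ids[gi],
            gene_meta=meta,
        )

    # -- I/O ---------------------------------------------------------
    def write(self, outdir: str | Path) -> None:
        """Write MTX (1-based coordinate) + genes.tsv + barcodes.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(self.values), field="integer")
        pd.Series(self.cell_ids).to_csv(
            outdir / "barcodes.tsv", sep="\t", index=False, header=False
        )
        genes = pd.DataFrame({"gene_id": self.gene_ids})
        if self.gene_meta is not None:
            for col in ("chromosome", "start"):
                if col in self.gene_meta:
                    genes[col] = self.gene_meta[col].to_numpy()
        genes.to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)

    @classmethod
    def read(cls, indir: str | Path) -> "CountMatrix":
        indir = Path(indir)
        values = sp.csr_matrix(mmread(str(indir / "matrix.mtx")))
        cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].to_numpy(object)
        genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)
        meta = None
        if genes.shape[1] >= 3:
            meta = pd.DataFrame(
                {"chromosome": genes[1].to_numpy(), "start": genes[2].to_numpy(int)},
                index=genes[0].to_numpy(object),
            )
        return cls(values, cells, genes[0].to_numpy(object), meta)


@dataclass
class SpotMatrix(CountMatrix):
    """Counts over multi-cell capture spots, with grid coordinates.

    ``coordinates`` is a frame indexed by spot id with columns ``x``,
    ``y`` and optionally ``layer`` (anatomical band label).
    """

    coordinates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.coordinates):
            self.coordinates = self.coordinates.reindex(self.cell_ids)
            if not np.isfinite(self.coordinates[["x", "y"]].to_numpy(float)).all():
                raise ValueError("spot coordinates must be finite")

    @property
    def spot_ids(self) -> np.ndarray:
        return self.cell_ids

    def subset(self, cells=None, genes=None) -> "SpotMatrix":
        out = super().subset(cells, genes)
        out.coordinates = self.coordinates.reindex(out.cell_ids)
        return out

    def write(self, outdir: str | Path) -> None:
        super().write(outdir)
        coords = self.coordinates.copy()
        coords.insert(0, "spot_id", coords.index)
        coords.to_csv(Path(outdir) / "coordinates.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, indir: str | Path) -> "SpotMatrix":
        base = CountMatrix.read(indir)
        coords = pd.read_csv(Path(indir) / "coordinates.tsv", sep="\t").set_index("spot_id")
        return cls(base.values, base.cell_ids, base.gene_ids, base.gene_meta, coords)


@dataclass
class NormMatrix:
    """ln(1 + count * scale / cell_total) expression, rows = cells."""

    values: sp.csr_matrix | np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    scale: float = 1e4
    source: CountMatrix | None = None

    def __post_init__(self) -> None:
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.gene_ids = _check_ids(self.gene_ids, "gene")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        idx = pd.Index(self.gene_ids)
        pos = idx.get_indexer(list(genes))
        return pos

    def subset_genes(self, genes: Sequence[str]) -> "NormMatrix":
        pos = self.gene_index(genes)
        if (pos < 0).any():
            missing = [g for g, p in zip(genes, pos) if p < 0]
            raise KeyError(f"genes not present: {missing[:5]}...")
        return NormMatrix(
            self.values[:, pos] if sp.issparse(self.values) else self.values[:, pos],
            self.cell_ids,
            np.asarray(list(genes), dtype=object),
            self.scale,
        )


@dataclass
class QCReport:
    """Counts of what a QC filter removed and why."""

    n_cells_in: int
    n_cells_out: int
    removed_low_genes: int
    removed_high_mito: int
    n_genes_in: int
    n_genes_out: int
    removed_mito_ribo_genes: int = 0
    removed_low_detection_genes: int = 0

    def __str__(self) -> str:  # pragma: no cover - logging convenience
        return (
            f"cells {self.n_cells_in} -> {self.n_cells_out} "
            f"(low-gene {self.removed_low_genes}, high-mito {self.removed_high_mito}); "
            f"genes {self.n_genes_in} -> {self.n_genes_out}"
        )


def _detected_genes_per_cell(values: sp.csr_matrix) -> np.ndarray:
    return np.asarray((values > 0).sum(axis=1)).ravel()


def _mito_fraction(m: CountMatrix) -> np.ndarray:
    mito, _ = m.gene_flags()
    totals = np.asarray(m.values.sum(axis=1)).ravel().astype(float)
    mito_counts = np.asarray(m.values[:, mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)
    return frac


def filter_cells_qc(
    m: CountMatrix,
    min_genes: int = 500,
    max_mito_frac: float = 0.10,
    drop_mito_ribo: bool = True,
) -> tuple[CountMatrix, QCReport]:
    """Retain cells with > ``min_genes`` detected genes and < ``max_mito_frac``
    mitochondrial fraction, then drop mito/ribo gene columns.

    Both inequalities are strict, and the mito fraction is computed on the
    raw matrix before any gene removal.  Returns the filtered matrix and a
    :class:`QCReport`.
    """
    detected = _detected_genes_per_cell(m.values)
    mito_frac = _mito_fraction(m)
    keep_genes_rule = detected > min_genes
    keep_mito_rule = mito_frac < max_mito_frac
    keep = keep_genes_rule & keep_mito_rule
    report = QCReport(
        n_cells_in=m.n_cells,
        n_cells_out=int(keep.sum()),
        removed_low_genes=int((~keep_genes_rule).sum()),
        removed_high_mito=int((keep_genes_rule & ~keep_mito_rule).sum()),
        n_genes_in=m.n_genes,
        n_genes_out=m.n_genes,
    )
    if not keep.any():
        raise EmptyResultError(f"no cells pass QC: {report}")
    out = m.subset(cells=np.flatnonzero(keep))
    if drop_mito_ribo:
        mito, ribo = out.gene_flags()
        gene_keep = ~(mito | ribo)
        report.removed_mito_ribo_genes = int((~gene_keep).sum())
        out = out.subset(genes=np.flatnonzero(gene_keep))
    report.n_genes_out = out.n_genes
    return out, report


def filter_spots_qc(
    m: SpotMatrix,
    min_genes: int = 500,
    min_spots_per_gene: int = 15,
    max_mito_frac: float = 0.10,
) -> tuple[SpotMatrix, QCReport]:
    """Drop spots with fewer than ``min_genes`` detected genes or more than
    ``max_mito_frac`` mitochondrial expression, then drop genes expressed
    in fewer than ``min_spots_per_gene`` of the surviving spots.

    Spot rules are "fewer than" (strict <); spots are filtered before
    genes, so gene detection counts refer to the spot-filtered matrix.
    """
    detected = _detected_genes_per_cell(m.values)
    mito_frac = _mito_fraction(m)
    keep_genes_rule = detected >= min_genes  # "fewer than 500" removed
    keep_mito_rule = mito_frac <= max_mito_frac  # "over 10%" removed
    keep = keep_genes_rule & keep_mito_rule
    report = QCReport(
        n_cells_in=m.n_cells,
        n_cells_out=int(keep.sum()),
        removed_low_genes=int((~keep_genes_rule).sum()),
        removed_high_mito=int((keep_genes_rule & ~keep_mito_rule).sum()),
        n_genes_in=m.n_genes,
        n_genes_out=m.n_genes,
    )
    if not keep.any():
        raise EmptyResultError(f"no spots pass QC: {report}")
    out = m.subset(cells=np.flatnonzero(keep))
    gene_detect = np.asarray((out.values > 0).sum(axis=0)).ravel()
    gene_keep = gene_detect >= min_spots_per_gene
    report.removed_low_detection_genes = int((~gene_keep).sum())
    if not gene_keep.any():
        raise EmptyResultError(f"no genes pass QC: {report}")
    out = out.subset(genes=np.flatnonzero(gene_keep))
    report.n_genes_out = out.n_genes
    return out, report


def lognormalize(m: CountMatrix | SpotMatrix, scale: float = 1e4) -> NormMatrix:
    """Library-size normalize to ``scale`` counts per cell and log-transform.

    entry = ln(1 + c * scale / cell_total).  Zero counts stay exactly zero,
    so the sparsity pattern is preserved.
    """
    totals = np.asarray(m.values.sum(axis=1)).ravel().astype(float)
    if (totals <= 0).any():
        bad = m.cell_ids[totals <= 0][:5]
        raise ValueError(f"all-zero rows cannot be normalized: {list(bad)}")
    x = sp.csr_matrix(m.values, dtype=float)
    row_scale = scale / totals
    x.data *= np.repeat(row_scale, np.diff(x.indptr))
    np.log1p(x.data, out=x.data)
    return NormMatrix(x, m.cell_ids, m.gene_ids, scale=scale, source=m)


# -- gene-set (GMT) I/O ----------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into {set name: ordered gene list}."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        name, genes = parts[0], [g for g in parts[2:] if g]
        sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + [str(g) for g in genes])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
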