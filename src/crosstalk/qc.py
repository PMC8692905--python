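"""Quality control and normalization of UMI count matrices.

Implements the filtering and normalization conventions common to
droplet/well-based single-cell studies of the aortic wall:

* cells are kept when their log10 total UMI lies within a symmetric
  standard-deviation window around the population mean and they detect a
  minimum number of genes;
* genes are kept when detected in a minimum number of cells, with
  mitochondrial genes removed by name convention;
* counts are scaled to a fixed per-cell size factor of 10,000
  ("TPM-like" values) and transformed with the natural logarithm.

Matrices are gene-major (genes x cells) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("crosstalk")

SIZE_FACTOR = 10_000.0

CONDITIONS = ("nonAD", "AD")


def _as_str_array(ids: Sequence[str]) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if len(set(arr)) != len(arr):
        raise ValueError("identifiers must be unique")
    return arr


@dataclass
class CountMatrix:
    """Raw UMI counts (genes x cells) with per-cell and per-gene metadata.

    ``cell_meta`` is indexed by cell id and carries ``donor``,
    ``condition`` (one of ``nonAD``/``AD``) and optionally ``cluster``.
    ``gene_flags`` is indexed by gene id and carries ``is_mito``.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    gene_flags: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional (genes x cells)")
        if np.any(self.values < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.floor(self.values)):
                raise ValueError("counts must be integers")
            self.values = self.values.astype(np.int64)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match gene/cell ids")
        self.cell_meta = self.cell_meta.reindex(self.cell_ids)
        self.gene_flags = self.gene_flags.reindex(self.gene_ids)
        if "is_mito" not in self.gene_flags.columns:
            self.gene_flags["is_mito"] = False
        self.gene_flags["is_mito"] = self.gene_flags["is_mito"].fillna(False).astype(bool)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def total_umis(self) -> np.ndarray:
        """Per-cell total UMI counts."""
        return self.values.sum(axis=0)

    def detected_genes_per_cell(self) -> np.ndarray:
        return (self.values > 0).sum(axis=0)

    def cells_per_gene(self) -> np.ndarray:
        return (self.values > 0).sum(axis=1)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.values[:, mask],
            self.gene_ids,
            self.cell_ids[mask],
            self.cell_meta.loc[self.cell_ids[mask]],
            self.gene_flags,
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.values[mask, :],
            self.gene_ids[mask],
            self.cell_ids,
            self.cell_meta,
            self.gene_flags.loc[self.gene_ids[mask]],
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.values.T.copy(),
            obs=self.cell_meta.copy(),
            var=self.gene_flags.copy(),
        )


@dataclass
class FilterReport:
    """Audit record of one filtering pass."""

    kind: str
    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removed_cell_ids: list = field(default_factory=list)
    removed_gene_ids: list = field(default_factory=list)
    umi_bounds: Optional[tuple] = None
    min_genes_per_cell: Optional[int] = None
    min_cells_per_gene: Optional[int] = None
    drop_mito: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.n_cells_out != self.n_cells_in - len(self.removed_cell_ids):
            raise ValueError("cell bookkeeping inconsistent")
        if self.n_genes_out != self.n_genes_in - len(self.removed_gene_ids):
            raise ValueError("gene bookkeeping inconsistent")

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "n_cells_in": int(self.n_cells_in),
            "n_cells_out": int(self.n_cells_out),
            "n_genes_in": int(self.n_genes_in),
            "n_genes_out": int(self.n_genes_out),
            "removed_cell_ids": [str(c) for c in self.removed_cell_ids],
            "removed_gene_ids": [str(g) for g in self.removed_gene_ids],
        }
        if self.umi_bounds is not None:
            d["umi_bounds_log10"] = [float(b) for b in self.umi_bounds]
        for key in ("min_genes_per_cell", "min_cells_per_gene", "drop_mito"):
            v = getattr(self, key)
            if v is not None:
                d[key] = v
        return d


@dataclass
class NormalizedMatrix:
    """Natural-log, size-factor-10,000 normalized expression (genes x cells).

    Satisfies, for every cell, ``sum_genes(exp(v) - 1) == size_factor``
    because values are ``ln(count / total * size_factor + 1)``.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    size_factor: float = SIZE_FACTOR
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match gene/cell ids")
        self.cell_meta = self.cell_meta.reindex(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def cell_index(self, cells: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array([lookup[c] for c in cells], dtype=int)

    def subset_cells(self, cells: Sequence[str]) -> "NormalizedMatrix":
        idx = self.cell_index(cells)
        return NormalizedMatrix(
            self.values[:, idx],
            self.gene_ids,
            self.cell_ids[idx],
            self.cell_meta.iloc[idx],
            self.size_factor,
            list(self.provenance),
        )


def filter_cells(
    m: CountMatrix, sd_window: float = 2.0, min_genes: int = 1000
) -> tuple[CountMatrix, FilterReport]:
    """Keep cells inside the log10-UMI window and above the gene floor.

    A cell is retained when its log10 total UMI lies within
    ``mean +/- sd_window * sd`` (sample s.d., inclusive bounds, both
    statistics computed once over all input cells) AND it detects at
    least ``min_genes`` genes (count > 0).
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValueError("cannot filter an empty matrix")
    totals = m.total_umis()
    zero = totals == 0
    if np.any(zero):
        bad = ", ".join(map(str, m.cell_ids[zero][:5]))
        raise ValueError(f"cells with zero total UMI (log10 undefined): {bad}")
    log_totals = np.log10(totals.astype(float))
    mean = log_totals.mean()
    sd = log_totals.std(ddof=1) if m.n_cells > 1 else 0.0
    lo, hi = mean - sd_window * sd, mean + sd_window * sd
    detected = m.detected_genes_per_cell()
    keep = (log_totals >= lo) & (log_totals <= hi) & (detected >= min_genes)
    report = FilterReport(
        kind="filter_cells",
        n_cells_in=m.n_cells,
        n_cells_out=int(keep.sum()),
        n_genes_in=m.n_genes,
        n_genes_out=m.n_genes,
        removed_cell_ids=list(m.cell_ids[~keep]),
        umi_bounds=(float(lo), float(hi)),
        min_genes_per_cell=int(min_genes),
    )
    logger.info(
        "filter_cells: kept %d/%d cells (log10 UMI window [%.4f, %.4f], min_genes=%d)",
        report.n_cells_out, report.n_cells_in, lo, hi, min_genes,
    )
    return m.subset_cells(keep), report


def filter_genes(
    m: CountMatrix, min_cells: int = 10, drop_mito: bool = True
) -> tuple[CountMatrix, FilterReport]:
    """Keep genes detected in at least ``min_cells`` cells; drop mito genes.

    Mitochondrial genes (flagged ``is_mito``) are removed regardless of
    prevalence when ``drop_mito`` is true.
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValueError("cannot filter an empty matrix")
    prevalence = m.cells_per_gene()
    keep = prevalence >= min_cells
    if drop_mito:
        keep &= ~m.gene_flags["is_mito"].to_numpy()
    report = FilterReport(
        kind="filter_genes",
        n_cells_in=m.n_cells,
        n_cells_out=m.n_cells,
        n_genes_in=m.n_genes,
        n_genes_out=int(keep.sum()),
        removed_gene_ids=list(m.gene_ids[~keep]),
        min_cells_per_gene=int(min_cells),
        drop_mito=bool(drop_mito),
    )
    logger.info(
        "filter_genes: kept %d/%d genes (min_cells=%d, drop_mito=%s)",
        report.n_genes_out, report.n_genes_in, min_cells, drop_mito,
    )
    return m.subset_genes(keep), report


def flag_mito_genes(m: CountMatrix, prefix: str = "MT-") -> CountMatrix:
    """Set ``is_mito`` by gene-name prefix (default ``MT-``)."""
    flags = m.gene_flags.copy()
    flags["is_mito"] = pd.Index(m.gene_ids).str.startswith(prefix)
    return replace(m, gene_flags=flags)


def normalize(m: CountMatrix, provenance: Optional[list] = None) -> NormalizedMatrix:
    """Size-factor-10,000 normalization followed by natural log.

    ``v(g, c) = ln(count(g, c) / total(c) * 10000 + 1)``; totals are
    computed over the genes present in ``m`` (i.e. after gene filtering),
    so per-cell conservation ``sum(exp(v) - 1) == 10000`` is exact. The
    ``+1`` pseudocount keeps zero counts at exactly 0.
    """
    totals = m.total_umis().astype(float)
    zero = totals == 0
    if np.any(zero):
        bad = ", ".join(map(str, m.cell_ids[zero][:5]))
        raise ValueError(f"cells with zero total UMI cannot be normalized: {bad}")
    values = np.log1p(m.values / totals[None, :] * SIZE_FACTOR)
    return NormalizedMatrix(
        values=values,
        gene_ids=m.gene_ids,
        cell_ids=m.cell_ids,
        cell_meta=m.cell_meta,
        size_factor=SIZE_FACTOR,
        provenance=list(provenance or []),
    )


def select_variable_genes(
    nm: NormalizedMatrix,
    mean_low: float = 0.01,
    mean_high: float = 3.0,
    min_dispersion: float = 1.0,
) -> list[str]:
    """Variable genes by log-mean bounds and natural-scale dispersion.

    Keeps genes with ``mean_low <= mean(v) <= mean_high`` (v on the log
    scale) and dispersion strictly greater than ``min_dispersion``, where
    dispersion is variance/mean of the de-logged ``exp(v) - 1`` values.
    Genes with zero natural-scale mean have dispersion 0.
    """
    if nm.n_cells == 0 or nm.n_genes == 0:
        raise ValueError("empty matrix")
    log_mean = nm.values.mean(axis=1)
    natural = np.expm1(nm.values)
    nat_mean = natural.mean(axis=1)
    nat_var = natural.var(axis=1, ddof=1) if nm.n_cells > 1 else np.zeros(nm.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(nat_mean > 0, nat_var / nat_mean, 0.0)
    keep = (log_mean >= mean_low) & (log_mean <= mean_high) & (dispersion > min_dispersion)
    return [str(g) for g in nm.gene_ids[keep]]


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r of two 1-D vectors; raises on constant input."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    if denom == 0:
        raise ValueError("constant expression vector: Pearson correlation undefined")
    return float(np.clip((ac * bc).sum() / denom, -1.0, 1.0))


def cell_similarity(
    nm: NormalizedMatrix,
    clusters: Optional[Sequence[str]] = None,
    include_self: bool = True,
) -> pd.Series:
    """Pearson r of each cell to its own cluster's mean expression vector.

    The centroid includes the cell itself by default; ``include_self=False``
    recomputes a leave-one-out centroid (requires clusters of >= 2 cells).
    """
    labels = np.asarray(clusters if clusters is not None else nm.cell_meta["cluster"])
    out = np.empty(nm.n_cells)
    for cl in pd.unique(labels):
        idx = np.flatnonzero(labels == cl)
        if len(idx) < 2:
            raise ValueError(f"cluster {cl!r} has fewer than 2 cells")
        block = nm.values[:, idx]
        centroid = block.mean(axis=1)
        for j, ci in enumerate(idx):
            if include_self:
                ref = centroid
            else:
                ref = (centroid * len(idx) - block[:, j]) / (len(idx) - 1)
            try:
                out[ci] = _pearson_rows(block[:, j], ref)
            except ValueError as exc:
                raise ValueError(f"cell {nm.cell_ids[ci]!r}: {exc}") from None
    return pd.Series(out, index=list(nm.cell_ids), name="similarity")


def cluster_correlation_matrix(
    nm: NormalizedMatrix, groups: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Pearson correlation between per-gene mean vectors of cell groups.

    Groups default to ``condition:cluster`` labels from the metadata. The
    result is symmetric with unit diagonal.
    """
    if groups is None:
        meta = nm.cell_meta
        groups = (meta["condition"].astype(str) + ":" + meta["cluster"].astype(str)).to_numpy()
    labels = np.asarray(groups)
    names = sorted(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    centroids = []
    for name in names:
        idx = np.flatnonzero(labels == name)
        if len(idx) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 cells")
        c = nm.values[:, idx].mean(axis=1)
        if np.ptp(c) == 0:
            raise ValueError(f"group {name!r} has a constant mean vector")
        centroids.append(c)
    corr = np.corrcoef(np.vstack(centroids))
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def standin_cluster(nm: NormalizedMatrix, n_clusters: int, seed: int = 0) -> pd.Series:
    """Plumbing-only clusterer: k-means on the top principal components.

    Provided so the pipeline can run when no cluster labels are supplied;
    it makes no attempt to reproduce any particular clustering method.
    """
    from sklearn.cluster import KMeans

    var_genes = select_variable_genes(nm)
    if len(var_genes) < 2:
        var_genes = [str(g) for g in nm.gene_ids]
    x = nm.values[nm.gene_index(var_genes)].T
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    n_pc = min(10, len(s))
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(u[:, :n_pc] * s[:n_pc])
    return pd.Series([f"K{v}" for v in labels], index=list(nm.cell_ids), name="cluster")
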