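"""Pseudotime ordering, condition-composition states, and GO enrichment.

The ordering is a deliberately simple stand-in for tree-based pseudotime
methods: cells of one lineage are projected on the first principal axis
of their variable-gene submatrix, rank-normalized to [0, 1], and oriented
so non-diseased (nonAD) cells precede diseased (AD) cells on average.
Downstream computations only require an ordering plus a three-segment
partition, and an externally computed pseudotime can be supplied instead.

States follow the cell-source-proportion convention: pseudotime is cut
into three contiguous segments (exact two-cut search minimizing the
cell-count-weighted condition-mixing entropy) and each segment is labeled
``nonAD_enriched`` or ``AD_enriched`` when more than ``enrich_threshold``
of its cells come from one condition, else ``transition``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from .annotation import GeneTermAnnotation
from .markers import _group_p_values, bh_adjust
from .qc import NormalizedMatrix, select_variable_genes

logger = logging.getLogger("crosstalk")

STATES = ("nonAD_enriched", "transition", "AD_enriched")

ENRICHMENT_COLUMNS = ["term", "k", "K", "n", "N", "p", "q"]


@dataclass
class TrajectoryAssignment:
    """Per-cell pseudotime and three-level state with segment boundaries."""

    assignments: pd.DataFrame  # index: cell_id; columns: pseudotime, state
    boundaries: tuple[float, float]

    def __post_init__(self) -> None:
        bad = set(self.assignments["state"]) - set(STATES)
        if bad:
            raise ValueError(f"unknown states: {sorted(bad)}")

    @property
    def cells(self) -> list[str]:
        return list(self.assignments.index)

    def cells_in_state(self, state: str) -> list[str]:
        return list(self.assignments.index[self.assignments["state"] == state])

    def state_counts(self) -> pd.Series:
        return self.assignments["state"].value_counts().reindex(STATES, fill_value=0)

    def to_frame(self) -> pd.DataFrame:
        df = self.assignments.reset_index()
        df.columns = ["cell_id", "pseudotime", "state"]
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TrajectoryAssignment":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("cell_id")
        pt = df.sort_values("pseudotime")
        cuts = []
        states = pt["state"].to_numpy()
        for i in range(1, len(pt)):
            if states[i] != states[i - 1]:
                cuts.append((pt["pseudotime"].iloc[i - 1] + pt["pseudotime"].iloc[i]) / 2.0)
        while len(cuts) < 2:
            cuts.append(float(pt["pseudotime"].iloc[-1]))
        return cls(df[["pseudotime", "state"]], (float(cuts[0]), float(cuts[1])))


def order_cells(
    nm: NormalizedMatrix,
    cells: Optional[Sequence[str]] = None,
    var_genes: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Stand-in pseudotime for one lineage.

    Rank-normalized projection on the first principal axis of the
    variable-gene submatrix, scaled to [0, 1] and oriented so that the
    mean pseudotime of nonAD cells does not exceed that of AD cells.
    """
    sub = nm.subset_cells(list(cells)) if cells is not None else nm
    if sub.n_cells < 10:
        raise ValueError("need at least 10 cells to order")
    if var_genes is None:
        var_genes = select_variable_genes(sub)
    if len(var_genes) < 2:
        raise ValueError("need at least 2 variable genes")
    x = sub.values[sub.gene_index(var_genes)].T  # cells x genes
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    proj = u[:, 0] * s[0]
    ranks = rankdata(proj)
    if ranks.max() == ranks.min():
        pt = np.zeros(sub.n_cells)
    else:
        pt = (ranks - ranks.min()) / (ranks.max() - ranks.min())
    cond = sub.cell_meta["condition"].to_numpy()
    mean_non = pt[cond == "nonAD"].mean() if np.any(cond == "nonAD") else 0.0
    mean_ad = pt[cond == "AD"].mean() if np.any(cond == "AD") else 1.0
    if mean_non > mean_ad:
        pt = 1.0 - pt
    return pd.Series(pt, index=list(sub.cell_ids), name="pseudotime")


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(p * np.log(p) + (1 - p) * np.log(1 - p))
    return np.where((p <= 0) | (p >= 1), 0.0, h)


def assign_states(
    pseudotime: pd.Series,
    conditions: pd.Series,
    enrich_threshold: float = 0.6,
) -> TrajectoryAssignment:
    """Partition a pseudotime ordering into three condition-composition states.

    Performs an exact search over all two-cut segmentations of the cells
    sorted by pseudotime (ties broken by cell id), minimizing the
    size-weighted binary entropy of the condition mix within segments,
    then labels each segment by its majority-condition proportion. The
    result depends on pseudotime only through the ordering, so it is
    invariant to monotone transforms.
    """
    cells = np.asarray(pseudotime.index, dtype=object)
    pt = pseudotime.to_numpy(dtype=float)
    cond = conditions.reindex(pseudotime.index).to_numpy()
    if len(cells) < 3:
        raise ValueError("need at least 3 cells")
    present = set(cond)
    if not {"nonAD", "AD"} <= present:
        raise ValueError("both conditions (nonAD, AD) must be present")
    order = np.lexsort((cells, pt))
    is_ad = (cond[order] == "AD").astype(int)
    n = len(cells)
    cum = np.concatenate([[0], np.cumsum(is_ad)])

    def seg_cost(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        size = b - a
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(size > 0, (cum[b] - cum[a]) / np.maximum(size, 1), 0.0)
        return size / n * _binary_entropy(frac)

    i_idx = np.arange(1, n - 1)  # first cut: segment 1 is [0, i)
    j_idx = np.arange(2, n)  # second cut: segment 2 is [i, j), segment 3 [j, n)
    left = seg_cost(np.zeros_like(i_idx), i_idx)
    right = seg_cost(j_idx, np.full_like(j_idx, n))
    mid = seg_cost(i_idx[:, None], j_idx[None, :])
    total = left[:, None] + mid + right[None, :]
    total[i_idx[:, None] >= j_idx[None, :]] = np.inf
    flat = int(np.argmin(total))
    i = i_idx[flat // len(j_idx)]
    j = j_idx[flat % len(j_idx)]

    states_sorted = np.empty(n, dtype=object)
    for lo, hi in ((0, i), (i, j), (j, n)):
        size = hi - lo
        frac_ad = (cum[hi] - cum[lo]) / size
        if 1 - frac_ad > enrich_threshold:
            label = "nonAD_enriched"
        elif frac_ad > enrich_threshold:
            label = "AD_enriched"
        else:
            label = "transition"
        states_sorted[lo:hi] = label

    pt_sorted = pt[order]
    b1 = float((pt_sorted[i - 1] + pt_sorted[i]) / 2.0)
    b2 = float((pt_sorted[j - 1] + pt_sorted[j]) / 2.0)
    df = pd.DataFrame(
        {"pseudotime": pt_sorted, "state": states_sorted},
        index=pd.Index(cells[order], name="cell_id"),
    )
    return TrajectoryAssignment(df.loc[list(cells)], (b1, b2))


@dataclass
class StateDEGs:
    """Top trajectory DEGs with their peak-state block assignment."""

    table: pd.DataFrame  # columns: gene, p, state

    @property
    def blocks(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {s: [] for s in STATES}
        for gene, state in zip(self.table["gene"], self.table["state"]):
            out[state].append(gene)
        return out


def state_degs(
    nm: NormalizedMatrix, traj: TrajectoryAssignment, top_n: int = 1000
) -> StateDEGs:
    """Screen genes varying across the three states; assign by peak mean.

    Each gene is tested one-state-vs-rest with the rank-sum test over the
    three state groups; genes are ranked by their minimum p, the ``top_n``
    best kept (constant genes, p = 1, are never selected), and each is
    assigned to the state where its mean expression is maximal.
    """
    sub = nm.subset_cells(traj.cells)
    labels = traj.assignments.reindex(sub.cell_ids)["state"].to_numpy()
    for s in STATES:
        if (labels == s).sum() < 3:
            raise ValueError(f"state {s!r} has fewer than 3 cells")
    from .markers import _tie_terms_rows  # local import to avoid cycle noise
    from scipy.stats import rankdata as _rankdata

    ranks = _rankdata(sub.values, axis=1)
    tie_terms = _tie_terms_rows(sub.values)
    p_min = np.ones(sub.n_genes)
    means = np.empty((len(STATES), sub.n_genes))
    for si, s in enumerate(STATES):
        mask = labels == s
        p = _group_p_values(sub.values, mask, ranks, tie_terms)
        p_min = np.minimum(p_min, p)
        means[si] = sub.values[:, mask].mean(axis=1)
    testable = p_min < 1.0
    order = np.lexsort((sub.gene_ids.astype(str), p_min))
    order = order[testable[order]][: int(top_n)]
    rows = [
        (str(sub.gene_ids[g]), float(p_min[g]), STATES[int(np.argmax(means[:, g]))])
        for g in order
    ]
    return StateDEGs(pd.DataFrame(rows, columns=["gene", "p", "state"]))


def go_enrichment(
    query: Sequence[str],
    annotation: GeneTermAnnotation,
    universe: Sequence[str],
    p_max: float = 0.05,
    return_all: bool = False,
) -> pd.DataFrame:
    """Hypergeometric upper-tail GO-term enrichment of a gene set.

    For every term annotating at least one query gene, computes
    ``p = P(X >= k)`` with X hypergeometric(N=|universe|, K=term size in
    universe, n=|query|), BH-adjusts across the tested terms, and returns
    rows with ``p < p_max`` (all rows when ``return_all``).
    """
    query_set = {str(g) for g in query}
    universe_set = {str(g) for g in universe}
    if not query_set <= universe_set:
        missing = sorted(query_set - universe_set)[:5]
        raise ValueError(f"query genes outside the universe: {missing}")
    n = len(query_set)
    big_n = len(universe_set)
    term_to_k: dict[str, int] = {}
    term_to_big_k: dict[str, int] = {}
    for g in universe_set:
        for t in annotation.terms_for(g):
            term_to_big_k[t] = term_to_big_k.get(t, 0) + 1
            if g in query_set:
                term_to_k[t] = term_to_k.get(t, 0) + 1
    terms = sorted(term_to_k)
    if not terms:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    ks = np.array([term_to_k[t] for t in terms])
    big_ks = np.array([term_to_big_k[t] for t in terms])
    p = hypergeom.sf(ks - 1, big_n, big_ks, n)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    q = bh_adjust(p)
    df = pd.DataFrame(
        {"term": terms, "k": ks, "K": big_ks, "n": n, "N": big_n, "p": p, "q": q}
    ).sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    if return_all:
        return df
    return df[df["p"] < p_max].reset_index(drop=True)
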