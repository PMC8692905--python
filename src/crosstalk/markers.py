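"""Marker and differential-expression detection.

One-vs-rest and two-group comparisons use a Wilcoxon-Mann-Whitney
rank-sum test implemented here: exact permutation enumeration for small
samples (total n <= 12) and a tie-corrected, continuity-corrected normal
approximation otherwise. Multiple testing is controlled per gene family
with Benjamini-Hochberg step-up q-values, thresholded at q <= 0.05 by
convention.

Log fold changes are differences of mean natural-log normalized values
(``mean_in - mean_out``), the scale on which the 0.58 bulk-RNA threshold
(`BULK_LOG_FC_THRESHOLD`, exposed for reference, not used here) is quoted.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .qc import NormalizedMatrix

logger = logging.getLogger("crosstalk")

EXACT_MAX_N = 12
BULK_LOG_FC_THRESHOLD = 0.58  # |logFC| cutoff quoted for bulk DE; reference constant

MARKER_COLUMNS = ["gene", "group", "log_fc", "p", "q", "mean_in", "mean_out"]

_EPS = 1e-9


def _rank_sum_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for the rank-sum statistic.

    Enumerates all C(n, nx) assignments of the pooled midranks and doubles
    the smaller tail (including the observed value), capped at 1.
    """
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    observed = ranks[:nx].sum()
    lo = hi = total = 0
    for combo in combinations(range(len(pooled)), nx):
        w = ranks[list(combo)].sum()
        total += 1
        if w <= observed + _EPS:
            lo += 1
        if w >= observed - _EPS:
            hi += 1
    p = min(1.0, 2.0 * min(lo, hi) / total)
    u = observed - nx * (nx + 1) / 2.0
    return float(u), float(p)


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of a pooled sample."""
    _, counts = np.unique(values, return_counts=True)
    counts = counts.astype(float)
    return float(np.sum(counts**3 - counts))


def _rank_sum_normal(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Normal-approximation two-sided p with tie and continuity correction."""
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rank_sum = ranks[:nx].sum()
    u = rank_sum - nx * (nx + 1) / 2.0
    p = _normal_p(np.array([rank_sum]), nx, n, np.array([_tie_term(pooled)]))[0]
    return float(u), float(p)


def _normal_p(rank_sum_x: np.ndarray, nx: int, n: int, tie_terms: np.ndarray) -> np.ndarray:
    """Vectorized two-sided normal-approximation p from in-group rank sums."""
    ny = n - nx
    u = rank_sum_x - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    var = nx * ny / 12.0 * ((n + 1) - tie_terms / (n * (n - 1)))
    var = np.maximum(var, 0.0)
    sigma = np.sqrt(var)
    diff = u - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (diff - 0.5 * np.sign(diff)) / sigma
    p = np.where(sigma > 0, 2.0 * norm.sf(np.abs(z)), 1.0)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney test of two independent samples.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x`` and
    p is two-sided. Uses exact permutation enumeration when the pooled
    sample size is at most 12, and a tie-corrected, continuity-corrected
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if x.size + y.size <= EXACT_MAX_N:
        return _rank_sum_exact(x, y)
    return _rank_sum_normal(x, y)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j``, capped at 1. Inputs must lie
    in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _tie_terms_rows(values: np.ndarray) -> np.ndarray:
    """Per-row sum of t^3 - t over tie groups (rows are genes)."""
    out = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        out[i] = _tie_term(values[i])
    return out


def _group_p_values(
    values: np.ndarray,
    mask: np.ndarray,
    ranks: Optional[np.ndarray] = None,
    tie_terms: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-gene two-sided rank-sum p for group (mask) vs rest.

    Small pooled samples fall back to the exact path gene by gene so the
    scalar and matrix interfaces agree.
    """
    n = values.shape[1]
    nx = int(mask.sum())
    if n <= EXACT_MAX_N:
        return np.array(
            [rank_sum_test(values[g, mask], values[g, ~mask])[1] for g in range(values.shape[0])]
        )
    if ranks is None:
        ranks = rankdata(values, axis=1)
    if tie_terms is None:
        tie_terms = _tie_terms_rows(values)
    rank_sums = ranks[:, mask].sum(axis=1)
    return _normal_p(rank_sums, nx, n, tie_terms)


def find_all_markers(
    nm: NormalizedMatrix,
    clusters: Optional[Sequence[str]] = None,
    q_max: float = 0.05,
    min_log_fc: float = 0.0,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """One-vs-rest positive markers per cluster.

    For each cluster with at least ``min_cluster_size`` cells, every gene
    is tested cluster-vs-rest with the rank-sum test; q-values are BH
    adjusted within the cluster's gene family; rows with ``q <= q_max``
    and ``log_fc > min_log_fc`` are kept. Undersized clusters are skipped
    with a warning.
    """
    labels = np.asarray(clusters if clusters is not None else nm.cell_meta["cluster"])
    names = sorted(str(v) for v in pd.unique(labels[~pd.isna(labels)]))
    if len(names) < 2:
        raise ValueError("need at least 2 clusters")
    ranks = rankdata(nm.values, axis=1) if nm.n_cells > EXACT_MAX_N else None
    tie_terms = _tie_terms_rows(nm.values) if nm.n_cells > EXACT_MAX_N else None
    rows = []
    for name in names:
        mask = labels.astype(str) == name
        if mask.sum() < min_cluster_size:
            logger.warning(
                "find_all_markers: cluster %r has %d cells (< %d), skipped",
                name, int(mask.sum()), min_cluster_size,
            )
            continue
        p = _group_p_values(nm.values, mask, ranks, tie_terms)
        q = bh_adjust(p)
        mean_in = nm.values[:, mask].mean(axis=1)
        mean_out = nm.values[:, ~mask].mean(axis=1)
        log_fc = mean_in - mean_out
        keep = (q <= q_max) & (log_fc > min_log_fc)
        for g in np.flatnonzero(keep):
            rows.append(
                (str(nm.gene_ids[g]), name, log_fc[g], p[g], q[g], mean_in[g], mean_out[g])
            )
    table = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    return table.sort_values(["group", "q", "p", "gene"], kind="stable").reset_index(drop=True)


def find_markers_between(
    nm: NormalizedMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    q_max: float = 0.05,
    label: str = "A_vs_B",
) -> pd.DataFrame:
    """Differential genes between two disjoint cell groups.

    Positive ``log_fc`` means higher in ``group_a``. Both signs are
    retained (``q <= q_max``); use :func:`count_degs` for up/down tallies.
    """
    a = list(group_a)
    b = list(group_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least 3 cells")
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"groups overlap in {len(overlap)} cells")
    idx = nm.cell_index(a + b)
    values = nm.values[:, idx]
    mask = np.zeros(len(idx), dtype=bool)
    mask[: len(a)] = True
    p = _group_p_values(values, mask)
    q = bh_adjust(p)
    mean_in = values[:, mask].mean(axis=1)
    mean_out = values[:, ~mask].mean(axis=1)
    log_fc = mean_in - mean_out
    keep = q <= q_max
    rows = [
        (str(nm.gene_ids[g]), label, log_fc[g], p[g], q[g], mean_in[g], mean_out[g])
        for g in np.flatnonzero(keep)
    ]
    table = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    return table.sort_values(["q", "p", "gene"], kind="stable").reset_index(drop=True)


def count_degs(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Tally up/down/total DEGs per contrast from `find_markers_between` output."""
    rows = []
    for name in sorted(tables):
        t = tables[name]
        n_up = int((t["log_fc"] > 0).sum()) if len(t) else 0
        n_down = int((t["log_fc"] < 0).sum()) if len(t) else 0
        rows.append((name, n_up, n_down, n_up + n_down))
    return pd.DataFrame(rows, columns=["group", "n_up", "n_down", "n_total"])
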