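"""Ligand-receptor interactome scoring between condition-split cell groups.

The core quantities:

* per-group **ligand sets** — positive cluster markers intersected with
  the secreted-gene set of a ligand-receptor database;
* **secreting capacity** — for each group, the sum over its own specific
  ligands of that gene's across-group z-scored mean expression;
* **cross-match** — a ligand of a group is kept for a trajectory state
  when its GO terms intersect the state's enriched terms;
* **interaction score** — product of the ligand's mean expression in the
  sender group and the receptor's mean expression in the receiver group
  (means of natural-log normalized values).

Groups are typically ``n-<cluster>`` / ``d-<cluster>`` condition splits
(nonAD / AD), built with :func:`condition_split`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneTermAnnotation
from .qc import NormalizedMatrix

logger = logging.getLogger("crosstalk")

SCORE_COLUMNS = ["sender", "receiver", "ligand", "receptor", "score"]


@dataclass(frozen=True)
class LigandReceptorDB:
    """Secreted-gene set, receptor-gene set, and directed ligand->receptor pairs."""

    secreted_genes: frozenset
    receptor_genes: frozenset
    pairs: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "secreted_genes", frozenset(map(str, self.secreted_genes)))
        object.__setattr__(self, "receptor_genes", frozenset(map(str, self.receptor_genes)))
        pairs = tuple((str(a), str(b)) for a, b in self.pairs)
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate ligand-receptor pairs")
        for lig, rec in pairs:
            if lig not in self.secreted_genes:
                raise ValueError(f"pair ligand {lig!r} not in secreted set")
            if rec not in self.receptor_genes:
                raise ValueError(f"pair receptor {rec!r} not in receptor set")
        object.__setattr__(self, "pairs", pairs)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def condition_split(
    cell_meta: pd.DataFrame, min_cells: int = 10
) -> pd.Series:
    """Label every cell ``n-<cluster>`` (nonAD) or ``d-<cluster>`` (AD).

    Groups smaller than ``min_cells`` are dropped (label None) with a
    warning, mirroring the practice of scoring only adequately sampled
    condition-split clusters.
    """
    prefix = cell_meta["condition"].map({"nonAD": "n-", "AD": "d-"})
    if prefix.isna().any():
        raise ValueError("condition labels must be 'nonAD' or 'AD'")
    labels = prefix + cell_meta["cluster"].astype(str)
    counts = labels.value_counts()
    small = counts[counts < min_cells].index
    for name in small:
        logger.warning("condition_split: group %r has < %d cells, dropped", name, min_cells)
    return labels.where(~labels.isin(small), None)


def extract_cluster_ligands(
    markers: pd.DataFrame, db: LigandReceptorDB
) -> dict[str, frozenset]:
    """Per-group ligand sets: positive markers intersected with secreted genes."""
    if not db.secreted_genes:
        raise ValueError("ligand-receptor database has no secreted genes")
    out: dict[str, frozenset] = {}
    for group, sub in markers.groupby("group"):
        out[str(group)] = frozenset(set(sub["gene"]) & db.secreted_genes)
    return out


def extract_cluster_receptors(
    markers: pd.DataFrame, db: LigandReceptorDB
) -> dict[str, frozenset]:
    """Per-group receptor sets: positive markers intersected with receptor genes."""
    if not db.receptor_genes:
        raise ValueError("ligand-receptor database has no receptor genes")
    out: dict[str, frozenset] = {}
    for group, sub in markers.groupby("group"):
        out[str(group)] = frozenset(set(sub["gene"]) & db.receptor_genes)
    return out


def _group_means(
    nm: NormalizedMatrix, groups: pd.Series
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-group per-gene mean expression; returns (genes x groups frame, masks)."""
    labels = groups.reindex(nm.cell_ids)
    names = sorted(str(g) for g in labels.dropna().unique())
    masks = {name: (labels == name).to_numpy() for name in names}
    cols = {}
    for name in names:
        idx = np.flatnonzero(masks[name])
        sub = nm.values[:, idx]
        # cumulative sum is a strictly left-to-right reduction, so the mean
        # is bit-identical to a plain per-cell accumulation loop
        cols[name] = np.cumsum(sub, axis=1)[:, -1] / len(idx)
    frame = pd.DataFrame(cols, index=list(nm.gene_ids))
    return frame, masks


def secreting_capacity(
    nm: NormalizedMatrix,
    groups: pd.Series,
    ligand_sets: Mapping[str, frozenset],
) -> pd.DataFrame:
    """Rank groups by summed across-group z-scores of their specific ligands.

    For every secreted gene in the union of the ligand sets, its per-group
    mean expression is z-scored across groups (sample s.d.; a zero-s.d.
    gene contributes 0 everywhere); each group's capacity is the sum of
    z-scores over its own specific ligands. Rank 1 is the highest capacity.
    """
    means, _ = _group_means(nm, groups)
    if means.shape[1] < 2:
        raise ValueError("need at least 2 groups")
    union = sorted({g for s in ligand_sets.values() for g in s})
    known = [g for g in union if g in means.index]
    for g in set(union) - set(known):
        logger.warning("secreting_capacity: ligand %r absent from matrix, ignored", g)
    z = pd.DataFrame(0.0, index=known, columns=means.columns)
    if known:
        sub = means.loc[known]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        nz = sd > 0
        z.loc[nz] = sub.loc[nz].sub(mu[nz], axis=0).div(sd[nz], axis=0)
    rows = []
    for group in means.columns:
        ligands = sorted(set(ligand_sets.get(group, frozenset())) & set(known))
        capacity = float(z.loc[ligands, group].sum()) if ligands else 0.0
        rows.append((group, capacity, len(ligands), ",".join(ligands)))
    df = pd.DataFrame(rows, columns=["group", "capacity", "n_ligands", "ligands"])
    df = df.sort_values(["capacity", "group"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


@dataclass
class CrossmatchResult:
    """Ligands kept per (group, trajectory state) by GO-term overlap."""

    records: pd.DataFrame  # columns: group, state, ligand, matched_terms
    counts: pd.DataFrame  # columns: group, state, n_ligands, n_ligand_term_pairs


def crossmatch(
    ligand_sets: Mapping[str, frozenset],
    annotation: GeneTermAnnotation,
    state_terms: Mapping[str, object],
) -> CrossmatchResult:
    """Keep a group's ligand for a state iff its GO terms meet the state's.

    ``state_terms`` maps state name to either a set of enriched terms or
    an enrichment table with a ``term`` column. Both the distinct-ligand
    count and the matched (ligand, term) pair count are reported per
    (group, state). Ligands missing from the annotation contribute no
    terms and are logged.
    """
    term_sets: dict[str, frozenset] = {}
    for state, val in state_terms.items():
        if isinstance(val, pd.DataFrame):
            term_sets[str(state)] = frozenset(map(str, val["term"]))
        else:
            term_sets[str(state)] = frozenset(map(str, val))
    rec_rows, cnt_rows = [], []
    for group in sorted(ligand_sets):
        ligands = sorted(ligand_sets[group])
        for ligand in ligands:
            if ligand not in annotation:
                logger.info("crossmatch: ligand %r has no annotation, treated as term-free", ligand)
        for state in sorted(term_sets):
            n_kept = 0
            n_pairs = 0
            for ligand in ligands:
                matched = sorted(annotation.terms_for(ligand) & term_sets[state])
                if matched:
                    n_kept += 1
                    n_pairs += len(matched)
                    rec_rows.append((group, state, ligand, ";".join(matched)))
            cnt_rows.append((group, state, n_kept, n_pairs))
    records = pd.DataFrame(rec_rows, columns=["group", "state", "ligand", "matched_terms"])
    counts = pd.DataFrame(cnt_rows, columns=["group", "state", "n_ligands", "n_ligand_term_pairs"])
    return CrossmatchResult(records, counts)


def score_lr_pairs(
    nm: NormalizedMatrix,
    groups: pd.Series,
    db: LigandReceptorDB,
    ligand_sets: Mapping[str, frozenset],
    receptor_sets: Mapping[str, frozenset],
    allow_self: bool = False,
) -> pd.DataFrame:
    """Product-of-means interaction scores for eligible database pairs.

    For every database pair (L, R), sender group S with L in S's ligand
    set, and receiver group T with R in T's receptor set, emits
    ``score = mean(L | S cells) * mean(R | T cells)`` on the normalized
    log scale. Self-pairings (S == T) are skipped unless ``allow_self``.
    Database genes absent from the matrix are skipped with a log message.
    """
    means, _ = _group_means(nm, groups)
    gene_set = set(means.index)
    rows = []
    for sender in sorted(ligand_sets):
        if sender not in means.columns:
            continue
        s_ligands = ligand_sets[sender]
        for receiver in sorted(receptor_sets):
            if receiver not in means.columns:
                continue
            if sender == receiver and not allow_self:
                continue
            r_receptors = receptor_sets[receiver]
            for lig, rec in db.pairs:
                if lig not in s_ligands or rec not in r_receptors:
                    continue
                if lig not in gene_set or rec not in gene_set:
                    logger.warning(
                        "score_lr_pairs: pair (%s, %s) has a gene absent from the matrix, skipped",
                        lig, rec,
                    )
                    continue
                score = float(means.at[lig, sender] * means.at[rec, receiver])
                rows.append((sender, receiver, lig, rec, score))
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    return df.sort_values(
        ["score", "sender", "receiver", "ligand", "receptor"],
        ascending=[False, True, True, True, True],
        kind="stable",
    ).reset_index(drop=True)


def count_pairs_per_group(table: pd.DataFrame, min_score: float = 0.0) -> pd.DataFrame:
    """Number of scored pairs above ``min_score`` per (sender, receiver)."""
    if len(table) == 0:
        return pd.DataFrame(columns=["sender", "receiver", "n_pairs"])
    kept = table[table["score"] > min_score]
    counts = (
        kept.groupby(["sender", "receiver"], sort=True)
        .size()
        .reindex(
            pd.MultiIndex.from_frame(table[["sender", "receiver"]].drop_duplicates()),
            fill_value=0,
        )
        .rename("n_pairs")
        .reset_index()
    )
    return counts.sort_values(["sender", "receiver"], kind="stable").reset_index(drop=True)
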