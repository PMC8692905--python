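"""Synthetic multi-donor, two-condition UMI count data with planted structure.

The generator emulates the study design the pipeline targets: several
donors per condition (non-diseased ``nonAD`` vs diseased ``AD``), a
handful of cell clusters including a fibroblast-like sender ("FB2") and
a smooth-muscle-like receiver ("SMC"), and gamma-Poisson (negative
binomial) UMI counts with log-normally distributed library sizes.

Planted, recoverable structure drives every downstream stage:

* per-cluster marker genes, fold-change up-shifted in their home cluster;
* ligand-receptor pairs — the ligand (a secreted gene) is up-shifted only
  in the sender cluster's AD cells, the receptor in all receiver cells;
* a monotone expression program plus three blocks of state genes along a
  latent progression coordinate in the receiver cluster, defining a
  ground-truth three-state partition (nonAD-enriched / transition /
  AD-enriched);
* mitochondrial genes carrying the ``MT-`` prefix;
* a toy GO annotation in which planted ligands share terms with the
  AD-enriched state's planted genes.

Everything is drawn from a single ``numpy`` generator seeded from
``config.seed``, so identical configs give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import GeneTermAnnotation
from .interactome import LigandReceptorDB
from .qc import CountMatrix
from .trajectory import STATES


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults define the reference synthetic conditions used throughout
    the documentation and tests: 4 clusters x 2 conditions x 100 cells,
    1200 genes, 4-fold planted shifts, NB overdispersion 0.5 and a mean
    library size of 5000 UMIs.
    """

    n_clusters: int = 4
    cells_per_cluster_per_condition: int = 100
    n_genes: int = 1200
    n_mito_genes: int = 10
    n_secreted: int = 40
    n_receptors: int = 40
    n_planted_pairs: int = 5
    marker_fold_change: float = 4.0
    library_size_mean: float = 5000.0
    dispersion: float = 0.5
    n_donors_per_condition: int = 3
    seed: int = 0
    markers_per_cluster: int = 10
    identity_genes_per_cluster: int = 60
    n_program_genes: int = 60
    state_genes_per_state: int = 15
    program_amplitude: float = 6.0
    state_band_gap: float = 0.12
    library_size_sigma: float = 0.2
    donor_effect_sigma: float = 0.05

    def validate(self) -> None:
        for name in (
            "n_clusters",
            "cells_per_cluster_per_condition",
            "n_genes",
            "n_donors_per_condition",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_mito_genes", "n_secreted", "n_receptors", "n_planted_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.marker_fold_change <= 1:
            raise ValueError("marker_fold_change must exceed 1")
        if self.library_size_mean <= 0 or self.dispersion <= 0:
            raise ValueError("library_size_mean and dispersion must be positive")
        if self.n_planted_pairs > min(self.n_secreted, self.n_receptors):
            raise ValueError("n_planted_pairs exceeds available ligand/receptor genes")
        if self.n_planted_pairs > 0 and self.n_clusters < 2:
            raise ValueError("planted pairs need distinct sender and receiver clusters")
        budget = (
            self.n_mito_genes
            + self.n_clusters * self.markers_per_cluster
            + max(0, self.n_clusters - 1) * self.identity_genes_per_cluster
            + self.n_secreted
            + self.n_receptors
            + self.n_program_genes
            + 3 * self.state_genes_per_state
        )
        if budget > self.n_genes:
            raise ValueError(f"planted genes ({budget}) exceed n_genes ({self.n_genes})")

    @property
    def cluster_names(self) -> list[str]:
        names = [f"C{i}" for i in range(self.n_clusters)]
        if self.n_clusters >= 2:
            names[0] = "FB2"
            names[-1] = "SMC"
        return names

    @property
    def sender_cluster(self) -> str:
        return self.cluster_names[0]

    @property
    def receiver_cluster(self) -> str:
        return self.cluster_names[-1]

    @property
    def n_cells(self) -> int:
        return self.n_clusters * 2 * self.cells_per_cluster_per_condition


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset, for recovery checks."""

    planted_markers: dict[str, frozenset]
    planted_pairs: list[tuple[str, str, str, str]]  # (sender, ligand, receiver, receptor)
    planted_state_genes: dict[str, frozenset]
    shared_terms: dict[str, frozenset] = field(default_factory=dict)
    identity_genes: dict[str, frozenset] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)
    mito_genes: frozenset = frozenset()
    secreted_genes: tuple = ()
    receptor_genes: tuple = ()
    program_genes: frozenset = frozenset()
    sender_cluster: str = ""
    receiver_cluster: str = ""
    planted_states: dict[str, str] = field(default_factory=dict)
    planted_progression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set = set()
        for cluster, genes in self.planted_markers.items():
            if seen & set(genes):
                raise ValueError("planted marker sets must be disjoint across clusters")
            seen |= set(genes)
        for _, ligand, _, receptor in self.planted_pairs:
            if ligand not in self.secreted_genes:
                raise ValueError(f"planted ligand {ligand!r} not in secreted set")
            if receptor not in self.receptor_genes:
                raise ValueError(f"planted receptor {receptor!r} not in receptor set")

    @property
    def ligands(self) -> list[str]:
        return [p[1] for p in self.planted_pairs]

    @property
    def receptors(self) -> list[str]:
        return [p[3] for p in self.planted_pairs]

    def elevated_genes(self, cluster: str) -> frozenset:
        """All genes planted to be up-shifted in ``cluster`` in any way.

        Beyond the cluster's own markers this includes planted ligands for
        the sender (up in its AD cells) and receptors, program genes and
        state genes for the receiver — all of which raise the cluster's
        mean and are therefore legitimate one-vs-rest detections.
        """
        out = set(self.planted_markers.get(cluster, frozenset()))
        out |= set(self.identity_genes.get(cluster, frozenset()))
        if cluster == self.sender_cluster:
            out |= set(self.ligands)
        if cluster == self.receiver_cluster:
            out |= set(self.receptors)
            out |= set(self.program_genes)
            for genes in self.planted_state_genes.values():
                out |= set(genes)
        return frozenset(out)


def _gene_names(config: SimulationConfig) -> dict[str, list[str]]:
    names: dict[str, list[str]] = {}
    names["mito"] = [f"MT-{i + 1}" for i in range(config.n_mito_genes)]
    names["markers"] = [
        f"MK-{cl}-{j}" for cl in config.cluster_names for j in range(config.markers_per_cluster)
    ]
    # broad cell-type identity programs for every non-receiver cluster; the
    # receiver's progression/state/receptor programs play the same role
    # there, keeping the per-cell planted weight mass roughly balanced so
    # library-size renormalization does not turn baseline genes into
    # spurious relative markers of the unshifted clusters
    names["identity"] = [
        f"ID-{cl}-{j}"
        for cl in config.cluster_names[:-1]
        for j in range(config.identity_genes_per_cluster)
    ]
    names["secreted"] = [f"SEC{i:03d}" for i in range(config.n_secreted)]
    names["receptors"] = [f"REC{i:03d}" for i in range(config.n_receptors)]
    names["program"] = [f"PRG{i:02d}" for i in range(config.n_program_genes)]
    names["state"] = [
        f"ST-{s}-{j}" for s in STATES for j in range(config.state_genes_per_state)
    ]
    n_planted = sum(len(v) for v in names.values())
    names["background"] = [f"G{i:05d}" for i in range(config.n_genes - n_planted)]
    return names


def generate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a synthetic UMI count matrix and its ground truth.

    Counts are gamma-Poisson: per-cell library sizes are log-normal
    around ``library_size_mean``, per-gene baseline weights log-normal,
    planted shifts multiply the weights, and the per-cell expected counts
    (weights renormalized to the library size) are overdispersed with the
    configured NB ``dispersion`` (variance = mu + dispersion * mu^2).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    clusters = config.cluster_names
    n_per = config.cells_per_cluster_per_condition

    parts = _gene_names(config)
    genes = (
        parts["mito"] + parts["markers"] + parts["identity"] + parts["secreted"]
        + parts["receptors"] + parts["program"] + parts["state"] + parts["background"]
    )
    gene_pos = {g: i for i, g in enumerate(genes)}

    # cells: per cluster, a nonAD block then an AD block
    cell_ids, cell_cluster, cell_cond, cell_donor = [], [], [], []
    for cl in clusters:
        for cond in ("nonAD", "AD"):
            for i in range(n_per):
                cell_ids.append(f"{cond}-{cl}-{i:03d}")
                cell_cluster.append(cl)
                cell_cond.append(cond)
                cell_donor.append(f"{cond}-donor{i % config.n_donors_per_condition}")
    cell_cluster = np.array(cell_cluster, dtype=object)
    cell_cond = np.array(cell_cond, dtype=object)
    n_cells = len(cell_ids)

    # baseline gene weights; planted genes pinned to a detectable baseline
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    for key in ("markers", "identity", "secreted", "receptors", "program", "state"):
        for g in parts[key]:
            weights[gene_pos[g]] = 1.0
    for g in parts["mito"]:
        weights[gene_pos[g]] = 3.0

    factors = np.ones((config.n_genes, n_cells))

    # cluster markers
    planted_markers: dict[str, frozenset] = {}
    for ci, cl in enumerate(clusters):
        ms = parts["markers"][ci * config.markers_per_cluster:(ci + 1) * config.markers_per_cluster]
        planted_markers[cl] = frozenset(ms)
        rows = [gene_pos[g] for g in ms]
        cols = cell_cluster == cl
        factors[np.ix_(rows, cols)] *= config.marker_fold_change

    # identity programs (all clusters except the receiver, which carries
    # its progression machinery instead)
    identity_map: dict[str, frozenset] = {clusters[-1]: frozenset()}
    k = config.identity_genes_per_cluster
    for ci, cl in enumerate(clusters[:-1]):
        ids = parts["identity"][ci * k:(ci + 1) * k]
        identity_map[cl] = frozenset(ids)
        rows = [gene_pos[g] for g in ids]
        factors[np.ix_(rows, cell_cluster == cl)] *= config.marker_fold_change

    # ligand-receptor pairs: ligand up in sender AD cells, receptor in receiver
    sender, receiver = config.sender_cluster, config.receiver_cluster
    planted_pairs = []
    for i in range(config.n_planted_pairs):
        lig, rec = parts["secreted"][i], parts["receptors"][i]
        planted_pairs.append((sender, lig, receiver, rec))
        factors[gene_pos[lig], (cell_cluster == sender) & (cell_cond == "AD")] *= (
            config.marker_fold_change
        )
        factors[gene_pos[rec], cell_cluster == receiver] *= config.marker_fold_change

    # receiver-cluster progression: latent coordinate + state blocks
    planted_states: dict[str, str] = {}
    progression = np.zeros(n_cells)
    state_gap = config.state_band_gap
    receiver_mask = cell_cluster == receiver
    state_gene_map = {
        s: frozenset(
            parts["state"][si * config.state_genes_per_state:(si + 1) * config.state_genes_per_state]
        )
        for si, s in enumerate(STATES)
    }
    for cond in ("nonAD", "AD"):
        idx = np.flatnonzero(receiver_mask & (cell_cond == cond))
        n_pure = int(round(0.7 * len(idx)))
        if cond == "nonAD":
            blocks = [(STATES[0], idx[:n_pure]), (STATES[1], idx[n_pure:])]
        else:
            blocks = [(STATES[1], idx[: len(idx) - n_pure]), (STATES[2], idx[len(idx) - n_pure:])]
        for state, members in blocks:
            si = STATES.index(state)
            # states are metastable phases: progression density concentrates
            # within each state's band, leaving small gaps at the boundaries
            lo = si / 3.0 + (state_gap / 2.0 if si > 0 else 0.0)
            hi = (si + 1) / 3.0 - (state_gap / 2.0 if si < 2 else 0.0)
            t = rng.uniform(lo, hi, size=len(members))
            progression[members] = t
            for cid in members:
                planted_states[cell_ids[cid]] = state
            rows = [gene_pos[g] for g in state_gene_map[state]]
            factors[np.ix_(rows, members)] *= config.marker_fold_change
    prog_rows = [gene_pos[g] for g in parts["program"]]
    rec_idx = np.flatnonzero(receiver_mask)
    factors[np.ix_(prog_rows, rec_idx)] *= 1.0 + (config.program_amplitude - 1.0) * progression[rec_idx]

    # library sizes with a mild donor effect
    donor_names = sorted(set(cell_donor))
    donor_mult = {
        d: m
        for d, m in zip(
            donor_names,
            rng.lognormal(-config.donor_effect_sigma**2 / 2, config.donor_effect_sigma, len(donor_names)),
        )
    }
    lib = (
        config.library_size_mean
        * rng.lognormal(-config.library_size_sigma**2 / 2, config.library_size_sigma, n_cells)
        * np.array([donor_mult[d] for d in cell_donor])
    )

    # gamma-Poisson draw
    w = weights[:, None] * factors
    mu = w / w.sum(axis=0, keepdims=True) * lib[None, :]
    lam = rng.gamma(shape=1.0 / config.dispersion, scale=mu * config.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    cell_meta = pd.DataFrame(
        {"donor": cell_donor, "condition": list(cell_cond), "cluster": list(cell_cluster)},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    gene_flags = pd.DataFrame(
        {"is_mito": [g.startswith("MT-") for g in genes]},
        index=pd.Index(genes, name="gene_id"),
    )
    matrix = CountMatrix(counts, genes, cell_ids, cell_meta, gene_flags)

    truth = GroundTruth(
        planted_markers=planted_markers,
        planted_pairs=planted_pairs,
        planted_state_genes=state_gene_map,
        identity_genes=identity_map,
        genes=list(genes),
        mito_genes=frozenset(parts["mito"]),
        secreted_genes=tuple(parts["secreted"]),
        receptor_genes=tuple(parts["receptors"]),
        program_genes=frozenset(parts["program"]),
        sender_cluster=sender,
        receiver_cluster=receiver,
        planted_states=planted_states,
        planted_progression={
            cell_ids[i]: float(progression[i]) for i in np.flatnonzero(receiver_mask)
        },
    )
    return matrix, truth


def generate_lr_db(config: SimulationConfig, truth: GroundTruth) -> LigandReceptorDB:
    """Toy ligand-receptor database containing all planted pairs plus decoys.

    Decoy pairs link the remaining secreted and receptor genes one-to-one;
    their members carry no planted shift, so they are expressed at
    baseline only.
    """
    secreted = truth.secreted_genes
    receptors = truth.receptor_genes
    pairs = [(lig, rec) for _, lig, _, rec in truth.planted_pairs]
    k = config.n_planted_pairs
    for i in range(k, min(len(secreted), len(receptors))):
        pairs.append((secreted[i], receptors[i]))
    return LigandReceptorDB(frozenset(secreted), frozenset(receptors), tuple(pairs))


def generate_go_annotation(
    truth: GroundTruth, terms_per_gene: int = 3, seed: int = 0
) -> GeneTermAnnotation:
    """Toy GO annotation with planted ligand/state-gene term sharing.

    Every gene receives ``terms_per_gene`` terms. Each planted state's
    genes all carry that state's two reserved terms; each planted ligand
    carries one of the AD-enriched state's reserved terms (recorded in
    ``truth.shared_terms``); all remaining assignments are random draws
    from a general vocabulary.
    """
    if terms_per_gene < 1:
        raise ValueError("terms_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    general = [f"GO:G{i:03d}" for i in range(60)]
    reserved = {s: (f"GO:{s}:1", f"GO:{s}:2") for s in STATES}
    state_of_gene = {
        g: s for s, gs in truth.planted_state_genes.items() for g in gs
    }
    ligands = set(truth.ligands)
    mapping: dict[str, set[str]] = {}
    shared: dict[str, frozenset] = {}
    for gi, gene in enumerate(truth.genes):
        if gene in state_of_gene:
            base = list(reserved[state_of_gene[gene]])[:terms_per_gene]
        elif gene in ligands:
            ad_term = reserved[STATES[2]][gi % 2]
            base = [ad_term]
            shared[gene] = frozenset([ad_term])
        else:
            base = []
        n_fill = terms_per_gene - len(base)
        fill = rng.choice(general, size=n_fill, replace=False).tolist() if n_fill else []
        mapping[gene] = set(base) | set(fill)
    truth.shared_terms = shared
    return GeneTermAnnotation(mapping)
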