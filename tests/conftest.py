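"""Shared fixtures: a reference synthetic dataset and small toy builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crosstalk import (
    NormalizedMatrix,
    SimulationConfig,
    condition_split,
    filter_cells,
    filter_genes,
    find_all_markers,
    generate_counts,
    generate_go_annotation,
    generate_lr_db,
    normalize,
)

REF_SEED = 20240


@pytest.fixture(scope="session")
def ref_config() -> SimulationConfig:
    """Reference synthetic conditions (generator defaults, fixed seed)."""
    return SimulationConfig(seed=REF_SEED)


@pytest.fixture(scope="session")
def ref_data(ref_config):
    counts, truth = generate_counts(ref_config)
    db = generate_lr_db(ref_config, truth)
    annotation = generate_go_annotation(truth, terms_per_gene=3, seed=REF_SEED)
    return counts, truth, db, annotation


@pytest.fixture(scope="session")
def ref_nm(ref_data) -> NormalizedMatrix:
    counts, _, _, _ = ref_data
    kept, rep_cells = filter_cells(counts, sd_window=2.0, min_genes=100)
    kept, rep_genes = filter_genes(kept, min_cells=10, drop_mito=True)
    return normalize(kept, provenance=[rep_cells, rep_genes])


@pytest.fixture(scope="session")
def ref_groups(ref_nm) -> pd.Series:
    return condition_split(ref_nm.cell_meta, min_cells=10)


@pytest.fixture(scope="session")
def ref_cluster_markers(ref_nm) -> pd.DataFrame:
    return find_all_markers(ref_nm)


@pytest.fixture(scope="session")
def ref_group_markers(ref_nm, ref_groups) -> pd.DataFrame:
    return find_all_markers(ref_nm, clusters=ref_groups.to_numpy())


@pytest.fixture(scope="session")
def ref_traj_states(ref_nm, ref_data):
    """Per-state enriched-term tables from the reference trajectory."""
    from crosstalk import assign_states, go_enrichment, order_cells, state_degs

    _, truth, _, annotation = ref_data
    cells = [
        c for c, cl in ref_nm.cell_meta["cluster"].items() if cl == truth.receiver_cluster
    ]
    pt = order_cells(ref_nm, cells)
    traj = assign_states(pt, ref_nm.cell_meta["condition"])
    degs = state_degs(ref_nm, traj, top_n=300)
    universe = [str(g) for g in ref_nm.gene_ids]
    return {s: go_enrichment(b, annotation, universe) for s, b in degs.blocks.items()}


def make_norm(values, genes=None, cells=None, condition=None, cluster=None) -> NormalizedMatrix:
    """Build a NormalizedMatrix directly from a value array (toy inputs)."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cells = cells or [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    meta["donor"] = "d0"
    meta["condition"] = condition if condition is not None else ["nonAD"] * n_cells
    if cluster is not None:
        meta["cluster"] = cluster
    return NormalizedMatrix(values, genes, cells, meta)
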