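"""Reading and writing the pipeline's on-disk formats.

Count matrices travel as MatrixMarket triplets (genes x cells, 1-based)
with ``genes.tsv`` / ``barcodes.tsv`` sidecars, or as dense TSV. The
ligand-receptor database uses either a three-file toy dialect
(``secreted.tsv``, ``receptors.tsv``, ``pairs.tsv``) or CellPhoneDB-style
``gene_input`` / ``protein_input`` / ``interaction_input`` tables. Ground
truth and filter reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datagen import GroundTruth
from .interactome import LigandReceptorDB
from .qc import CountMatrix, FilterReport, NormalizedMatrix


# ---------------------------------------------------------------- counts

def write_counts_mtx(m: CountMatrix, outdir) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", scipy.sparse.coo_matrix(m.values))
    genes = m.gene_flags.reset_index()
    genes.columns = ["gene_id"] + list(m.gene_flags.columns)
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    barcodes = m.cell_meta.reset_index()
    barcodes.columns = ["cell_id"] + list(m.cell_meta.columns)
    barcodes.to_csv(outdir / "barcodes.tsv", sep="\t", index=False)


def read_counts_mtx(indir) -> CountMatrix:
    indir = Path(indir)
    values = np.asarray(scipy.io.mmread(indir / "matrix.mtx").todense())
    genes = pd.read_csv(indir / "genes.tsv", sep="\t").set_index("gene_id")
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t").set_index("cell_id")
    return CountMatrix(
        values.astype(np.int64),
        list(genes.index.astype(str)),
        list(barcodes.index.astype(str)),
        barcodes,
        genes,
    )


def write_counts_tsv(m: CountMatrix, path) -> None:
    """Dense genes-x-cells TSV (gene ids as row index, cell ids as columns)."""
    pd.DataFrame(m.values, index=list(m.gene_ids), columns=list(m.cell_ids)).to_csv(
        path, sep="\t"
    )


def read_counts_tsv(path, cell_meta: pd.DataFrame, mito_prefix: str = "MT-") -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    flags = pd.DataFrame(
        {"is_mito": df.index.astype(str).str.startswith(mito_prefix)},
        index=pd.Index(df.index.astype(str), name="gene_id"),
    )
    return CountMatrix(
        df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)), cell_meta, flags
    )


def write_normalized_mtx(nm: NormalizedMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "normalized.mtx", scipy.sparse.coo_matrix(nm.values))
    pd.Series(list(nm.gene_ids), name="gene_id").to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    meta = nm.cell_meta.reset_index()
    meta.columns = ["cell_id"] + list(nm.cell_meta.columns)
    meta.to_csv(outdir / "barcodes.tsv", sep="\t", index=False)


def read_normalized_mtx(indir) -> NormalizedMatrix:
    indir = Path(indir)
    values = np.asarray(scipy.io.mmread(indir / "normalized.mtx").todense(), dtype=float)
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene_id"].astype(str).tolist()
    meta = pd.read_csv(indir / "barcodes.tsv", sep="\t").set_index("cell_id")
    return NormalizedMatrix(values, genes, list(meta.index.astype(str)), meta)


# ---------------------------------------------------------- LR database

def write_lr_db(db: LigandReceptorDB, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"gene": sorted(db.secreted_genes)}).to_csv(
        outdir / "secreted.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene": sorted(db.receptor_genes)}).to_csv(
        outdir / "receptors.tsv", sep="\t", index=False
    )
    pd.DataFrame(list(db.pairs), columns=["ligand", "receptor"]).to_csv(
        outdir / "pairs.tsv", sep="\t", index=False
    )


def read_lr_db(indir) -> LigandReceptorDB:
    """Read either the toy dialect or a CellPhoneDB-style directory."""
    indir = Path(indir)
    if (indir / "secreted.tsv").exists():
        secreted = set(pd.read_csv(indir / "secreted.tsv", sep="\t")["gene"].astype(str))
        receptors = set(pd.read_csv(indir / "receptors.tsv", sep="\t")["gene"].astype(str))
        pairs_df = pd.read_csv(indir / "pairs.tsv", sep="\t", dtype=str)
        pairs = tuple(zip(pairs_df["ligand"], pairs_df["receptor"]))
        return LigandReceptorDB(frozenset(secreted), frozenset(receptors), pairs)
    return read_cellphonedb(indir)


def _read_table(indir: Path, stem: str) -> pd.DataFrame:
    for ext, sep in ((".csv", ","), (".tsv", "\t")):
        path = indir / f"{stem}{ext}"
        if path.exists():
            return pd.read_csv(path, sep=sep)
    raise FileNotFoundError(f"{stem}.csv/.tsv not found in {indir}")


def read_cellphonedb(indir) -> LigandReceptorDB:
    """Parse CellPhoneDB-style gene_input / protein_input / interaction_input.

    ``protein_input`` must carry boolean ``secreted`` and ``receptor``
    columns; ``interaction_input`` partners are uniprot accessions mapped
    to gene names through ``gene_input``. A pair is emitted for each
    interaction oriented secreted-partner -> receptor-partner.
    """
    indir = Path(indir)
    gene_input = _read_table(indir, "gene_input")
    protein_input = _read_table(indir, "protein_input")
    interaction_input = _read_table(indir, "interaction_input")
    uni_to_gene = dict(zip(gene_input["uniprot"].astype(str), gene_input["gene_name"].astype(str)))

    def truthy(col: pd.Series) -> pd.Series:
        return col.astype(str).str.lower().isin({"true", "1", "yes", "t"})

    secreted_uni = set(protein_input.loc[truthy(protein_input["secreted"]), "uniprot"].astype(str))
    receptor_uni = set(protein_input.loc[truthy(protein_input["receptor"]), "uniprot"].astype(str))
    secreted = {uni_to_gene[u] for u in secreted_uni if u in uni_to_gene}
    receptors = {uni_to_gene[u] for u in receptor_uni if u in uni_to_gene}
    pairs = []
    for a, b in zip(interaction_input["partner_a"].astype(str), interaction_input["partner_b"].astype(str)):
        for lig_u, rec_u in ((a, b), (b, a)):
            if lig_u in secreted_uni and rec_u in receptor_uni:
                lig, rec = uni_to_gene.get(lig_u), uni_to_gene.get(rec_u)
                if lig and rec and (lig, rec) not in pairs:
                    pairs.append((lig, rec))
    return LigandReceptorDB(frozenset(secreted), frozenset(receptors), tuple(pairs))


# ----------------------------------------------------------------- JSON

def write_ground_truth(truth: GroundTruth, path) -> None:
    doc = {
        "planted_markers": {k: sorted(v) for k, v in truth.planted_markers.items()},
        "planted_pairs": [list(p) for p in truth.planted_pairs],
        "planted_state_genes": {k: sorted(v) for k, v in truth.planted_state_genes.items()},
        "identity_genes": {k: sorted(v) for k, v in truth.identity_genes.items()},
        "shared_terms": {k: sorted(v) for k, v in truth.shared_terms.items()},
        "genes": list(truth.genes),
        "mito_genes": sorted(truth.mito_genes),
        "secreted_genes": list(truth.secreted_genes),
        "receptor_genes": list(truth.receptor_genes),
        "program_genes": sorted(truth.program_genes),
        "sender_cluster": truth.sender_cluster,
        "receiver_cluster": truth.receiver_cluster,
        "planted_states": dict(sorted(truth.planted_states.items())),
        "planted_progression": dict(sorted(truth.planted_progression.items())),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_markers={k: frozenset(v) for k, v in doc["planted_markers"].items()},
        planted_pairs=[tuple(p) for p in doc["planted_pairs"]],
        planted_state_genes={k: frozenset(v) for k, v in doc["planted_state_genes"].items()},
        identity_genes={k: frozenset(v) for k, v in doc.get("identity_genes", {}).items()},
        shared_terms={k: frozenset(v) for k, v in doc["shared_terms"].items()},
        genes=list(doc["genes"]),
        mito_genes=frozenset(doc["mito_genes"]),
        secreted_genes=tuple(doc["secreted_genes"]),
        receptor_genes=tuple(doc["receptor_genes"]),
        program_genes=frozenset(doc["program_genes"]),
        sender_cluster=doc["sender_cluster"],
        receiver_cluster=doc["receiver_cluster"],
        planted_states=dict(doc["planted_states"]),
        planted_progression={k: float(v) for k, v in doc["planted_progression"].items()},
    )


def write_filter_reports(reports: list[FilterReport], path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in reports], indent=1))
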