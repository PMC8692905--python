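"""End-to-end orchestration: simulate/load -> QC -> markers -> trajectory -> interactome.

A run is driven by a single nested configuration (YAML or dict) whose
defaults live in ``crosstalk/data/default_config.yaml``. Every stage
threshold is a named key. The run writes each stage's tables to the
output directory and a machine-readable ``run_report.json`` whose content
is a pure function of the inputs and seed (no timestamps), so repeated
runs with the same seed are byte-identical.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as cio
from .annotation import GeneTermAnnotation
from .datagen import SimulationConfig, generate_counts, generate_go_annotation, generate_lr_db
from .interactome import (
    condition_split,
    count_pairs_per_group,
    crossmatch,
    extract_cluster_ligands,
    extract_cluster_receptors,
    score_lr_pairs,
    secreting_capacity,
)
from .markers import count_degs, find_all_markers, find_markers_between
from .qc import filter_cells, filter_genes, flag_mito_genes, normalize, standin_cluster
from .trajectory import TrajectoryAssignment, assign_states, go_enrichment, order_cells, state_degs

logger = logging.getLogger("crosstalk")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def default_config() -> dict:
    text = resources.files("crosstalk").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


@dataclass
class RunConfig:
    """Validated nested run configuration (see default_config.yaml)."""

    raw: dict

    @classmethod
    def from_dict(cls, overrides: Optional[dict] = None) -> "RunConfig":
        cfg = cls(_deep_merge(default_config(), overrides or {}))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        mode = self.raw.get("mode")
        if mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        inputs = self.raw.get("inputs", {})
        has_real = bool(inputs.get("counts_dir") or inputs.get("counts_tsv"))
        if mode == "real" and not has_real:
            raise ValueError("real mode requires inputs.counts_dir or inputs.counts_tsv")
        if mode == "synthetic" and has_real:
            raise ValueError("synthetic mode must not set real-data count inputs")
        if mode == "real":
            if not inputs.get("lrdb_dir"):
                raise ValueError("real mode requires inputs.lrdb_dir")
            if not inputs.get("go_annotation_tsv"):
                raise ValueError("real mode requires inputs.go_annotation_tsv")

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.raw.get("simulation", {}))
        sim.setdefault("seed", self.raw.get("seed", 0))
        return SimulationConfig(**sim)

    def __getitem__(self, key):
        return self.raw[key]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


def run_pipeline(config: RunConfig, out_dir: Optional[str] = None) -> dict:
    """Execute all stages; write per-stage tables and return the run report."""
    cfg = config.raw
    out = Path(out_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    report: dict = {"mode": cfg["mode"], "seed": seed, "stages": {}}
    report["thresholds"] = {
        "qc": cfg["qc"],
        "markers": cfg["markers"],
        "variable_genes": cfg["variable_genes"],
        "trajectory": {k: v for k, v in cfg["trajectory"].items()},
        "interactome": cfg["interactome"],
    }

    # ---------------------------------------------------------- stage 1
    @_stage("simulate/load")
    def load():
        if cfg["mode"] == "synthetic":
            sim = config.simulation_config()
            counts, truth = generate_counts(sim)
            db = generate_lr_db(sim, truth)
            annotation = generate_go_annotation(
                truth, int(cfg["trajectory"]["go_terms_per_gene"]), seed
            )
            cio.write_counts_mtx(counts, out / "counts")
            cio.write_ground_truth(truth, out / "ground_truth.json")
            cio.write_lr_db(db, out / "lrdb")
            annotation.write_tsv(out / "go_annotation.tsv")
            lineage = truth.receiver_cluster
            report["stages"]["simulate"] = {
                "n_genes": counts.n_genes,
                "n_cells": counts.n_cells,
                "n_clusters": sim.n_clusters,
                "n_planted_pairs": sim.n_planted_pairs,
            }
            return counts, db, annotation, lineage
        inputs = cfg["inputs"]
        if inputs.get("counts_dir"):
            counts = cio.read_counts_mtx(inputs["counts_dir"])
        else:
            meta = pd.read_csv(inputs["metadata_tsv"], sep="\t").set_index("cell_id")
            counts = cio.read_counts_tsv(
                inputs["counts_tsv"], meta, cfg["qc"]["mito_prefix"]
            )
        counts = flag_mito_genes(counts, cfg["qc"]["mito_prefix"])
        db = cio.read_lr_db(inputs["lrdb_dir"])
        annotation = GeneTermAnnotation.read_tsv(inputs["go_annotation_tsv"])
        lineage = cfg["trajectory"]["lineage_cluster"]
        report["stages"]["load"] = {"n_genes": counts.n_genes, "n_cells": counts.n_cells}
        return counts, db, annotation, lineage

    counts, db, annotation, lineage = load()

    # ---------------------------------------------------------- stage 2
    @_stage("qc_norm")
    def qc():
        qc_cfg = cfg["qc"]
        cells_kept, rep_cells = filter_cells(
            counts, float(qc_cfg["sd_window"]), int(qc_cfg["min_genes"])
        )
        genes_kept, rep_genes = filter_genes(
            cells_kept, int(qc_cfg["min_cells"]), bool(qc_cfg["drop_mito"])
        )
        nm = normalize(genes_kept, provenance=[rep_cells, rep_genes])
        if "cluster" not in nm.cell_meta.columns or nm.cell_meta["cluster"].isna().any():
            logger.warning("no cluster labels supplied; using stand-in k-means clusters")
            nm.cell_meta = nm.cell_meta.copy()
            nm.cell_meta["cluster"] = standin_cluster(
                nm, int(cfg["inputs"]["n_standin_clusters"]), seed
            )
        cio.write_filter_reports([rep_cells, rep_genes], out / "filter_reports.json")
        cio.write_normalized_mtx(nm, out / "normalized")
        report["stages"]["qc"] = {
            "n_cells_in": rep_cells.n_cells_in,
            "n_cells_out": rep_cells.n_cells_out,
            "n_genes_in": rep_genes.n_genes_in,
            "n_genes_out": rep_genes.n_genes_out,
            "umi_bounds_log10": list(rep_cells.umi_bounds),
        }
        return nm

    nm = qc()

    # ---------------------------------------------------------- stage 3
    @_stage("markers")
    def markers():
        mk = cfg["markers"]
        cluster_markers = find_all_markers(
            nm, q_max=float(mk["q_max"]), min_log_fc=float(mk["min_log_fc"])
        )
        cluster_markers.to_csv(out / "cluster_markers.tsv", sep="\t", index=False)
        groups = condition_split(nm.cell_meta, int(cfg["interactome"]["group_min_cells"]))
        group_markers = find_all_markers(
            nm, clusters=groups.to_numpy(), q_max=float(mk["q_max"]),
            min_log_fc=float(mk["min_log_fc"]),
        )
        group_markers.to_csv(out / "group_markers.tsv", sep="\t", index=False)
        deg_tables = {}
        for cluster in sorted(nm.cell_meta["cluster"].astype(str).unique()):
            meta = nm.cell_meta
            ad = meta.index[(meta["cluster"].astype(str) == cluster) & (meta["condition"] == "AD")]
            non = meta.index[
                (meta["cluster"].astype(str) == cluster) & (meta["condition"] == "nonAD")
            ]
            if len(ad) < 3 or len(non) < 3:
                logger.warning("cluster %r lacks cells in one condition; DEGs skipped", cluster)
                continue
            deg_tables[cluster] = find_markers_between(
                nm, list(ad), list(non), float(mk["q_max"]), label=f"{cluster}:AD_vs_nonAD"
            )
        degs = count_degs(deg_tables)
        degs.to_csv(out / "deg_counts.tsv", sep="\t", index=False)
        report["stages"]["markers"] = {
            "n_cluster_markers": {
                str(k): int(v) for k, v in cluster_markers["group"].value_counts().sort_index().items()
            },
            "n_group_markers": {
                str(k): int(v) for k, v in group_markers["group"].value_counts().sort_index().items()
            },
            "deg_counts": degs.to_dict(orient="records"),
        }
        return cluster_markers, group_markers, groups

    cluster_markers, group_markers, groups = markers()

    # ---------------------------------------------------------- stage 4
    @_stage("trajectory")
    def trajectory():
        tcfg = cfg["trajectory"]
        lineage_cells = [
            c for c, cl in nm.cell_meta["cluster"].astype(str).items() if cl == str(lineage)
        ]
        if cfg["mode"] == "real" and cfg["inputs"].get("trajectory_tsv"):
            traj = TrajectoryAssignment.read_tsv(cfg["inputs"]["trajectory_tsv"])
        else:
            vg = cfg["variable_genes"]
            sub = nm.subset_cells(lineage_cells)
            from .qc import select_variable_genes

            var_genes = select_variable_genes(
                sub, float(vg["mean_low"]), float(vg["mean_high"]), float(vg["min_dispersion"])
            )
            pseudotime = order_cells(nm, lineage_cells, var_genes)
            traj = assign_states(
                pseudotime,
                nm.cell_meta["condition"],
                float(tcfg["enrich_threshold"]),
            )
        traj.write_tsv(out / "trajectory.tsv")
        degs = state_degs(nm, traj, int(tcfg["top_n_state_degs"]))
        degs.table.to_csv(out / "state_degs.tsv", sep="\t", index=False)
        universe = [str(g) for g in nm.gene_ids]
        state_terms = {}
        for state, block in degs.blocks.items():
            enr = go_enrichment(block, annotation, universe, float(tcfg["p_max"]))
            enr.to_csv(out / f"enrichment_{state}.tsv", sep="\t", index=False)
            state_terms[state] = enr
        report["stages"]["trajectory"] = {
            "lineage_cluster": str(lineage),
            "n_lineage_cells": len(traj.cells),
            "state_sizes": {k: int(v) for k, v in traj.state_counts().items()},
            "boundaries": [float(b) for b in traj.boundaries],
            "block_sizes": {k: len(v) for k, v in degs.blocks.items()},
            "n_enriched_terms": {k: int(len(v)) for k, v in state_terms.items()},
        }
        return traj, state_terms

    traj, state_terms = trajectory()

    # ---------------------------------------------------------- stage 5
    @_stage("interactome")
    def interactome():
        icfg = cfg["interactome"]
        ligand_sets = extract_cluster_ligands(group_markers, db)
        receptor_sets_all = extract_cluster_receptors(group_markers, db)
        receiver_suffix = f"-{lineage}"
        receptor_sets = {
            g: s for g, s in receptor_sets_all.items() if g.endswith(receiver_suffix)
        }
        capacity = secreting_capacity(nm, groups, ligand_sets)
        capacity.to_csv(out / "secreting_capacity.tsv", sep="\t", index=False)
        xm = crossmatch(ligand_sets, annotation, state_terms)
        xm.records.to_csv(out / "crossmatch_records.tsv", sep="\t", index=False)
        xm.counts.to_csv(out / "crossmatch_counts.tsv", sep="\t", index=False)
        scores = score_lr_pairs(nm, groups, db, ligand_sets, receptor_sets)
        scores.to_csv(out / "interaction_scores.tsv", sep="\t", index=False)
        pair_counts = count_pairs_per_group(scores, float(icfg["min_score"]))
        pair_counts.to_csv(out / "pair_counts.tsv", sep="\t", index=False)
        report["stages"]["interactome"] = {
            "secreting_capacity": capacity[["group", "capacity", "n_ligands", "rank"]].to_dict(
                orient="records"
            ),
            "top_secretor": str(capacity.iloc[0]["group"]) if len(capacity) else None,
            "crossmatch_counts": xm.counts.to_dict(orient="records"),
            "n_scored_pairs": int(len(scores)),
            "top_pairs": scores.head(20).to_dict(orient="records"),
            "pair_counts": pair_counts.to_dict(orient="records"),
        }

    interactome()

    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("run complete; report written to %s", out / "run_report.json")
    return report
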