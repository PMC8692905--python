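# Fully specified defaults for the synthetic end-to-end run.
# Every stage threshold is surfaced here by name; the qc block scales the
# per-cell gene floor to the synthetic transcriptome size (the library
# function defaults keep the whole-transcriptome values 1000 / 10).
mode: synthetic
seed: 0
output_dir: crosstalk_run

simulation:
  n_clusters: 4
  cells_per_cluster_per_condition: 100
  n_genes: 1200
  n_mito_genes: 10
  n_secreted: 40
  n_receptors: 40
  n_planted_pairs: 5
  marker_fold_change: 4.0
  library_size_mean: 5000.0
  dispersion: 0.5
  n_donors_per_condition: 3
  markers_per_cluster: 10
  identity_genes_per_cluster: 60
  n_program_genes: 60
  state_genes_per_state: 15
  program_amplitude: 6.0

qc:
  sd_window: 2.0
  min_genes: 100
  min_cells: 10
  drop_mito: true
  mito_prefix: MT-

markers:
  q_max: 0.05
  min_log_fc: 0.0

variable_genes:
  mean_low: 0.01
  mean_high: 3.0
  min_dispersion: 1.0

trajectory:
  lineage_cluster: SMC
  enrich_threshold: 0.6
  top_n_state_degs: 1000
  p_max: 0.05
  go_terms_per_gene: 3

interactome:
  group_min_cells: 10
  min_score: 0.0

inputs:
  counts_dir: null
  counts_tsv: null
  metadata_tsv: null
  lrdb_dir: null
  go_annotation_tsv: null
  trajectory_tsv: null
  n_standin_clusters: 4
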