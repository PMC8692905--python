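# Methods

This note documents the models and procedures implemented in `crosstalk`,
the parameters that matter, the design choices made where the procedure was
genuinely open, and what the synthetic validation does and does not show.

## QC and normalization

**Cell filter.** A cell is retained when (a) its log10 total UMI lies within
`mean ± sd_window · s.d.` of the log10 totals of *all input cells* (sample
standard deviation, inclusive bounds, computed in a single pass — re-applying
the same bounds is a no-op), and (b) it detects at least `min_genes` genes
(count > 0, inclusive). Defaults `sd_window = 2`, `min_genes = 1000` suit
whole-transcriptome data; the synthetic run configuration scales `min_genes`
to 100 because the simulated transcriptome has 1200 genes. Cells with zero
total UMI are a hard error (log10 undefined), not a silent drop.

**Gene filter.** Genes detected in at least `min_cells` cells (default 10,
inclusive) are kept; genes flagged mitochondrial are removed regardless of
prevalence. Mitochondrial genes are recognized by a configurable name prefix
(default `MT-`), since annotations differ across references.

**Normalization.** `v = ln(count / cell_total · 10,000 + 1)`. The `+1`
pseudocount is a design decision: UMI data are zero-dominated and `ln(0)` is
undefined; with it, zero counts map to exactly 0 and the transform is
invertible, giving the per-cell conservation invariant
`Σ_genes (e^v − 1) = 10,000` exactly (cell totals are computed *after* gene
filtering so the invariant holds on the emitted matrix).

**Variable genes.** Kept when the mean log value lies in
`[mean_low, mean_high]` (defaults 0.01, 3) and dispersion exceeds
`min_dispersion` (default 1), with dispersion defined as variance/mean of the
de-logged `e^v − 1` values — the mean/variance-ratio convention behind those
bounds. On the synthetic data, where every gene is negative-binomial with
dispersion 0.5 at mean counts of a few, this filter is intentionally
permissive; on sparse real data it is selective.

**Similarity.** Per-cell similarity is the Pearson correlation to the cell's
own cluster centroid; the centroid *includes* the cell (the simplest reading
of "average expression vector of the cell type"), with `include_self=False`
available for leave-one-out sensitivity analysis. Group-level structure uses
Pearson correlation between (cluster × condition) mean vectors. Constant
vectors raise an error naming the offending cell rather than returning NaN.

## Rank-sum testing and multiple-testing control

The two-sample Wilcoxon–Mann–Whitney test is implemented directly because it
is the statistical workhorse of every marker computation:

* pooled n ≤ 12 — exact: all C(n, n₁) relabelings of the pooled midranks are
  enumerated and the two-sided p is twice the smaller tail (observed value
  included), capped at 1;
* pooled n > 12 — normal approximation with midranks, the standard tie
  correction `σ² = n₁n₂/12 · [(n+1) − Σ(t³−t)/(n(n−1))]`, and a 0.5
  continuity correction. Degenerate σ = 0 (all values tied) returns p = 1.

The switch at n = 12 keeps the exact path affordable (≤ 924 combinations).
For groups of ≥ 3 observations — the minimum every marker function accepts —
the two paths agree within 10% relative error around the switch point; with a
group of 2 the approximation degrades, which is one reason the marker
functions refuse such groups. Tests verify exact-path equality with an
independent enumeration oracle and large-sample agreement with an external
implementation.

Multiple testing uses Benjamini–Hochberg step-up q-values
(`q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1), applied within each cluster's
gene family, with the conventional q ≤ 0.05 cut. BH was chosen as the
q-value procedure because the quoted threshold originates from a toolchain
whose default it is; the implementation is cross-checked against
statsmodels.

Markers are *positive* (log fold change > 0 by default), with
`log_fc = mean_in − mean_out` on the natural-log normalized scale. The
log-fold-change convention matters: the 0.58 threshold often quoted for bulk
differential expression lives on this scale and is exposed as
`BULK_LOG_FC_THRESHOLD` for reference only — bulk pipelines are out of scope.

## Trajectory states

**Pseudotime stand-in.** Tree-based pseudotime reconstruction is replaced by
the rank-normalized projection of the lineage's cells on the first principal
axis of their variable-gene submatrix, scaled to [0, 1] and oriented so the
mean pseudotime of nonAD cells does not exceed that of AD cells. Downstream
computations need only an ordering plus a three-segment partition, and an
externally computed pseudotime can be injected as TSV in the same dialect.
The orientation rule canonicalizes the sign ambiguity of principal axes.

**State assignment.** Cells sorted by pseudotime (ties broken by cell id, so
the result is invariant to monotone transforms) are split into three
contiguous segments by an exact O(n²) search over the two cut points,
minimizing the size-weighted binary entropy of the condition mix within
segments. A segment whose majority condition exceeds `enrich_threshold`
(default 0.6; no published cutoff exists, 0.6 separates "clear majority" from
"mixed" while letting a 50/50 segment stay `transition`) is labeled
`nonAD_enriched` or `AD_enriched`; otherwise `transition`. On small or weakly
structured lineages the entropy optimum can produce a degenerate (near-empty)
transition segment; downstream state DEG analysis then refuses to run (each
state needs ≥ 3 cells) and the pipeline aborts naming the stage — a
deliberate loud failure rather than silent nonsense.

**State DEGs and enrichment.** Genes are screened one-state-vs-rest with the
rank-sum machinery; the `top_n` (default 1000) by minimum p are kept
(constant genes, p = 1, never qualify) and each is assigned to the state of
its maximal mean expression. Per state block, GO enrichment is the
hypergeometric upper tail `P(X ≥ k)` with the universe fixed to the genes
surviving the gene filter (not the whole annotation — enrichment should be
judged against what could have been observed), BH-adjusted, reported at
p < 0.05 by convention.

## Interactome

Groups are condition-split clusters labeled `n-<cluster>` / `d-<cluster>`;
groups under 10 cells are dropped with a warning (means over fewer cells are
too noisy to rank). Receiver groups are the condition splits of the lineage
cluster, matching the ligand-producing side's grouping; the trajectory-state
dimension enters through the cross-match rather than through state-split
receiver means (the scoring function itself is group-agnostic, so state-split
receivers can be passed explicitly when wanted).

* **Ligand sets**: positive markers (q ≤ 0.05) ∩ secreted genes — "specific
  secreted proteins" of the group.
* **Secreting capacity**: for each ligand in the union of ligand sets, the
  vector of per-group mean expressions is z-scored across groups (sample
  s.d.; zero s.d. contributes 0 — such a gene carries no between-group
  information). A group's capacity is the sum over its own ligand set; groups
  are ranked descending. Within floating tolerance each gene's z-scores sum
  to zero across groups.
* **Cross-match**: ligand kept for a state iff terms(ligand) ∩ enriched
  terms(state) ≠ ∅. Both the distinct-ligand count and the matched
  (ligand, term) pair count are reported, since either reading of "number of
  matched pairs" is defensible. Ligands missing from the annotation
  contribute no terms (logged).
* **Scores**: `mean(L | sender) × mean(R | receiver)` on the natural-log
  normalized scale. Log-scale means (rather than back-transformed counts)
  keep the scoring consistent with the marker statistics that selected the
  genes. Receptor eligibility requires the receptor to be a marker of the
  receiver group. Self-pairings are skipped unless requested. Group means are
  computed with a strictly sequential (cumulative-sum) reduction so the
  scores are bit-identical to a per-cell accumulation loop.

## Synthetic data generator

The generator emulates the target study design: `n_donors_per_condition`
donors per condition (default 3, matching the 3-vs-4-donor scale of such
studies), `n_clusters` cell types (default 4) including a fibroblast-like
sender (`FB2`) and an SMC-like receiver (`SMC`), and gamma-Poisson counts:
per-cell library sizes log-normal around `library_size_mean` (default 5000,
σ = 0.2, plus a 5% log-normal donor effect), per-gene baseline weights
log-normal, counts negative-binomial with `dispersion` 0.5
(var = μ + 0.5μ²) — the standard UMI overdispersion model. A single
`numpy` generator seeded from `config.seed` drives everything, so output is
bitwise reproducible.

Planted structure (all fold changes default `marker_fold_change = 4`):

* 10 designated markers per cluster (disjoint across clusters) — the
  sensitivity target for marker recovery;
* a 60-gene "identity program" per non-receiver cluster. Real cell types
  express broad identity programs, and this mass balances per-cell planted
  weight across clusters: without it, library renormalization makes every
  baseline gene genuinely (relatively) elevated in the unshifted clusters,
  which the rank-sum test duly detects at n ≈ 800;
* 5 ligand→receptor pairs: the ligand (a secreted gene) is up-shifted only
  in the sender's AD cells, the receptor in all receiver cells; decoy
  database pairs link secreted/receptor genes expressed at baseline only;
* a progression program in the receiver: each receiver cell gets a latent
  coordinate t ∈ [0, 1]; 70% of nonAD cells occupy the first third (the
  planted `nonAD_enriched` state), 70% of AD cells the last third
  (`AD_enriched`), the rest a mixed middle (`transition`). States are
  metastable: t is drawn within each state's band leaving a 0.12 gap at the
  boundaries, as trajectory density concentrates within states. 60 program
  genes scale smoothly as 1 + 5t (6-fold at t = 1) and 15 state genes per
  state are up-shifted blockwise — together strong enough that the principal
  axis orders cells at ρ ≈ 0.95 against the latent coordinate;
* 10 mitochondrial genes with the `MT-` prefix at elevated baseline;
* a toy GO annotation (3 terms/gene): each state's genes carry that state's
  two reserved terms, each planted ligand carries one of the AD-state's
  reserved terms (recorded as the ground-truth shared terms), everything
  else draws from a 60-term general vocabulary.

`GroundTruth.elevated_genes(cluster)` returns *everything* planted to be up
in a cluster (markers, identity program, ligands for the sender, receptors/
program/state genes for the receiver); precision of marker detection is
judged against this set, sensitivity against the designated markers only.

**What the generator does not emulate:** batch/chip effects beyond a scalar
donor depth factor, doublets, ambient RNA, read-level artifacts, realistic
gene-gene correlation structure, or the sparsity of whole-transcriptome data
(1200 genes at ~5000 UMIs gives mean counts of a few, far denser than real
data). Passing recovery tests therefore demonstrates correctness of the
computations and recoverability of planted signal under controlled noise —
not performance on real tissue.

## Problem sizes and determinism

The reference synthetic conditions are 4 clusters × 2 conditions × 100 cells
(800 cells) × 1200 genes; the full pipeline runs in a few seconds and the
test suite in well under a minute. The run report contains no timestamps, so
two runs with the same seed produce byte-identical reports and tables; every
number in the report is recomputable from the stage outputs on disk.

## Known limitations

* The pseudotime stand-in is linear; lineages with branching or cyclic
  structure need an external ordering (supported via TSV injection).
* The entropy segmentation assumes exactly three contiguous states; more
  structured condition mixtures are out of its scope.
* The product-of-means score has no permutation null; it ranks pairs but
  does not attach a significance level (a deliberate non-goal).
* BH q-values assume the usual positive-dependence conditions; rank-sum
  tests across genes are correlated through cell totals, so the null
  false-discovery fraction is controlled in expectation, not per run.
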