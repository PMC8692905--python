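"""Order the receiver lineage in pseudotime and assign three states.

Pseudotime is the rank-normalized first principal axis of the lineage's
variable genes, oriented so non-diseased cells come first. Cells are then
cut into three contiguous segments minimizing condition-mixing entropy
and labeled by majority condition (> 60%): nonAD-enriched, transition,
AD-enriched. Top trajectory DEGs are blocked by peak state and tested for
GO-term enrichment (hypergeometric, p < 0.05).
"""

import pandas as pd

from crosstalk import (
    SimulationConfig,
    assign_states,
    filter_cells,
    filter_genes,
    generate_counts,
    generate_go_annotation,
    go_enrichment,
    normalize,
    order_cells,
    state_degs,
)

config = SimulationConfig(seed=7)
counts, truth = generate_counts(config)
annotation = generate_go_annotation(truth, terms_per_gene=3, seed=7)
kept, _ = filter_cells(counts, 2.0, 100)
kept, _ = filter_genes(kept, 10, True)
nm = normalize(kept)

lineage = [c for c, cl in nm.cell_meta["cluster"].items() if cl == truth.receiver_cluster]
pseudotime = order_cells(nm, lineage)
traj = assign_states(pseudotime, nm.cell_meta["condition"], enrich_threshold=0.6)
print("state sizes:", traj.state_counts().to_dict())
print(f"segment boundaries at pseudotime {traj.boundaries[0]:.3f} and {traj.boundaries[1]:.3f}")

planted = pd.Series(truth.planted_states).reindex(traj.assignments.index)
print(f"agreement with planted partition: {(traj.assignments['state'] == planted).mean():.3f}")

degs = state_degs(nm, traj, top_n=300)
print("DEG block sizes:", {s: len(b) for s, b in degs.blocks.items()})
universe = [str(g) for g in nm.gene_ids]
enr = go_enrichment(degs.blocks["AD_enriched"], annotation, universe, p_max=0.05)
print("terms enriched in the AD-enriched block:")
print(enr.head(4)[["term", "k", "K", "p"]].to_string(index=False))
# The reserved AD-state terms surface with tiny p-values: the planted
# disease program is recovered from expression alone.
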