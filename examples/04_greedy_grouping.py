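"""Group genes into ortholog groups from GenBank files alone.

Emits a synthetic family to GenBank, re-reads it (discarding the
ground-truth labels), and reruns the greedy single-linkage grouper:
global-alignment identity >= 50% over a >= 70% length-ratio gate links
gene pairs, and connected components become ortholog groups. The recovered
partition is compared against the generator's truth.
"""

import tempfile
from collections import defaultdict
from pathlib import Path

from panbgc import (
    SyntheticGCFSpec,
    assign_orthologs_greedy,
    emit_genbank,
    generate_gcf,
    read_gcf_directory,
)

spec = SyntheticGCFSpec(
    n_bgcs=5, core_size=4, accessory_pool_size=3, accessory_prob=0.5,
    unique_rate=0.5, mean_protein_length=120, mutation_rate=0.05, seed=3,
)
truth_gcf = generate_gcf(spec)
truth = {(g.bgc_id, g.gene_id): g.og_id for g in truth_gcf.genes()}

with tempfile.TemporaryDirectory() as tmp:
    emit_genbank(truth_gcf, Path(tmp), with_truth_table=False)
    gcf = read_gcf_directory(tmp, gcf_id="regrouped")
    assign_orthologs_greedy(gcf, identity_threshold=0.5, coverage_threshold=0.7)

predicted = {(g.bgc_id, g.gene_id): g.og_id for g in gcf.genes()}


def blocks(assignment):
    grouped = defaultdict(set)
    for gene, og in assignment.items():
        grouped[og].add(gene)
    return {frozenset(v) for v in grouped.values()}


print(f"genes: {len(truth)}  true OGs: {len(blocks(truth))}  "
      f"recovered OGs: {len(blocks(predicted))}")
print("partitions identical:", blocks(truth) == blocks(predicted))

# With <= 5% per-copy mutation the grouper reproduces the generating
# partition exactly; group labels differ, the gene sets do not.
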