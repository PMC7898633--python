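"""Generate a synthetic 28-experiment herbivory meta-dataset and call DEGs.

Builds the default scenario (four planted experiment clusters, a shared
core-response module that is silent in the aphid-like cluster, a
mite-specific module), applies the DEG thresholds (padj < 0.05,
|log2FC| > 1) per experiment, and assembles the gene x experiment matrix.
"""

from herbimeta import (
    assemble_matrix,
    call_degs,
    default_meta_spec,
    simulate_meta_experiments,
)

spec = default_meta_spec(seed=0)
tables, manifest, truth = simulate_meta_experiments(spec)

print(f"{len(tables)} experiments, {spec.n_genes} genes each (before "
      "platform masking)")
for t in tables[:5]:
    up, down = call_degs(t)
    print(f"  {t.experiment_id:>8}: {len(up):3d} up, {len(down):3d} down")

matrix = assemble_matrix(tables, manifest)
print(f"\nDEG matrix: {len(matrix.genes)} genes x "
      f"{len(matrix.experiments)} experiments")
print("Rows are the union of genes called DE in at least one experiment;")
print("cells hold log2 fold changes (0 where measured but not DE), with")
print("masks recording DE status and platform coverage.")
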