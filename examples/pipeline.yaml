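# Full-pipeline configuration for the synthetic fixture bundle written by
#   netoverlap simulate --seed 1 --outdir fixtures/
# Run with:
#   netoverlap run --config examples/pipeline.yaml
network: fixtures/edges.tsv
genes_a: fixtures/genes_a.txt
genes_b: fixtures/genes_b.txt
universe: fixtures/universe.txt
gmt: fixtures/sets.gmt
expression: fixtures/expr.tsv
annotations: fixtures/annot.tsv
coexpression_genes: fixtures/genes_b.txt
n_perm_localization: 1000
n_perm_proximity: 500
n_boot_ewce: 5000
enrichment_fdr: 0.01
ewce_alpha: 0.05
seed: 42
outdir: netoverlap_results
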