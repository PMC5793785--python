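# Shipped demonstration fixture: two homologous synthetic "species",
# 20 genes, three Ribo-seq replicates, planted uORFs with known truth.
seed: 17
permutations: 10
simulate:
  n_genes: 20
  n_species: 2
  end_depth: 500
thresholds:
  beta_ends: 0.001
  beta_uorf: 0.05
  jaccard: 0.6
  position_tol_nt: 5
  cluster_window_nt: 25
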