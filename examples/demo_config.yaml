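# Scaled-down demonstration cohort: same design as the default study
# conditions (12 uninfected subjects, 14 infected subjects / 79 samples,
# duplicate runs) with fewer proteins so a full run takes seconds.
simulation:
  n_proteins: 120
  n_neopterin_coupled: 30
  n_nfl_coupled: 20
  n_rna_coupled: 8
  n_overlap: 5
  sigma_ppm: 2.0
  sigma_net: 0.01
  dropout_rate: 0.15
  loading_magnitude: 0.6
  seed: 1
ppm_tol: 10.0
net_tol: 0.025
min_peptides: 2
r_cut: 0.3
p_cut: 0.05
min_n: 10
cluster_k: 2
protein_cluster_k: 5
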