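# Demo pipeline configuration: simulate a small cohort and run all stages.
#   dcctree run --config configs/demo.yaml
outdir: results/demo_run
seed: 1
simulate:
  n_per_group: [10, 10]
  n_nodes: 6
  t_len: 300
  group_qbar_scale: 0.5
  group_theta_shift: 0.05
  ados_node: 0
  ados_coupling: -20.0
dcc_starts: 3
mst_mode: abs_reciprocal
variance_ddof: 1
alpha: 0.05
fdr_family: node
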