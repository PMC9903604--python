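# Full simulated run of the triad pipeline.
# Keys prefixed sim_ configure the synthetic triad generator.
seed: 1
alpha: 0.05
fc_threshold: 2.0
expressed_fpkm: 1.0
focal_daps: [3, 8]
sim_daps: [3, 8]
simulate: true
sim_n_genes: 5000
sim_n_reps: 3
sim_effect_log2: 3.0
sim_dispersion: 0.08
phenotype_reps: 20
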