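# Demo pipeline config: a 5-vs-5 extreme-phenotype simulated cohort with a
# planted dominant cis haplotype (penetrance 0.9), followed by diversity
# selection, the co-segregation cascade, association statistics and the
# expression-enrichment test.
seed: 20150415
out_dir: haph_demo_run
stages: [simulate, diversity, filter, assoc, enrich]
simulate:
  n_affected: 5
  n_unaffected: 5
  penetrance: 0.9
  phenocopy: 0.0
  carrier_freq: 0.41
  background_variants: 300
classify:
  affected_min: 50
  unaffected_max: 39
diversity:
  k: 5
assoc:
  prevalence: 0.5
enrich:
  upshift: 2.0
  n_background_genes: 500
  noise_sd: 0.3
  gene_set_size: 171
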