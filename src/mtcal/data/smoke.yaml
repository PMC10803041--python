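# Small end-to-end configuration: 5k pairs per library, toy genome.
seed: 7
simulate:
  n_chroms: 2
  chrom_length: 800000
  n_genes: 60
  n_enhancers: 10
  n_super_enhancers: 2
  n_induced_genes: 10
  libraries:
    - [NM, 1]
    - [HT, 1]
  pairs:
    n_per_library: 5000
    emit_sequences: mt_only
numt:
  threshold: 5
  seed_k: 12
diff:
  focal: "class:mt"
  test: fisher_2x2
  alternative: greater
deg:
  planted_down_n: 10
  planted_or: 4.0
enrich:
  alpha: 0.05
  kd_table: bulk
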