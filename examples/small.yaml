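# A compact scenario for quick runs: 120 kbp genomes, 2 panel strains,
# 3 rRNA operons; planted 30 kbp translocation and 4 kbp inversion.
n_strains: 2
genome_length_bp: 120000
n_genes: 100
n_rrna_operons: 3
n_trna: 8
fragment:
  n_cds: 4
  n_trna: 1
  displacement_bp: 30000
inversion:
  n_cds: 3
  n_trna: 1
  length_bp: 4000
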