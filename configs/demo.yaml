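# Demo pipeline: all-synthetic, small chromosome, finishes in ~1 minute.
seed: 7
chromosome:
  name: chrX
  length_bp: 60000000
resolutions:
  hic_bp: 100000
  density_bp: 200000
hic:
  regimes: [WT_Xi, SMCHD1_KO, XIST_KO]
  read_depth: 3000000
  n_compartments: 10
  boundary_bp: 27000000
coverage:
  enrichment_S1: 0.5
  noise_sd: 0.2
expression:
  n_genes: 150
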