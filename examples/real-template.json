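{
  "mode": "real",
  "outdir": "slicerscan_real_out",
  "seed": 0,
  "genome_fasta": "PATH/TO/genome.fa",
  "gfp_alignments": "PATH/TO/gfp_AGO1IP.bed",
  "dcr1_alignments": "PATH/TO/dcr1_AGO1IP.bed",
  "annotation_bed": "PATH/TO/annotation.bed7",
  "trim": {"adapter3_constant": "TGGAATTCTCGGGTGCCAAGG", "n_random_each_side": 4},
  "scan": {"min_coverage": 40.0, "min_run_len": 20, "min_strand_fraction": 0.75, "max_dG": -10.0}
}
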