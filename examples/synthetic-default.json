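{
  "mode": "synthetic",
  "outdir": "slicerscan_out",
  "seed": 42,
  "expectation_mode": false,
  "write_fastq": true,
  "sim": {"library_depth": 50000, "n_short_hairpin": 3, "n_canonical": 3},
  "scan": {"min_coverage": 40.0, "min_run_len": 20, "min_strand_fraction": 0.75, "max_dG": -10.0}
}
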