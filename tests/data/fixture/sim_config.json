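{
  "n_maternal": 2,
  "n_early_zygotic": 1,
  "n_excluded_high": 0,
  "n_unclassified": 0,
  "intronless_fraction": 0.0,
  "introns_per_gene": [
    2,
    2
  ],
  "exon_len_range": [
    150,
    300
  ],
  "intron_len_bins": [
    [
      60,
      99
    ],
    [
      100,
      400
    ],
    [
      401,
      600
    ]
  ],
  "intron_bin_weights": [
    1.0,
    1.0,
    1.0
  ],
  "retention_levels": [
    0.0,
    0.5
  ],
  "class_retention": null,
  "mis_splice_rate": 0.0,
  "noncanonical_fraction": 0.0,
  "read_len": 100,
  "frag_len_mean": 200.0,
  "frag_len_sd": 20.0,
  "fragments_per_boundary": 25,
  "window_pad": 60,
  "min_overlap": 10,
  "nested_pairs": 0,
  "alt_transcripts": false,
  "force_intronless_last": true,
  "intergenic_gap": 500,
  "chrom_name": "chrS",
  "seed": 7,
  "structure_seed": 20240214
}
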