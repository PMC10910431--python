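{
  "name": "synthetic_amplicon",
  "exon_lengths": [150, 110, 104, 110, 82, 182, 160, 120, 165],
  "cds_start_offset": 60,
  "cds_length": 1023,
  "sequence_seed": 7,
  "isoforms": {"full": [], "skip56": [5, 6], "skip6": [6]},
  "snvs": [
    {"cds_position": 823, "ref": "C", "alt": "T", "splice_allele_base": "C"}
  ],
  "alleles": [
    {
      "name": "splice_allele",
      "weight": 0.364,
      "snv_bases": {"823": "C"},
      "isoform_weights": {"full": 0.147, "skip56": 0.853}
    },
    {
      "name": "trans_allele",
      "weight": 0.636,
      "snv_bases": {"823": "T"},
      "isoform_weights": {"full": 1.0}
    }
  ]
}
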