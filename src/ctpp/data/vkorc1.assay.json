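{
  "label": "VKORC1 G-1639A (rs9923231)",
  "notes": "SYNTHETIC template reconstructed from the published primers and fragment sizes; not genomic reference sequence.",
  "locus": {
    "label": "VKORC1 G-1639A (rs9923231)",
    "template": "ACGTACGTACCACAGACGCCAGAGGAAGAGAGACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGAAGACCTGAAAAACAACCATTGGCCAGGTGCGGTGGCTCACGCGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTCCAAACTACTTGGGAGGCTGAGGTACGTACGT",
    "snp_offset": 112,
    "allele_x": "A",
    "allele_y": "G"
  },
  "primers": {
    "F1": {
      "seq": "CACAGACGCCAGAGGAAGAGAG",
      "start": 10
    },
    "R1": {
      "seq": "CGTGAGCCACCGCACCT",
      "start": 112
    },
    "F2": {
      "seq": "GAAGACCTGAAAAACAACCATTGGCCG",
      "start": 86
    },
    "R2": {
      "seq": "CTCAGCCTCCCAAGTAGTTTGG",
      "start": 272
    }
  },
  "conditions": {
    "monovalent_cation_conc": 0.05,
    "total_strand_conc": 5e-08
  }
}
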