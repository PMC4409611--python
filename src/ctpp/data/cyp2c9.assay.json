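{
  "label": "CYP2C9 A1075C (CYP2C9*3, rs1057910)",
  "notes": "SYNTHETIC template reconstructed from the published primers and fragment sizes; not genomic reference sequence. Some sources misprint the rsID as rs1570910; rs1057910 is correct.",
  "locus": {
    "label": "CYP2C9 A1075C (CYP2C9*3, rs1057910)",
    "template": "ACGTACGTACCCAGGAAGAGATTGAACGTGTGATTGACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAGCACGAGGTCCAGAGATACATTGACCTTCTCCCCACCATACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACCGGGTGAGAGAAGTGCATAACTCCGTACGTACG",
    "snp_offset": 116,
    "allele_x": "A",
    "allele_y": "C"
  },
  "primers": {
    "F1": {
      "seq": "CCAGGAAGAGATTGAACGTGTGATTG",
      "start": 10
    },
    "R1": {
      "seq": "TGGTGGGGAGAAGGTCAAT",
      "start": 116
    },
    "F2": {
      "seq": "GCACGAGGTCCAGAGATACC",
      "start": 97
    },
    "R2": {
      "seq": "GAGTTATGCACTTCTCTCACCCG",
      "start": 274
    }
  },
  "conditions": {
    "monovalent_cation_conc": 0.05,
    "total_strand_conc": 5e-08
  }
}
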