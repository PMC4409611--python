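>vkorc1_synthetic_template SYNTHETIC reconstruction, not genomic reference
ACGTACGTACCACAGACGCCAGAGGAAGAGAGACGTACGTACGTACGTACGTACGTACGT
ACGTACGTACGTACGTACGTACGTACGAAGACCTGAAAAACAACCATTGGCCAGGTGCGG
TGGCTCACGCGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT
ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT
ACGTACGTACGTACGTACGTACGTACGTACGTCCAAACTACTTGGGAGGCTGAGGTACGT
ACGT
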