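>cyp2c9_synthetic_template SYNTHETIC reconstruction, not genomic reference
ACGTACGTACCCAGGAAGAGATTGAACGTGTGATTGACGTACGTACGTACGTACGTACGT
ACGTACGTACGTACGTACGTACGTACGTACGTACGTAGCACGAGGTCCAGAGATACATTG
ACCTTCTCCCCACCATACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT
ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT
ACGTACGTACGTACGTACGTACGTACGTACGTACCGGGTGAGAGAAGTGCATAACTCCGT
ACGTACG
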