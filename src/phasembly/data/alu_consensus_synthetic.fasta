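>Alu_consensus_synthetic stand-in consensus (randomly generated, fixed seed); not the published AluY sequence
AGGGAGTAAAGTCACGATGACATGGAAGCTGTCGTAGTTATGCGAGAGTCCAGGCTGGGACCGTCCGGAG
TCAGATTTTTCGGTCCGACTCACATGTGTAATTGCACAAGTCCGTCAGGCGGATACGCTCGGGTTAGGCC
CGGTACGATGTCTCTACTACGTAACAGTAACAACGAGGTGGATAATAAACGAGCGTGCTACATCCGCTTT
TTATCCCCCAACAAAAATTCACTTGAACTAACTGCACTCGACTATGGACTGCGTATAGTCAAGCGGGCCC
AAATGAACTACAAGAGTAGCATTTGCCTAGA
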