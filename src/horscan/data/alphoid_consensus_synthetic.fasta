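>alphoid_consensus_synthetic 171bp synthetic stand-in for a published alphoid monomer consensus
ATGATGCCTGATGAATTTTTTGACTAAACTTACTATGTAACGGTCCGTTGGGGCTTAAAA
GTGCCTTGTCGCATGTACAAGTAATCTGAAAGGACCCACACTTACCCACGCCCTTGTACA
AAAACAAGGAGAGTAAATCTAATTGAGAGTTAACAGCCGGTACAAACGATA
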