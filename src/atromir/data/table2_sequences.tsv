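# Transcribed cloning-oligo table: BLOCK-iT Pol II miR RNAi oligos used to express the
# mature miRNAs. The mature miRNA sequence is embedded in each "top" oligo between the
# TGCTG prefix and the GTTTTGGCCACTGAC hairpin-loop linker.
name	role	dna_sequence
miR-206	top	TGCTGTGGAATGTAAGGAAGTGTGTGGGTTTTGGCCACTGACTGACCCACACACCCTACATTCA
miR-206	bottom	CCTGTGAATGTAGGGTGTGTGGGTCAGTCAGTGGCCAAAACCCACACACTTCCTTACATTCCAC
miR-21	top	TGCTGTAGCTTATCAGACTGATGTTGAGTTTTGGCCACTGACTGACTCAACATCTCTGATAAGCTA
miR-21	bottom	CCTGTAGCTTATCAGAGATGTTGAGTCAGTCAGTGGCCAAAACTCAACATCAGTCTGATAAGCTAC
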