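>candY.t5_chrX
AATCGGGACACTGAGATTTGTCAGCGTCTACTAGCGTTTGTTAACGTCTCTGGAGTTTTACCGCAATTCCAAAGAAGTTAGAAACCGCCAGGGCTACAATACTGTACAATAGACTCCATACAATACCAGGTATAAGTTGACTGAGAGACCTGGCCTTAACCCCTCTGCTCTCTGTAAAGCTAATCGCGAGTGTTGTCAGGAAGCCTGTATGAACGAGTAATATCTAGTCGAAACGAAGCAAAGATGCTCACTCCAAGCTCATGAAATGGTCTCGTAGTTGCATCTACTGGGTTTGCATCAAAACCCGCGGGGAATGCCTGCCATGCGGGGTGCCCTAAGCAGGACAGTTTCGGTGTACCGTCCGACCAGTAGGGGGATACTGCACGTTAGGTCCCTGAGTTCTAGGACCCCTTATGACCGACAATGCTCATATATCATCAGTAGTATCAATGTGACCCATATGCGCGGCTTATAACTGTAGAAATCTGGGTAGAGCTTAT
>candY.t5_chrY
AATCGGGACACTGAGATTTGTCAGCGTCTACTAGCGTTTGTTAACGTCTCTGGAGTGTTATCGCAATTCCAATGAAGTTAGAAACCGCCTGGGCTACAATACTGTACAATAGACTCCATACAATACCAGGTATAAGTTGACTGAGAGACCTGGCCTTAACCCCTCTGCTCTCTGTAAAGCTAATCGCGAGTGTTGTCAGGAAGCCTGTATGAACGAGTAATATCTAGTCGAAACCAAGCAAAGATGCGAATTCCAAACTCATGAAATGGTCTCGTAGTTGCATCTACTGGGTTTGCATCAAAACCCGCGGGGAATGCCTGCCATGCGGGGTGCCCTAAGCAGGACAGTTTCGGTGTACCGTCCGACAAGTAGGGGGATACCGCACGTTAGGTCCCTGAGTTCTAGGACCCCTTATGACCGACAATGCTCATATATGATCAGTAGTATCAATGTGACCCATATGCGCGGCTTATAACTGTAGAAATCTGGGTAGAGCTTAT
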