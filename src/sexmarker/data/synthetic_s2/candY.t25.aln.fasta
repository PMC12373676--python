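>candY.t25_chrX
TGGTACAAAGTATGCCGCCTATATAGGTTATTCCTAAGGTTCATACGTCTTTTCTGCAAGACAGTACATCGAACAAGAGCACACTGCATGGCGCATTCATTTATGGGCCTACCTGTTCGGGTATGCCCGCGCCTAGAATCTTTCAAGCTCGACCGCACGCAGCTTACCAGTCCGCAGTCTGTGGTTGGATTCGCTGGCTAAGGGACGATGGCAGGGTAGAGTGGTTCGAGACCCTGAGTTAGTGCAAGGTTGCGGACTTATTCCGGCAGTTCGTATTCTGCAGAACTCTTACGGGATGGAACTTGCTTCGTCCCACCGCCCTTAGGGCGGAACTTCGTGAACAGTGTTGAACCGGGTGACCGCAGCTCATCACATGGGCCCGCTAGCTCCTGCGGATGCCCTTGTTGCGTTTCAAGTGCGTGCCATATCGAACCTTATTTGAGTAACTCCAATGCTCCAGGAGCCGTCAGTTTTTAAGGACGAGTCTTGTCCCGTTGCTC
>candY.t25_chrY
TGGTACAACGTATGCCGCCTGTATAGGTTATTCCCAAGGTTCATACGTCTTTTCGGCAATACAGTCCATCGAACAAGCGCACACTTCATGGGGATATCATTTATGGGCCTACCTGTTCAGGTATGCCAGCGCCAAGAATCGTTCAGGCTCGACCGCACGCACCTTGCCAGTCCGCATTCTGTGGTTGGATTCGCTGGCTAAGGGACGAGGGCACGGTAGAGTGGTTCGAGACGCTGGGTTAGCGCAAGAATTCGGCCTGCTTCAGGCAATCCGTATTTTGCAGAAGTATTACGGGATGGAACTTGCTTCGTCCCACCGCCCTTGTGGCGGAACTTCGTGAACAATGTTGAACAGGGGGACTTCTGCTCATAACATAGGCCCGCTATCTCCTGCGGATGCCCGTGTTGCGTTGCAAGTGCGTTCCATAATGAACCCCATTTGAGGAGCTCCCAAGCTCCAGGAGGAGTCAGTTTTCAACGACGAGTCTTGTCCACTTGGTC
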