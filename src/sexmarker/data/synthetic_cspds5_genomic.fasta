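>cspds5_chrX
GAAGGTGTGCTGATTTACGACGCAGATTGGAGCGCGTCGGGGCTAGCCAGTTGTGGGCCGTTCTGGGAAAATGCCGATTGAGATCCGCAGACCATTTCTACCCGCAGAGTGCCCAGTATGGGGTTTAGATGCTGATTTAGCTATTAGATCGGATTATCATCCAGAGAATGAGTGTCAAGGCACCCTAGATTTGATAGTAGACCATGTGCTTATTTCAATGGAGCTTCTCACCCTTAGGTCCATCTCGCATAGAAACGTTATAACCCGTGAACGGGAACAAGGGTTGCTCGACTGTGTCCGAATTACAGATTACATTTTGATCTTGCACCATAACACAGGCGATAACTCCCCTCGCCGACCAGAGAGGGTCCGGCACGTTATCACTCGTGAGAAACATGTGCTCCTAAGGTTCCGGGAGCTGACTTGACTCACACTCGAAGAAGCATGTCCGAGCCGTCAACCCGAGGTAATCGCGTATTTACCGCACCCAACCAAGCTGTGCATAAGCATTCGCGGGAGTTAGGCGGTGCATTTTTCTGAGCCACCTAGCTTCTGATGAGAATATGGTAGGGTGAGAGGTGGTGAATCGTTAGCGTGAAACCGACGGTATTGTAAGTAGTCGACGTTATCAACGCATATTTAAGTTTGAGGACGGCTACAGCGCAAAATTACCGCTCTTCCTGAGCTTCACAGATGCAGGCGTTGACTCTTTCTCAAGT
>cspds5_chrY
GAAGGTGTGCTGATTTACGACGCAGATTGGAGCGCGTCGGGGCTAGCCAGTTGTGGGCCGTTCTGGGAAAATGCCGATTGAGATCCGCAGACCATTTCTACCCGCAGAGTGCCCAGTATGGGGTTTAGATGCTGATTTAGCTATTAGATCGGATTATCATCCAGAGAATGAGTGTCAAGGCACCCTAGATTTGATAGTAGACCATGTGCTTATTTCAATGGAGCTTCTCACCCTTAGGTCCATCTCGCATAGAAACGTTATAACCCGTGAACGGGAACAAGGGTTGCTCGACTGAGTTACAGTTTGGAATTCCTTTTGATCTTGCACCATAACACAGGCGATAACTCCCCTCGCCGACCAGAGAGGGTCCGGCACGTTATCACTCGTGAGAAACATGTGCTCCTAAGGTTCCGGGAGCTGACTTGACTCACACTCGAAGAAGCATGTCCGAAGCCGTCAACCCGAGGTAATCGCGTATTTACCGCACCCAACCAAGCTGTGCATAAGCATTCGCGGGAGTTAGGCGGTGCATTTTTCTGAGCCACCTAGCTTCTGATGAGAATATGGTAGGGTGAGAGGTGGTGAATCGTTAGCGTGAAACCGACGGTATTGTAAGTAGTCGACGTTATCAACGCATATTTAAGTTTGAGGACGGCTACAGCGCAAAATTACCGCTCTTCCTGAGCTTCACAGATGCAGGCGTTGACTCTTTCTCAAGT
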