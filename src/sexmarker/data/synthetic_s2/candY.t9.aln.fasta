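>cspds5_chrX
GAAGGTGTGCTGATTTACGACGCAGATTGGAGCGCGTCGGGGCTAGCCAGTTGTGGGCCGTTCTGGGAAAATGCCGATTGAGATCCGCAGACCATTTCTACCCGCAGAGTGCCCAGTATGGGGTTTAGATGCTGATTTAGCTATTAGATCGGATTATCATCCAGAGAATGAGTGTCAAGGCACCCTAGATTTGATAGTAGACCATGTGCTTATTTCAATGGAGCTTCTCACCCTTAGGTCCATCTCGCATAGAAACGTTATAACCCGTGAACGGGAACAAGGGTTGCTCGACTGTGTCCGAATTACAGATTACATTTTGATCTTGCACCATAACACAGGCGATAACTCCCCTCGCCGACCAGAGAGGGTCCGGCACGTTATCACTCGTGAGAAACATGTGCTCCTAAGGTTCCGGGAGCTGACTTGACTCACACTCGAAGAAGCATGTCCG-AGCCGTCAACCCGAGGTAATCGCGTATTTACCGCACCCAACCAAGCTGTGCATAAGCATTCGCGGGAGTTAGGCGGTGCATTTTTCTGAGCCACCTAGCTTCTGATGAGAATATGGTAGGGTGAGAGGTGGTGAATCGTTAGCGTGAAACCGACGGTATTGTAAGTAGTCGACGTTATCAACGCATATTTAAGTTTGAGGACGGCTACAGCGCAAAATTACCGCTCTTCCTGAGCTTCACAGATGCAGGCGTTGACTCTTTCTCAAGT
>cspds5_chrY
GAAGGTGTGCTGATTTACGACGCAGATTGGAGCGCGTCGGGGCTAGCCAGTTGTGGGCCGTTCTGGGAAAATGCCGATTGAGATCCGCAGACCATTTCTACCCGCAGAGTGCCCAGTATGGGGTTTAGATGCTGATTTAGCTATTAGATCGGATTATCATCCAGAGAATGAGTGTCAAGGCACCCTAGATTTGATAGTAGACCATGTGCTTATTTCAATGGAGCTTCTCACCCTTAGGTCCATCTCGCATAGAAACGTTATAACCCGTGAACGGGAACAAGGGTTGCTCGACTGAGTTACAGTTTGGAATTCCTTT-TGATCTTGCACCATAACACAGGCGATAACTCCCCTCGCCGACCAGAGAGGGTCCGGCACGTTATCACTCGTGAGAAACATGTGCTCCTAAGGTTCCGGGAGCTGACTTGACTCACACTCGAAGAAGCATGTCCGAAGCCGTCAACCCGAGGTAATCGCGTATTTACCGCACCCAACCAAGCTGTGCATAAGCATTCGCGGGAGTTAGGCGGTGCATTTTTCTGAGCCACCTAGCTTCTGATGAGAATATGGTAGGGTGAGAGGTGGTGAATCGTTAGCGTGAAACCGACGGTATTGTAAGTAGTCGACGTTATCAACGCATATTTAAGTTTGAGGACGGCTACAGCGCAAAATTACCGCTCTTCCTGAGCTTCACAGATGCAGGCGTTGACTCTTTCTCAAGT
>cspds5_cultivarB_chrX
GAAGGTGTGCTGATTTACGACGCAGATTGGAGCGCGTCGGGGCTAGCCAGTTGTGGGCCGTTCTGGGAAAATGCCGATTGAGATCCGCAGACCATTTCTACCCGCAGAGTGCCCAGTATGGGGTTTAGATGCTGATTTAGCTATTAGATCGGACTATCATCCAGAGACTGAGTGTCAAGGCACCCTAGATTTGATAGTAGACCATGTGCTTATTTCAATGGAGCTTCTCACCCTTAGGTCCATCTCGCATAGAAACGTTATAACCCGTGAACGGGAACAAGGGTTGCTCGACTGTGTCCGAATTACAGATTACATTTTGATCTTGCACCATAACACAGGCGATAACTCCCCTCGCCGACCAGAGAGGGTCCGGCACGTTATCACTCGTGAGAAACATGTGCTCCTAAGGTTCCGGGAGCTGACTTGACTCACACTCGAAGAAGCATGTCCG-AGCCGTCAACCCGAGGTAATCGCGTATTTACCGCACCCAACCAAGCTGTGCATAAGCATTCGCGGGAGTTAGGCGGTGCATTTTTCTGAGCCACCTAGCCTCTGATGAGAATATGGTAGGGTGAGAGGTGGTGAATCGTTAGCGTGAAACCGACGGTATTGTAAGTAGTCGACGTTATCAACGCATATTTAAGTTTGAGGACGGCTACAGCGCAAAATTACCGCTCTTCCTGAGCTTCACAGATGCAGGCGTTGACTCTTTCTCAAGT
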