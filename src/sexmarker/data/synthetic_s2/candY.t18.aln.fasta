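>candY.t18_chrX
TTTTATTCAATTGGTATTATTCCTTAGCCTGCTGTATTGCCGCTCTCGCGCTGATGGTCAGAAGGGTGAGAAAGTCAATAAGGCCCTCGAAGGGCGTGCTTTTTTCTCTGGGCAGGGCCAGCACACAAGTCTAGGAATCATCCGACGCGCTAACGTGGGAGGGCCCGTATCGAGTTCCTTTGTGACCGCTACTTTCAGACCCATCCTAGTGCCGGTGGAGACCGGTCGGTGCCCGCTATTGCTACGTTGAATCTGCGGAGACCTTACGTCCAAAATCTATCCCCTAGTGTCATCATGGGCAATTTAGAAATTGTGAAGCGCGTAGGCCTTGTCGCAGCGGGTTCTCCGGTTACGCGTCTCGTTTAACAGCCCCCTCTGAGATCTCCAGTGTGGGCTTTATCCTAGCGTGCAGGGCTAACTGATGGGGAGCTCGCTACCTAGCCGCCACAGCGGACAACATCAAAGACGCCTAAAGAGGGGACACGGGGAGGTTATGAAGG
>candY.t18_chrY
ATTTATTCAATTGGTATTATTCCTTAGCCTGCTGTATTGCCACTCTCCCGCTGATGGTCAGAAGCGTGAGAAAGTCAAATCGGCCGTCGATGGGCGTGCTTTGTTGTCTGGGCAGGGCCAGCACATAAGTCTAGGTATCATCCGACGGGCCAAGGTGTGAGGGTCCCTATGGAGTTCCTTTGTGACCGCTACTTTCAGACCCATCCTAGTGCCGTTGGAGACCGGTCGGTGCCCGCTCTTGCTATGTGAATTCTGCGGAGACCTTACGTCCAACTTCTATCCCCCAGCGCCATCATGGGCAATTTAGAAATTGTGAAGCGCGTAGGCCTTGTCGCAGCGGGTTGACCGGCTACGCGTTTCGTTTAACAGCCCCATCTGAGATCTCAAGTGTGGGCTTTATCCTACCGTGCAGGGCTGACTGATGGGGAACTCGCTACCTAGCCGCCACAGCGGACAGCAACGAGGACGCCTAAAGAGCGGCTACGGGGAAATTATGAAGG
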