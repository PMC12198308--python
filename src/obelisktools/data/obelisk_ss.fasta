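>Obelisk_000003|Obelisk-S.s
ACTTGGTTAGTCCAGGAACTGTAATATATTAGAAAGGAAGTAAACCAAACATGTTAGATTGGAATACCTC
ATCAGACATCTTCGTCGAGAAGCTTCTTCAGAGAAACTACAAGAGTCAGAGTCTGCACAGCCAACCTCGC
CATCGACCCCAAGTGGATGGAATTCCTTACGAGTTTGGATACAAAGGAACGATCTATCCTCTGAATAAAT
CACGAAACTGTATCATCATCTTGCTGTTGATACCCATTCTAGTTCACAGTACCAGAAATGCAGCCTACTT
CGAGAGTCTCGAGAAGAAAATTGTCGAGCAAGTGAAGCTAAACAGGGCTCAAGGTAAATGGCAATTAGTC
AGAGAACTTCTCGGACTAAAAGGCACTTTCCTCAAGCCCCGCTGGCAACACTTTGCGAAGACAGTTTCTT
CAAGAGACTTCTTCGGAAATTGGCTACCTCTGATGCTAGAAATAGAAAGGTACCTTTACAGTAAAAAGAT
GTATCCAGATTCATATTTATCCTGGGACGATCATTCTTCGTACCGAGTTCGCAAGAAAGTCTACCGCCGT
GGTTATGACGACAAGGGTAGCCGGAGACCTGAACACAAGTGGTTCCCTGAGAATGCCTTCTCTCGAGAAT
TGCTTGATGAAGTTCCGGTCAAACGTGCTGTTTACAAGCCGTTCGAACTATATCATGGTTACTCTGAAAA
ACGAAGGCGGAGATCGTCTCTAAGTTCTCTTCTAGATTTATAGGCAACGGAAAGCCTAAGAACTTAAGGT
CGAACTTCTTCTTTCAAGAATTTCCTAATTGGTAAATTCTCTCAGTAAATCAATAACTTATTTTCCTTTG
GAGAATTTGTTCCCTCTGAGGAAGAAGTAAAATTAAAATTTCGGGATTTTGAGGGACGGCAATCACGTCC
CCTTTTCTCTTTTCGGAGAAAAAGGGATTGGGATTACCATCCCCTTAATTCTGTAAATTTTATTTTACCT
CTTTCCTCTTAGGTTCAAATCCCCCAGAAGGGAAAAGTAGTTGACTATTGAAAGTCTCTACCCTATTGGG
AAAGGCTCGTCGGAAAACAGTTCTCCGAAAGTTCTCATGACATTCTGGTGTCACAAAGTCGAGATGAGAA
CAAAGATTCGTCTTCGG
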