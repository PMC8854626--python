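>synthetic_col4a4_like SYNTHETIC CDS
GTTCCAGCCAGTTTAACCATTGCCAAACGGAGATTTCAGTCGCAGTCCAATAAGATTCTTAGCGAGCTCA
AGCATCGTTGGCAGCAGATACGGTATCCACCTGCAACCGACCCCGGGTGTATAGGCCCGAGGGGCAATAT
GGGGCGCGCGGGTCCTTTTGGTCAGCTCGGGTATCACGGGTGCGACGGTCCTGATGGAATGGTAGGATCG
CCTGGGTCACCTGGCACAACGGGAAAACTTGGGGCCGCGGGACCTTTAGGGGTAAGTGGGGTATTTGGAG
ATTACGGCAGGATAGGCGCTTGCGGGCGATTCGGCTTACTAGGCTGCTCGAGATTCAGACCTGACGGGTC
CGACGGCCGTTGCGGCGCGATAGGAAGGAAGGGCATCGACGGTGCCGCGGGTGAGCAAGGACTCAGAGGC
ATTAGCGGTTTGACGGGCGTTGCTGGGGCTCATGGTTTGTCCGGATTACCTGGCTTTGCGGGTCAGCCAG
GCGTCTATGGTGTGGACGGGACTACGGGTTTGAAGGGGGCGCGGGGCTGTTTAGGATTCCACAGAAGACG
ACAGTGCTACTCTAGAGGCGTTAAGGGGACTCAGGGATCGCTAGGACCTATCGGGCTAGTCGGCTGTCCC
GGCTTTTTTGGGAGAGCCGGGCGCAGCGGACATACCGGGGTTTTGGGGTTTTTTGGTATGGAAGGCTCTC
CCGGAGAACCGGGATTCTATGGGGTCGACGGACTCGTAGGTCATGTCCGACCAAGTGCAGCTTTCGAATT
TAACGGCAGAGAAGGGCGTACTGGCCGGAGAGGGCCAAGCGGCCTAGTAGGCACCAGAGGTTACGCTGGA
AAATCCGGGCAGTTCGGCGCGATAGGCTCGTGGGGTTCGAGGGGTGATCCTGGAAAACCGGGCATAGCCG
GGCCGAGTGGGGAGGCGGGTCCAATGGGGACTACTGGTTTGAATGGCGTGTTAGGTATCACTGGACTCTA
TGGTATAAGAGGGTCCCCGGGGGCGACAGGAAGCGAGGGTCGCAATGGTCCATATGGAATAATGAAAATA
GAATATATGGGACCCACGGGTCTGGTAGGACGGCTCGGGAATCCCGGATGTCATGGTGTAACAGGTCCGA
GGGGTCTACTAGGTAAACTGGGCTATACCGGTAGACAGGGTGAGTTAGGGGAGAGTGGTGTCGCGGGTAA
GAAGGGGTTCCCTAATAGTCCTGGGACACAAGGCCACGAAGGTCTAGTAGGCTGGCTCGGGGCTTATGGG
ACCAGAGGTCTTAAAGGACCGGCAGGAAAGGTGGGGTGCATCGGTAAGGCCGGCATCCACGGTAATCCCG
GTAGTATCGGTGCCATAGGCCAGTACGGACACCCAGGATGCCATGGCGCGCACGGCCGGTCAGGTCCACT
AGGAATCGAAGGAGAAGTTGGGGTAAACGGGCTGTACGACGATAGAAGCAAGGCACGGTCAGCAGATAAC
AATGGTACGCAGGGGATTACAGGGACAACAGGTTCATTGGGTCTTAACGGTCATACCGGATGCACGGGAT
ACTACGGGAGTATAGGAAAATCAGGGGACCGGGGAGTCTGGGGTGAATCCGGACGCCCCGGGGACTGTGG
CCCTGTACTATTACATACGGGGGCGGAAGGTGTGGTTGGTTGCACGGGGTCTATTGGTTACACGGGGCCG
TCAGGCTTGGTAGGATTTTCTGGCATTCATGGTCGTATTGGTAGGAGGGGAGTAGTAGGCAGAGCTGGGT
CTCATGGCATCTCTGGCGATTACGGGTTCGATGGAACTTTGGGACTCGATGGCTGGGAGGGAACGGAAGG
CTGTTGTGGGCTGTACGGCTCGTCAGGCGACCTTGGATGCTATGGACATGCTGGGGTGAGGGGTAAACTG
GGGTCAACTTTAAGAGGAGACAAAGGGAGATCGGGGCTGAGCGGTAACTTGGGGCACAGTGGAATACCGG
GGAGACTTGGCGCTAATGGCAATGATGGTGCACAAGGACCGGACGGACGTTTTGGGGTTCGAGGGTTTCA
TGGGTGCAGTGGGTTACAGGGATCCCAAGGATACTGCGGGGCCAGGCCTGTGACGCACTCTGAGGGTCCG
GTCGGCTCCGATGGAACAGAAGGGCAGATTGGGAATGATGGAGCTACGGGAACGGACGGGGATACGGGAG
AGGCTGGTCGGAAGGGACCCAAGGGTCAGCCAGGCCTAAGAGGCTTGGTGGGCGTGAGTGGCCCCAAAGG
GTCTCCCGGACAGGTAGGCTCTATGCCCAACGGACTCCCTGGGAGCCACGGACCCTGTGGATCGTCTGGA
AAGCTCGGGCGTGCCGGACGGTTGGGCAGAAAGGGACATTGTGGCGACTGCGGTCTAAACGGACATAGTG
GGTGTCGAGGATTGCTGGGATCCGTGGGCCTCGCTGGATGCCATCTTATGTCGTCACTCCATATCGCTTT
AGGTAGTTTAGGGCAGGCAGGCACTTGTGGGACCGTGGGCACTTGGGGGATGTTTGGCCCCAAGGGATAC
ACGGGCATCCCTGGAACACCGGGAAAAAGCGGGCCAATTGGAAGACATGGAATCTCGGGTGCAATCGGAG
ATTTAGGGTGGGCTGGATCTATAGGTATGCAAGGACGCAGTGGCTGTTACGGCATGTCGGGCTCGGTTGA
CCGCCAAGGGAGCGAGGGGCAAGCAGGCAACGAAGGCCGGGCCGGGTTGGCGGGGACTTGGGGACCTACC
GGGCAGAGAGGAGTACTAGGACATGAGGGAAATTCCGGAAATTCAGGGCCTATAGGCGTAACCGGTTGGA
TTGGGGTATTTGGCTACGTGGGGACGTGCGGACGGCTTCTACTTCCAAAGGCAGGGATTCTGGGAACGAA
AGGGTACATCGGATGTATTGGGTGCCCCGGACGCAGCGGCTGGCGTGGGGCGCTGGGTGCACGCGGGTCG
GCAGGTCCGTTGGGCGATGTAGGGTATACCGGAACCAAGGGTAGACTCGGGGTTCCCGGGTGGTTTGGAC
AGATTGGGACGGTGGGGAAACCTGGGTGGAGCGGACCCGAAGGAGCAAACGGGATCACGCTATTAGTTCC
GCTCGGGTCGGTCGGATTAACCGGCTACTGCGGCAGGAGTGGAACTACTGGACGCGTCGGCAGCCGTGGT
ACTCTTGGAAAGAATGGCCGGATTGGTCTTTTAGGTTGTGACGGCTTCCTTGGGTACGTTGGTTCCTTGG
GCGTCCTTGGACCACCCGGTCCGTCCGGCGAGCACGGGAATATTGGGCCGTGTGGAAGCGCCGGTACGAT
CAGTCCCGCTTCTCTCGCTGATCCTAATGGACCGCTAGGTGACCGGGGGTACCTGGGCTACTCTGGACCA
CGCGGATCTAACGGAAAGTTGGGCGTATGGGGTATATGTGGCCTTTGCGGTTTCCCCGGTACGCAGGGTG
CAGCTGGAGCGGAGGGCCTTTGCGGTTTCCCTGGCCCTGTAGGCGTCTGGGGCTGGGCTGGACGATCTGG
GATCACTGTATCCCTCCCCTTCCGGAGGGAGACAGAATCGGGGCACGCAGGCGAGCCGGGTCACCCCGGG
CGGGAGGGCTTAGTGGGTTCTTGTGGTGTGGTAGGATCAAAGGGTAAGACGGGCCGCCCCGGTATCTTGG
GAACTAACGGAACGGAGGGGTTAACCGGTCTCCGGGGTGCTTATGACCGACGGGTGCACACCCGTTTAGC
AGGTCTTTACGGTAAAGCGGGGACCGCGGGGTTCTTGGGTTTAATGGGATGTAGTGGTCCACGAGGACTA
GCAGGCGAGATGGGCATTGTGGGCACTGCTGGTCACACCGGAGTAAGGGGGAACCCCGGTTATGTGGGAC
GGATGGGCAGAGCCGGCATAAAGGGCCCAGTTGGGCAGGTTGGCTTGACAGGATCTATACATCCTCTGGT
ACCAAGTCGCTCGGGTTGCGAAGGGCAGGCCGGACACACTGGCCACCACGGCTTCACAGGCAACACGGGG
GATACGGGTAGCGACGGGCGAGTGGGTACTGTTGGAGCTGTCGGCTTTAATGGTGCCGCGGGGGTGTGCG
GTGCTCGCGGCGTCACGGGGATAACTGGCTTCAGCGGGATCTCGGGCTTCTGTGGATCAGAGGGCCTCAG
GGGACATTCTGGGTGCAACGGACTACCCGGTGCACTTGGATATCAGCTCCGCATTACGGGGTTTTGGGGT
GCTGAAGGGCATACCGGTATCAAAGGCGATGACGGCGTCAACGGTGCCAACGGACCTCCTGGGCCTAAGG
GCAAGCCCGGAAGGATAGGTTCGAACGGGCCCCATGGGTTGTCTGGGTCGGATGGCACTAACGGGTGCCT
TGGTCAGGTGGGCTCGCGTGGACTGGACGGAACAAAATGGCAATTACTAAAGTACTCTAGGCCCGGGGCC
GACGGCGCCCCAGGCGTGAGTGGCAAGTACGGGCTGAAAGGGAGTGTGGGACAAATAGGCGACCCGGGAC
CCAACGGTAGAATCGGCAGGATTGGGGCTTCCGGAGCCAGAGGTAACGACGGATATGCTGGTCTAAACGG
TTGTTACGGTTGTGCAGGTAGTCCTGGAGCAATTGGCCTTGCCGGATTCACTGGATGTCCGGGGGCAACT
TGCCACCAACATGATGTTCTACAGTCGGACGGGGACTCTGGGGTCCGCGGGCTCGTCGGGGCCCAGGGTC
CTCGTGGTAGCGCGGGTAGTGCTGGCATCATAGGCAGGCGGGGATCTTGTGGCAACAGAGGAATCTTAGG
ATATTCTGGACCGGTCGGGTCATTCGGACGCAATGGAACTCCCGGTCGGGTCGGAAGGCGGGGAAATGCC
GGGGAGAAGGGGGAGACGATATGTGGCCCGCCTGGTCAGCAGGGACTTTTAGGGTCCTTGGGTTGGTTGG
GGGCACTCGGACTTACGGGCACCATTGGCGTCTGTGGAAGGATTGGTGTGCGTGGTCTCTTTGGGAGTGC
TGGATGGTCCGGCTGGCACGGGTGCCTGGGCATTGTTGGACATACTGGACGCTTTGGTATCCAAGGGAAT
AAGGGGGCCCTAGGTCCCCTCTTACTGTCAGCCGCACCCGTGATACTCTTACCGCAAACATCTCACTCTG
AATCTCGTCCGGAGTCCCACTTGGCTGAAAACCCGCCTGCCTCGAACCAAAAAAAATGCTTTGATCCGGC
CATATCAAAAGCGGCGTGTAAATGGACGAACGCAGCACTGTGTCTCTTATGTTTCATAGACACAACTTCG
GTGAACGAGCTCCTTGCATCCTGTGCTTGCCTAATCAATATCGTACTGTATGCAGTCCGCGATCGTCCCC
GCTCGCTGTCAACGGATGTACATTCGTTACTGTCCCTGACCATTTACAAGATGTCGCACTATATCAGCGC
AAATTCACAGCATTGTGACAGAAACCTAATAGTCGTCTTGGAGCCATCCCACCGTCCCGCTGTTCAGAAA
CGCGCGATCCCCTCTACGCATGAGCGTTTCCCTCATGATCAGACGGAGCGTTTACATGCACCGACGACCC
ACACGAGTTTTCTTAGTCTCTGTAGTAATCTAGCACTCACTGCTCTTGTTTTTCGCCACCATATCAGAAA
CCCGAGAAGGAAAGTAATGAATATAAGCCACTTCTATAGGACCGCGGAGTCTGAACCAACACCCAGTTCA
TTCATGATCGCTCCTATTTCTTCATGCTCCGATGATAATTCGCTAGTACCGATCGTATACAGGAGTACTC
CAAAACCT
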