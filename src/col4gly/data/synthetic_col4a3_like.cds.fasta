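>synthetic_col4a3_like SYNTHETIC CDS
GAGATGTTGTTAAATAGGAGTAGGGACCATCGTATCTTCGCGGCCACGAGCTGGCAGTCGTACAAACGGC
TGCGGACGGTCGGCCCACCTGGCCGCTCCGGCGTGTGTGGAATGCTTGGAGCTGCGGGGTTACGAGGTTT
GTGCGGCAATTCTGGTCAGGCCGGATCTTCGGGCTACATAGGTTATTCAGGGAAGTACGGGAGTTCGACT
CCGGTTTACAACGGCTTAGAAGGACATGAGGGACCTATGGGCGCAAGCGGTTACGCCGGTACAGTCGGTG
AGCTTGGGGTCCTGGGGCTTGTCGGTTCACAAGGTATAGCCGGTTTGTTAGGTCGTACGGGTTCAGTGGG
GTTCCCAGGATTGTGGGGGCTATTCGGCTTCGCTGGTGATCAGGGCGATCAAGGATGTTATTCACGGGGA
TGGCCTGGAGTTCCAGGTGAGTTCGGAATCTTGGGTTTTGCTGGTAATTATGGAAAGAGGGGAACACCTG
GGGCGCACGGCGCTGTGGGAGCTTCTGGAGCTATGTACATTGAGATTCGGGTCAGTAGGTTATATGGAGA
ACTCGGCACGCGCGGAGAGGCTGGCTGCGTAGGCTGTTATGGATCGCGAGGGATTTACGGTCAACTAGGA
ACGAGGGGCAAACCGGGAGCGGTGGGCTGGACCGGAACTGTCGGGTACCACGGGTTTCTAGGACGTAATG
GGCTAATCGGTGTGGAAGGACACAAGGGATTACGGGGATACAGTGGGAATGTGGGAGACACTGGCTGTGC
CGGGTTACCTGGCAAATCAGGTCTCCGTGGATCGGTGGGGGCGACATTGACAAGCGGTGAAATAGGCAGA
GTCGGCCTAATGGGGATTCATGGTATCCGGGGCTTTATGGGATACCAAGGATGCGTAGGCATAGTTGGCC
GATCCGGCCTGTGCGGCCACCTTGGGAGTGAAGGTAAGATTGGATATATCGGGAAACCGGGGTCCGAAGG
CCATATTCCTTGGAAGTCACCGAAATCCGGAAAGTTGGGGCCAGCTGGCATAACAGGCACTAGGGGCGAA
AAAGGCTCTACTGGTCAATATGGAGCTTTTGGGGAGTGGGGCGTTCGTGGCGAATGTGGTATGCCCGGAA
ATTGGGGACTCAAAGGTAGTTTTGGGACGATGGGCTCCACCGGTCGTACGGGGTATCACGGGAGGTTTGG
GAGGAGAGGTCTCCAGTCTAGTGGTATGTTCGGTCTCCGTGGGCGAATGGGTAACTCGGGGTGGTCAGGA
ACATTTGGCGCTATCGGTACGTATGGCTGGCTTGGTCAGGCAGGCACTGTTGGGGTAAAGGGTCATGAAG
GCAATCAAGGATATGAGGGTTGTTGGGGCGATGTGGGTCTAACTGGGCATAAGGGTACACGCGGTCTATT
AGGTGACATAACTTCTGGTGTGGCGGGATATCGAGGTTGTAGCGGCAGTAAAGGTAGCCCTGGGCGGACC
GGCAATTGTGGATGCTCCGGTTTGGTGGGATTCCTTGGTGCGAGTGGAAGCTGCGGGGTGCGAGGGGTAC
GTGGCTATATCGGTCCTCAAGGCATCCCCGGTGACCGTGGACCTGCGGGTCCGGTCGGAGTGGATGGTGC
TTCCGGTGCGCCCGGTTCGTATTTTTCCAACTCCCAGAAGGAATTTAATGTTCTTGGAGTCGTCGGGGTA
GCAGGCCGCCACGGGCTGGTCGGAATACCGGGGGATCTTGGGTCACTGGGATGCGCAGGTGTCTGGGGCG
ACAGTGGACCAAAGGGCGACTCAGGGTCAAAAGGTAGACGTGGTGAAGTGGGGTGGTGGGGCTACCGAGG
TGACCTAGGCCCCAACGGGCGGGTAGGGTTTCCACTCTGTGGATTAGAGGGACGTCCTGGGGAGCGGGGC
GAATTGGGACACGCGGGTAAACATGGATGCACAGGACTGTCGGGGTCCTTCGGGCACCACGGTCCGCGAG
GACGAATTGGGCTCAGAGGGAGTCGGGGGTCTGTAGGAATGTACGGTTCTCCAGGCTTCAATGCGTCAGA
AGTCAGCCGTGTAGGTCGTATGGGGGTCAGAGGGATACCGGGCTACACGGGAACGCACGGTCTATTCGGT
GCCGTTGGAAATTGGGGGACGACTGGTCCGCGTGGTTACATTGGGACCAATGGTCCTATAGGGGACACGG
GCTGTTTAGGTGTGGCATATTCGACCCGCCCAGCAGGTCGACAAGGAACGTGCGGTCGTATTGGTGACTT
TGGAGCGACGGGGCTACGCGGGCGCGTTGGCTTAAATGGGCAGGCTGGCCACAAAGGTCCTCATGGGAAG
GCGGGAATCAGAGGAGCATCAGGACGGCGCGGACAGTTAGGTCAACAAGGCATCTTAGGCGTTAGGGGAG
CCGTTGGGACCGCTGGTACGGAGGGTTGGCTGGGTTTGGAAGGTGACAAAATAGAGACCGGCATTGCTGG
AACTACAGGGCGCGTTGGTGAAACTGGCGAAGTGGGGTTAAGGGGCAAGACGGGGCCGGTCGGCGTGCCG
GGCTTCCTTGGAACCAATGGTAAAACTGGCGATATTGGTCGTAGTGGGACCCAGGGTACTCACGGTATAA
GGGGTCACACTGGAGCAGAGGGTATCCCGGTGCCCCGAGTGTCCGTCCATGAATACGGAACACACGGCGC
CCAGGGCCCTAGCGGACATCAAGGGTTGAAGGGAACTCTAGGTTGGAGTGGCACACGCGGGCTCTACGGA
CTGAGTGGAGCTGCCGGGCGAATCGGGCGTAGTGGTGACAGTGGATATCAGGGTTTTCTGGGGAGCTTAG
GCCACTACGGCGCCCGCTCGTCGCTAATAAAACTTAACTACTATTTAGGGTTTTGGGGATCGTCCGGGCA
TGACGGCTACAACGGACGACCCGGGGCATCGGGGACTAGCGGACAGCGCGGATATTCCGGCAGGGCCGGG
CACAGCGGCACTACTGGACGGCCAGGCTCCGTGGGTCGACTGGGTTCTCATGGGGCTTTCGGCAGTTCTG
GCCTCATTGGCTCAGACGGTATTTACGGTTTCAGAAAATGGAGCTCTAGAGATCAGATACCACGTCCGGC
CGGATTGCTCGGTGCCACCGGTCATAGAGGTTTTCGTGGCACTCCTGGGTGGCCCGGAGCACGAGGCCCA
ACGGGATTCAAGGGTAGTTGGGGGGCTAAGGGCAGTCGGGGTGTCCGTGGAATTTCTGGTTTGGTAGGCC
ATACCGGTAAGAAGGGGCAGTGTGGTCAACTGGGTACCTCAGGATTTTTAGGCCCCGCGGGTATAATGGG
TGACAATGGAGCCTCGGGTTATTTATTGCTCCTACGTGGTAACACCGGTGAGATAGGGCTCGTGGGTATT
TTCGGATGTGATGGTGTTTCAGGGGTCAGGGGACCTGATGGAATCTGCGGTGCGACAGGGCTGGTCGGAT
TTCTGGGTAATAAAGGCAAGGCCGGTCGCCCCGGTGTCAAGGGCCCCTATGGCGTGAGGCAACCCGTCAT
CAACTTAAAGACCCTCGTCTGTACAGGTATAAAGGGGCAGTCGGGAGTCTGCGGCCCGTTAGGCACTCGA
GGTCCCGACGGGGAGACAGGAACCCACGGCCTCACGGGGTTGCATGGATTCTGCGGACACACCGGTGCAA
GAGGTGAAATGGGGAAAAACGGCCTTAGAGGCCTTTATGGACCAAATGGCGTAAACGGCGCTTATGGTAG
GTACGGTTATTCGGGTGTGATCGGATTAGACGGAAGACGTGGTTCATACGGGACGATCAGTCAAGGTCTG
GCGGGCCCTAGAGGTATTCGGGGGAAACGGGGTCTCCTAGGAGCCAACGGTTGGCGGGGTTGCCTAGGAG
CCTCTGGGCGCCGCGGGACCGATGGATCGGTGGGATCATGGGGAGATTCAGGTAACGTGGGTGTGCTAGG
TCTATTTGGTATAGTGTCGCTGACCGGTTGTCGCGGTCAACCTGGTCTCTCAGGCGATTATGGCTACTTT
GGTTCACAAGGAGAAGCCGGTGACGTCGGAGATGCGGGTACAAATGGGGCAGCAGGCTGCCTGGGCTTAG
AAGGTGTCATGGGAAGCAGTGGAGAGCCCGGTAGTCGAGGCTTCACAGGTAGGCCGCAGCCAACGGCCTT
GGCCGTTTGTGGAAGTAATGGTTGGCGTGGCCACCAAGGCGCGATAGGTCAAATGGGTTCACCAGGGTGC
GTCGGGCGGCCGGGTCCGAAAGGGACGGAGGGTCACTGTAACACGGAATTGCAGTTTTACCCATGCGAAC
ATGGTCCAACAGGTCTATATGGCTACCCAGGATGCTGTGGTGACTCGGGCTACATCGGTGCTTGCGGTGA
ACCTGGTGTTCCTGGGGAAATTGGAGCGTCTGGAGACCTAGGACTCTACGGGGAGGTTGGAGAACGTGGA
CACACTGGGGATCTTGGTGACAATGGATATCTTGGGGTGGCGGGTAACGAGGGCCCTTTAGGCAGAATGG
GAACACCGGGCCGTACTAAGATCACACACGACCTCAAAGCTATCAAGATTGGTATCCCAGGTTGCAGTGG
GGCCGCCGGAGCATGTGGTGTGTTGGGATCGGAAGGACTTCTGGGATGGTCTGGCATGTGTGGGAGCACC
GGACGGTCGGGCCAGGTAGGTATTTTAGGATACATTGGCAATTTAGGTCACCATGGATGCTGCCTAGCTT
TAAGTCGTGTTAGGGTAATCCTTCCTACGACGAGCGCCCAGAATATCCGGTACCTTGCATTCCCTCGACA
GTGCGAGCTATTCGATCGTTCCTGTCTGGTTTTCAGGTGCCGACCGCTGGTGAGAAGCGCGATCCATTCT
GTTCAATCCTTACAAAGCGCTCGTTGCAGGTGGGTCCCCGCGTGTCACGTTAGCGCTTTACAAGCGATGG
AGATAGTACTTAAACCTACCATATCGGTTCATTATGTGTCATGCTGGTTATCATTTTTCTGCGTGCAAAG
CTACAGAGTCCGACCTGACTCCAGGCGATATAGCTACGACTCCACTCGGTTACCGACCCCTCACCCCCCC
TGCACGCGTCCTTGTCGCACTAACAATACAAGGCTAACACACTCATCGCGAAAGGTGTGTATAACGATCA
AGACGCTCATTTGTTCCGAGCACAGGTGGGACCGACTCCAGAAGGAACTTCAATATAGCTACCAGCAGAA
GCAATACCCTTTACTTCTTACACTTAGCCTCACTCGCGCATGTGAGCGGTGCACGATTCGGCCAAAGTTT
GTGCAGGCAGCAATGAGGTCCTACTGGACGGATTCACCTCATTATGCGCGAGTCCCCATCGCCATTCCCA
ACAAGCGAAGTCCTCGGGAAACAACTGCCATGTTTCATAACGCCCTACAACACGTGCCACTC
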