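>synthetic_col4a5_like SYNTHETIC CDS
TCCATGACGCACCCTTCACGCACCCATGAGTCAGTCTTTAGGTGCAATCTTATTAGTGCCCACGAAATGA
GAGTGCGAGCGGGGTTACGAGGAGCATTAGGTTCTGCGGGCCCGAAGGGACAGCATGGGCTCGCTGGTTC
TTACGGTCAGTGGGGTATACGGGGGGCTGCTGGACGTACCGGTAGTCGCGGTCTCGCGGGCTCGGACGGG
CGCCCTGGGCTCTACGGGCGGTCTATACGACGTTGCCGCGAGACATCCCGCCTAACCGGGGCACATGGTC
TCAATGGAATGACCGGGAAGCTCGGGGACCGGGGCTGGCAGGGTCGCCCCGGGTTGTACGGGACGGTTGG
TCCTCCAGGATTGAGCGGCAGGTACGGGAGCACGGGAAACTCGGGTCCCACCGGCCGCCTGGGCGATGAT
GGGCTACGCGGTTCAGTGGGAGAATGCGGGAGGCTAGGGTTCCTTGGAACGGCTGGTCTTACCGGATACC
AACGTTGTATGTACACAAAAAACCAACGTGGAGAGTCCGGGACGTCAGGACTCTTGGGCCGCATGGGCAT
CAAGGGGCCGTTTGGCTACCTCGGGAAATCTGGATTCAGTGGTCGCGTTGGCATGGAGGGACAAGCGGGT
CGGTTCGGCAATGCGGGATTGGAAGGTGTTGCTGGATCCAGGGGACGGACGGGGTTGTGGGGTTCTATCG
GTATGAATGTTTTGTCAGATGGTACAACGGGCACAGATGGACCCCTCGGCGAGTATGGTTCAGTGGGGGA
CTATGGCCCTTCCGGTCCCGAGGGATTGTCAGGACCCTGCGGGCTTACGGGGGATAGGGGCCTTCTTGGC
CTCACGGGGAAAAACGGTTCAGCGGGCAGTCGAGGCAGGCGGGGGTCACTGGGAACGTTGGGATTAGCAG
GACGAGCAGGGCCACCGGCTGATACAGTCCGGTCGGACCTGGATGGCGCTCACGGTGTAATCGGTAGATG
TGGCCCCGAAGGATTCTCGGGGACCGTGGGCTTGTACGGCAGTATGGGGCGACGCGGCTCTGCCGGATTC
AAAGGAAGCCTCGGTGCGACAGGCCTTTGTGGAGTGCGAGGTTCAACGGGCAGTAGGGGATCCTCCCGAT
TCGTTAAAGCGTACGGGGTCCTTGGTTTCATTGGCGTAATCGGAGAGACAGGAGTGGCAGGAGTCGCTGG
GCAAAGTGGCAGGTGCGGTATCTTTGGCCTACCAGGTAGGATCGGCCGTAGGGGTTATGCCGGGTGTCAA
GGATTGAATGGCACAGCGGGTGTCTCGATTACCAAAAACTGCATCTTCAGAAGCATTAGAGGGCGACAAG
GGTCATTTGGTTTCTCCGGTCATATCGGTGAGGACGGCCCTATCGGAAATAGGGGACAGCCAGGGACCAG
CGGACTCAAGGGTGATATAGGCAGAATCGGGCTGTGTGGCTCTGCCTCTTTAATCCCATATGCAAGCATA
CACTTAGCCGATGGTAGCTTGGGCTTCAGCGGGAGGTCCGGCGCTTCAGGCCGGGCGGGCCTGCCTGGCA
TTACGGGGCTGAATGGTCAAATAGGCCACAGGGGTGTGGACGGAGCACACGGCAATTTCGGTGATCCAGG
CGCCCGCGGACATAACCGACAGATGTACATTGGTGAACATGGCTCGAAAGGAAGTCTCGGCATGCCCGGC
CAGATAGGCTGCAACGGCTATTTAGGTACGACTGGCAAACGCGGGGTAAGAGGCAGACTAGGAACATTTG
GCCATGTCGGGACGCGAGGCTTCATCGGAAGCAGAGGACGCTCAGGCGCTAACGGCAGTCCGGGGGTCTC
CGGGGACTGTGGTTGTGACGGCCAGGCCCTGCTTAAGCACTTGCGCCGCGGGTCGCTTGGGGCAGCGGGC
ATTTTCGGTTACGATGGACCCTCAGGATGTTTCGGTAGGCATGGACCACGAGGATACAATGGACGGGAAG
GTCATGTTGGGGCCGCTGGTAACGCCGGCATACTTGGTTACCCAGGGTGCGTCGGCAGTACCGGAGTCTC
TGGACCGTCTGGCCCTTATTACAGCAAGTCCGGGAAAGCGGGGACTTCGGGGCGTAGAGGACACCGCGGC
TGTGATGGGACTATTGGATTTTACGGCGTAGACGGCGTCCAAGGGGCTTGCGGCTTTCACGGTTCTGTGG
GACGGTATGGGGATAAGGGGAATGCGGGTGTGTCAGGTCGTTGTGGTATGTCTGGAGTGTGGGGTAGTAG
TATAATATATTCCTTGCGGTCGGAGCTCGGGCCCAGTGGTACTGTCGGAGATAGCGGATCCAGTGGAAAA
ATGGGTAGAATCGGCAGCTCGGGGCGTAGTGGACTTTTTGGTGAGTCTGGTATCGACGGTTTCCCGGGTC
TCCCCGGCTATTTTGGGCACCCGGGGTATGATGGTGCTCGGGGAGCACTGGGATTTCAAGGGAGCAGTGG
GAAGCTTGGCACAGTGTTGAACCCTAAGTGTGCCCCGTGCCTAGGCACAGATGGGATGCTCGGCCAACGT
GGCATATTCGGCCCTAGAGGGTGTAACGGGCCCACCGGAAGTTTCGGTGCACCCGGTATGGACGGATTGG
CGGGCGAATCAGGTCTGAGCGGCGTGGTTGGTTCTTCAGGTGTGCGCGGCTCCAAGGGGGCACGTGGAGT
CACAGGACCTTGGGGAACACGCCGCTCGATGAGCCCCTATGTATTTCATAAGTTCGGCCACGTAGGAGTC
ACAGGCCAGTCAGGTCCCAAGGGAACGCTCGGGGAGCTAGGTCCAGCCGGCACAATGGGGCAGCATGGGG
TAACAGGAAATGCCGGCTATCTAGGAATTAAAGGGTGCAATGGTCCTAGGGGTTGTCTCGGCTATCTCGG
TCGGATTGGCATGTGCCTGGAGTTGTTAGCAGATACCTGTCCGCTCGGCCGTGAAGGGGTGAAAGGGGTT
TACGGATCTTTAGGGAAGCCAGGGCGTGTTGGCCTGATTGGACCCTCAGGTCAGGCAGGCCAGGCTGGAT
TGTCAGGAACGCGAGGCGCGTATGGCTCCTGTGGCGAGCCGGGACGGAGAGGTAGAATCGGCAAATGGGG
CACGAATGGAACAATAGGAGAATTACGAGAGCCTTGGAGATACTCACATCGTCCTTCTAAAGGAATGCGG
GGCCCAGTGGGTAGCGCTGGGCTCTTAGGACTTGCGGGCTGGCTTGGTCAGTTGGGCGACAGAGGCTTGA
TAGGGTATACTGGTCCCGCAGGGTACATTGGCATTTCGGGCGCTAAAGGAGCAGACGGCGCCCCGGGATG
TTTAGGGTATTTAGGAAGTATAGGAAAATTTGGTAGCAGCGGTTCCATGGGGTCCAATGGTATAACAGGC
CGGGTTCTTCCACATAGATATTTAGCCCTCACCAATGAATTGGGTGCGTCTGGCTCAAGAGGTGCTTCTG
GATCTTTAGGTGTGTCTGGGACTGTTGGATCTAAGGGCCATTCAGGAACGCCTGGGTTCGTGGGAATAGA
AGGAACTTGTGGGTGCGCGGGAAATGACGGCAGGGAAGGATTCTGTGGAGCCGAGGGTAGTCAAGGATAC
GATGGGAAACATGCTCTAGCAATGTCCGACAACAGGCGTCGCTATGGTGCAGCCGGTGAGGAGGGAAACT
CAGGTGATGTTGGTAGATTAGGGTTACGGGGGGTAGTTGGAACCTCCGGAATTTACGGGGCGAACGGTTA
TCACGGGCTACGAGGTCGAGAGGGCTCGCCGGGCAGTTCGCTTTCTCCCGGTTCCCCGGGCTGGACAGGC
GCTGACGGTTTGGAAGGGACAGACGGTCCAGCTGGGTCTCGTGGAGCGAACGGGAATCAGGGAAGGCCAG
GTCTTGATGGGAGCTTCGGCCTAGCCGGCATCTATGGTAGACTGGGGGCGCCAGGGAGAAGCGGTTTATC
TGGTGATAGAGGCGAACAAGGGCATCACGGTCCCCTTATGTACGGGAGACGAGGCACCTTAGGAACCAGA
GGGGATATAGGGGAACCGGGCCTTGCAGGGGCTATAGGTAATCCCGGTAACAGGGGTATCCAAGGGCAGT
TTGGAACTTCGGGCCGTTCGGGGACAGTAGGCGTAGAGGGTTCCTGTACCACCCCTCCCGACTCGCTTGG
GCTGCTCGGTGACTTTGGCAGTGCCGGCAAGCCGGGGACCCCAGGATCAGAAGGATTTATAGGCGCAAGT
GGTGATATTGGCAGCAAAGGAACCGATGGTTGGACGGGGGCAACAGGCAACGTTGGGCTCCGCGGACCCA
TAATGATCAACATCGTGGGCACACACGGGGAGGCGGGGGAAAATGGACCTAAGGGTGAATTAGGACAGTC
CGGAGCACAAGGAACTAGAGGCTACTGTGGGTCTTGGGGCCAGCTTGGAGCTTCCGGGGAGGCTGGAGTC
AGGGGGGAGACTGGAGCTTTAGGGTTGAGCGGAAGTGCGGGGGTTCCCGGTTCATTCGGCCATGCCGGTG
ATCCGGGAGAAATTGGGCCAATCGGCTGCACCGGGATCCATCTGCCCATAAACGCAATTCCTTTGCGGCG
CAGTGGTTACCTTGGACGGTTAGGGGACCAAGGTAAACTTGGCCCACATGGCCGTTGTGGACTCGCAGGC
GAGAGAGGGAGATGGGGCTACCGCGGGTATAAAGGAGTGCGCGGAACTGTGGGCGTACTAGGGTCTTCTG
GACCAAGCGGCGTAGCCCTGTTTACACCGGCGACATTCTACGTGGCGTTTGTAGTGAGCCAGGTCTATAA
AGAAACTACCCAACCAATGTTAATTGCCGTCCCCATGGTAAGCGCGTGGAGCGACCGGGCCTATATAACG
CAACTTAGAACGCCCATTATCGTTACTCCATTGTCATATGTCCACGCACGCAGAAAACGCCAATGCCGAG
CACTTAATGACCTATTTCGGCAGCGTTCCCCTTTCTCAACACTGCTGTCGTCATTCCGATGGTTAGTTAG
TAACTCCAAAGCCAGCGCTCTCACACACATCACTTCTTGTACCCGATTGAGTTTGCTCTATTTGGACGTC
AAATGTAGTACGCGTGTGCTCCATTCGCCACCGCGGTACCGGCCTTATTGCCAAAATCGGCCTCGAAGTG
ATGATCTTGTGAAGACTTCGACAGCATTGAGAAATCTAGCATGGTATTGCAGGCCTATTATCAGATTCCT
TGTCAAGGCCCATCCTATTTCTAGTAGGTACTCCGACTATAGCCTCATACCACGTGCTATTCCGCCCCCT
GCAATTTGCTACTTTAGACCACTACTACGCATCTTTTTGACGTTTGAAGCAATATCCTTCGTCACTAGCT
GTTCAGCAGTAAGGTGCCCTCAAATTGAGCGTATATCCCGCCGTGATTTTCGTTGGCGGATAGCCACTCA
AGCG
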