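>chrS
GCGGGTTTACCTACCCATGTCAGTGTAGACACTTCGGCTCGGCGAGATTAGACGCTTAGC
AGTTGAAAATCCTCGCGAGTATTATCATTATTGCGCGCATGAGGAGGAAGCCCCCCGCAG
GGTTAATATAAAATTTAACATATTTCCTAGGCCCGCACGCGTTGATGAGGGACGGGAGAC
GTCATGACAATGCCGAAACAAAAAAAGGATAGCGATGATCGACTGGAAGTCGTGCTCGGC
CCGAGGCCCCGCACTAATGCAAGGATATCTTAAAGCTGAAGCTTCCTTAATGCAAACCAT
ACCAAATATAATAGTAACTCAATTGGCGTACAGGAACATGTGAGTGCGCCGTGCGATATG
CCTACCTTTTAAAAATGGGGATTTGTCGAGCCTCGACGTGGAGTAACCAATCTATTAAAA
TCGACGGACCCGGTCTAATAGTAGGACCGCTGGACGAATACGATGACACCATAGCTCTGC
AGCCACCGACGCGCCTGACACCCTATTGTGAACGCGATAATTTCTAGCGCGGGTTCTACG
AGTCGCACTCACCCCCCTAATTCAGCAGTCCATAGCCACGCTGACGGACCACTACGAGGA
AACAATTATGCGCCCTTCCAATTGCTTCTGATTACTCCGTGTTTACCCCGTGCCTCGGGA
TGGCTGGACACCGAGTCGTCCAACAGTGTGCAGAACCCGAATTTTTGCGGGTCTATGGTT
AGATGATAACTCAACGATACCCGGGCTGCTACAGTGGTCAACACTATAGAACGATCCCGC
ATCACGCGACCGAGTGTGAGGCTTGAGTTTTCAGCGGAATGACATACGACAGCGTTGATA
CTTATAACTAAGCGGGAAGGTCACAGTTAGGACAGGGACAGTGACACGAGATGAGTCAGC
GTATCGGTATAGGGCGTCATTTAAGTGGTACCAGCAACCTCCGAAAGCAACCGCAGAATA
CGTCTCGCTTTCTGGGGATAAAACACGGTTAATGCGGAAGAGAGGAACACTCATTAGTAG
ACCACTAAGCAGTTCGCTACACTGAGGACCGGAGAGGGAGTCGCGTATTTTTAAGTGGGA
AGTTATCTCGCTACCAGTCCTCGACATCACTGACGGTTTCTCCTGATCTAGGACGAATGA
GGCTAGCCACTTCCGCGCTGGTAATATTACGTGCTGTTCGGTTCACCCCCCAAATCGGGT
AACGCATGCCGAAACCATGTCCTACACTCTCGACACACGGATTTAACCCTTAATATTCAG
ACTCCATAGAACTTGGGTGTACCTGGAGGAGCCTTATTAGAATAAGTTCGATTGCTTCGT
TCATCAATTAGCTCGGGCGGGAGGTGCTTGTTCGGTTCGACCGCCTGACCCTCTCGCGAA
TATTTCCTGTATTTCGCCAGCGGTAATCTATACAAGAAGGTGCTCCCATTCTGCATATTA
AATTGATAGATGGCGGAAGGATGCGCGCTATATCTCCGGGCCGTGCACGAGCAAACATTA
TTGCACCAATACCCATCTTACAAGATCGGCGATCAACAAGATTATATAGTCCCACCATAC
AGCGTGTCGAAACCAGGCTGAGTTCGGACATGATATCACCACACTTTCCTGATTCTTGCA
TGCCCGGAAAAGAGTAGGCTAACATCGCCCGTATACCCCGGAGCGCCGGATTCGAAAGGT
GTTCTCACTCAGGCGCACCTTCTAATCCACGGGCGAGGCAGTATATAAATAGCTGGTAGG
GCAGATATAATGAATTAAGTTATACATAAAGCATGATTGACGCTTGCACGAAGGCAATCT
TCTGAGTTACAATAGTTCAGCCTTGACTAGAAAAGGTCTCTTCCAGGACCTTCGTATAGG
CGTAGGCAGTACAGAGATGGCGTGGCTTTCAGGAGGGGCTAAAGATGATGAGAAAGACAT
TTACGGGATAGCGAGGCAGCGCTAGGTTTGTAATTAAGCCATCTACGAGGACATGCCCGA
GGGGTGAACTGCCATGGGGCTGACCGTAGATAAGGCGGACTGAACTGGCCTTCACCTCGC
CACAGATACGGCCTCGCCCGCCCGTACGTATTTGCATTGCCGACTAACCCGCCAAAGTTA
CTGTAATCGTCCTCGCAACTGGTTGTAAAGGATGTGAGTTTATAAGTACATCTATAGGCA
GCCTCGCGTGAACGCAGTTAGAGCCATTCGCTTCATATTGGGGTCCCATAGACTGGTGAA
TAGTTACATTATTCAGCACGTGCCGTAATTGAATATGGCTCAGGGTCATGCGGCCCCTAG
GCAAGTTGTTAAGCATAGAGAGCGTGATACCCCCCGGCTAGGGTTCACCGCAAGCCGCGG
CGGCCGGGTCCTAAAGCGTTCTACGCACTTCTCTGCGGCCAAGTGGTGCAACAGCGTTTT
AAACACGCAGGCCATATCCCGACCCTTCACTGGAGAACTGCCGAATTATTTCGCGGCAGG
GTACCGTTCCATTGGCAATATATATAGCTAACTCCTGAATCGCGGCTGTCTAGTGTTAAG
GCATCCTGACCCCTCAGCAGGGCAGCTATTGAATTCTACTAGGACCGGAGCCTGCTTTGT
TCACAGAGTTCTCGGTCCGGGGTCCGAACCTTTGTCGCTTGTATCGGTCCTTGCTACGCC
GACACAATTGAACGGGCTACAGAAGTAGGTGCTTCGATTGTTTGTAAAGCTTACTGCCGA
CTCGGTGTATCGGCACAGTGAGCACGTCCACTATCACCTTTGACCGCCCTGAACATAAAG
GAAGAATCCCGCCCCGTAGGCATCGTCTTGTGAAATACGCGTTCTCTGGCGCTTCGACCG
CCAGGCTAGAATACAATACATCTGCGGGTCAACTTGTTCCAAGAGGAGCAGTAATCTGAT
TGTACTGAAAACTCAGAAAAACAGTGACGACGCTAGGTTTCTTCACTCCGGGCTGTTTGC
GCCTACTGCCAAAGTAACGGGGGCAAGCACCCCACGCGGGAGCCATCGTAGGTGTCGCCT
AATAGGGGGGCAAACAGCAGGGTTGCCGTATACTCCTGGGCTGAGCGACACCCGAGTCTC
TACCTCTCCATAACATAGGCTAAGGAGTAAATGTTGTTGTAAGCCAGGCCGCAACCGTGA
CGTCCCAAGTGCTAATAATATCGATTTGTTCCTGTGTAGTTCGTAACCCCGGAACTCGGT
TCCGTCCTACTGATATGCTACGCACCACATCTGAAGGCTCAGGGCCCCGCCCGTACGAGA
CAGAGAGCGAAGTACCCTTGAGCCGAGGAGGGTTCTGAATGGTACCTTCTACGACTTAGA
GAATTTTATGGCCCGTACGGGTCAGCCAATTGGATGGTCCCTTTCGGGAAACGATAGCGG
TCCAGCTAACCCCAGCAATACTATGCCCGACGAGTGGTAGTGGAGTGATCCTTAACTGGT
CGGCTGCGAGGTACACCTTTATATACTGGGGTTGTAAAATTGGGAGCTAAATAGAATGTC
TTCGGTTCGATGGCATCGAATTCTTGCTAAAATGCGACTTTTGAACGAATCCTGACTAAT
CTGAACGACTGTCCCAGTTCGAACTGCTGCGAAGCACGCGGGATCGCCATGGCTTACTAG
GCTTTTGCTCGCACGACACCCGTGGGTAATGAGGCTCAAGGCTTCCCGACCAAGGGGATA
TCAGGGAGATAGCGCCTTTTGGGAGGCGTGGGTAGTAGCCTGCTGGGAGGTTTGACCTGT
GTGGTATAGGAATAAAAATTGTTAGACGGAGGGAAATACGCCGTGGCGGTTTCGGCGTTT
GGTGACGGTTGAATTGCCTTTGGCCGCTCAATATCGATGCAAGTTCTTGGGCAATCAGAA
ACTAGCGCTACCAACCTAATTAAACTGATTGGCGAATAGTTAAGCTTCACCTGCCAATTA
GTGACTGGAAGTACGTTGCGGAGACTATTCATGCCTAGTCCCATCTTCCAGGTCTCGCAA
CACTCTGGTCCCCTGTCTCCCAGCACAAGTCCTGTTTCGGGGAAGATGCGCGTTATCAAG
GGTCTCCAGAAAGACCTGTCCTAGCCTTATTGTGAATATATCCACGAAGATACGGTGGTC
GAGTCGGCGAAGCAAATTTAGCATAAGACACAACAGCTCGCCGTCCGCACTATGTAGAAA
GTAATAATGGGTAGAGGCCAAAAGACTACCGTGTATGCGATGGTCAGTTCCACCACTCTC
GATCTTATTAACGACCCTACCGTCAAGTAGACGGCACGCACTCCATAGTGCTTTCTGAGT
AAATTATTGCCAATAGATTATATCACCAAGGGTCGATCAATGTAACTGTGGACGTCAATC
CGGCCCATAGTATTGACAAGGGCGCCATGTTATGGTGCTTAGATCTAATTGCGGAGCTCC
TCATACTTGCGGCCGGCCGGACAGTGGCATACCTCTCTACATCGTACGCTGGACGAATGT
GTAGCTACCCCGTCCGTGCATCCCTTTCCTTGGCTAATAATCACCAAAGGAACGGGATGA
ATAACGAAGCGCACACACCTCGGAATTAGACCCGACCACGCGTCACGTGTCCATAGCACA
TAACGTTTTATGGATTATGAAGCAGTCGAGACAAATAGTTGCTAACGCAAGGGCATATGC
TCAATTTGTCTACGCGGCGGAATACAACTCACCATCGTGGTCGCATGAGTCGTAGGCGCC
GTGACTTTGTAATCACATTAAGGGATCGCCCAATTTCGGATTTAAGCTGTACTAGTAAGA
AATGCCAACTCCACCCAGTCGGTGTGCTTCAAATGGAGTACCACCGGCTCATGTTAGGTC
TGAGTACGTGACCTGAGCGGTTTCTAAGCCCACTCGCGCAACGAAGGGGTGAGGTAGATT
TGGCGGTCTGACCCTACGGCGCAGTCTTTTATCCGGGGCCTTCTTTACGAAACCTAATCA
TACTGCTTAATCACTCACCCATCTGATGAAACTTCCTCGTAGCCATGGAACCATAAAACT
TTAGCCCGGGGAAAGCATTTGATTCCGTTAAGGTGTGACTTGCTCGTGTGTCTCGAGCTC
ACCATTAGAATGCATCGCGATTGCTGAACACATATTCGTCAAGCCTATGCGAACACCGGC
GGTACCACGGGCGAGAGATTACGTGGATGATGGAGTTACAGTACTTACTAAAAGACAACT
GTGTCATCTGTGGACTTGGCTACGAAGGTTGGGCAATGACCCGATTCGCTGCTATGGCTG
GGGTCCCTCACCGGCCGAAGTGGCACAAATCGCGCGACCTCCGATTATAATTCCCAGGAC
TACTACTTGGGACAGATGAATACGAACCTGGCGATCCTGC
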