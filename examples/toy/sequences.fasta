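>bac0000|human
GCAGGTGTTCTCGATCTCACAGACGTAGCAGCCATCAAATGGACAATACCCAACGGGCGGAAATATGTCGACTCTTCTATGGCCTGGTTG
>bac0000|mouse
GCGGGTGTTCTCGACCTCACAGACGTAGCGGCCATCAAGTGGAAGATGCCCAACGGGCGCAAATATGTTGACTCATCTATGGCCTGGTTG
>bac0000|rat
GCGGGAGTTCTCGACCTCACAGACGTAGCGGCCATCAAGTGGAAGATGCCCAACGGGCGCAAATATGTTGACTCATCTATGGCCTGGTTG
>bac0000|cow
GTAGGTGTTCTCGATTTCACAGACGTAGCTGCCATCAAGTGGAAGATGCCCAACGGCCGCAAATATGTTGACTCTTCTATGGCCTGGCTG
>bac0001|human
AGGTGCTACTCTCACCCTACTCTATGGTATAATAGCCCCACATGCGCGTCATCCTTCACCGCTGGCACCTTCTTTGCATTCACAAATAAG
>bac0001|mouse
AAGTTCTACTCCCACCCTACTCTCTGGTACAACGGCCCCACATGCGCATCGTCCTTCACTGCCGGAACCTTCTTTGCATTCACGAATAAG
>bac0001|rat
AAGTTCTACTCCCACCCTACTCTCTGGTACAACGGCCCCACATGCGCATCGTCCTTCACTGCCGGCACCTTCTTTGCATTCACGAATAAG
>bac0001|cow
AAGTGCTACTCTCACCCTACGCTCTGGTACAACGGGCCAACTTGCGCTTCATCTTTTACTGCCGGCACCTTCTTCGCATTTACAAATAAA
>mat0000|human
CCCTGTGTTTTGTGTAGCCCCTGTAATCTAGCTACCTCCTCCGGCCTTTACCTACTCTGGCTAGGTCGCATCTTCGCTTGGCGCGGGCCG
>mat0000|mouse
CCGTGCATCTTGTGTAGCCCCTGTAATCTGGCGACCTCCTCCGGTCTGTATCTACTCTGGCTAGGGCGCACCTTTGCTTGGCGCGGGTCA
>mat0000|rat
GCGTGCATCTTGTGTAGCCCCTGTAATCTGGCGACCTCCTCTGGTCTTTATCTACTCTGGCTAGGCCGCACCTTTGCTTGGCGCGGCTCA
>mat0000|cow
CCCTGCATCTTATGTAGGCCCTGTAATCTGGCGGCCGCCTCCGGTCCTTATCTACTCTGGCTGGGCCGCACTTTCGCTTGTAGCGGGCCA
>mat0001|human
ATCGTAATCCACATTCACATACCGCGCGCCTTAACCCCAGCGTGCTGTCACGGAAACTACCGCGTTCCTCGCCAAGCGTACCTCGAACTA
>mat0001|mouse
ATCGTAATCTATATTCACATTCCGCGTGCCTTGATCCCACCGTACTGTCACGGTAACTATCGCGTGCCCCGCCAAGCTTACCTCGAACTA
>mat0001|rat
ATCGTAATCTATATTCACATCCCGCGTGCCTTGATCCCACCGTACTGTCACGGTAACTATCGCGTTCCCCGCCAAGCTTACCTCGAACTG
>mat0001|cow
ATTGTCATACATATCCACATCCCGCGTGCCCTAACCCCACCGTACTGTCACGGTAACAATCACGTTCCCCGCCAAGCGTACCTCGGACTG
>pat0000|human
GCTATGTTTAGCCGCCGGGACAACTTTGTATGCGTCGTCTCGAGTTTAATCTGTTTGTGGACCGTGAATGCTGCTGGCCAGCCCACCCCT
>pat0000|mouse
GCTATGTTTAGCCGCCGGGACAACTTTGTGTGTGTCGTCTCGAGTTTGCTTTGTTTGTGGAGAGTGAATACTGCAGGCCAACCCACCCCA
>pat0000|rat
GCTATGTTTAGCCGCCGGGACAACTTTGTGTGTGTCGTCTCGAGTTTGCTTTGTTTGTGGAGAGTGAATACTGCAGGCCAACCCACCCCA
>pat0000|cow
GCTATGTTTAGTCGTAGGGATAACTTTGTATGTGTGGTCTCGAGTTTGCTTTGTTTGTGGAGAGTGAATGCAGCGGGCCAGCCCACCCAT
>pat0001|human
GAACGCGGGATCGCAAATTGCCGTCAGAATAGGCAAATACATCAATTCTCTTTGGCGCAGACGAACTCTCGCACCACCCCACACGGCCAC
>pat0001|mouse
GAACGCGGGATCGCCAATTGCCGCCAGAACAGGCAAATACATCAATTCTCTTTGGCGCAGACTAGCTCTCGCACCACCCCCCATGACAAC
>pat0001|rat
GAACGCGGCATCGCCAATTGCCGCCAGAACAGGCAAATACATCAATTCTCTTTGGCGCAGACCAGCTCTCGCACCACCCCCCATGACAAC
>pat0001|cow
GAACGCGGCATTGCCAACTGCCGGCAGAACAGGCAAATACATCAATTCTCTTTGGCCCAAACCAGCTACCGCACCACCCCGCATGGTCAC
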