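>IGHV-CLAN1-SYN synthetic clan-I-like heavy-chain V segment (subset #1 archetype)
TTACCAGAGGGGGGACCCCTTCCCAGCGAAACGATTAGTCCGCTCGAAAAAAAATCAATT
CATGCTCTTACAGCGAGTAACGAAGGCCCAGAAGACGAATTGAGTTTAGTGCAGTGTGGA
ACAGCCTTCGTCTGTTTTTTGGGGCGACCGTCCCCTCGGCTTTCTAGCAGCCGGTCTGCA
TCATATTACGCGCTCTGTGCGAGA
>IGHV1-69-SYN synthetic IGHV1-69-like heavy-chain V segment (subset #6 archetype)
ATTACCGCCCGTTTTCCTGCGTCGTATACAGAATGCTTGGGTAAAACTGGATTTTCTCAG
GGTAACGAATCTATGCATAATTTAAACCCTGAATTACGTTCGAAAACTCGACATACTTGT
TTCAAAGGACGGAGTCACAATACTGTCGTTGGATTGACTTCTCTAATAATCTTAAATCGT
TATATTATAGGAAGTTGTGCGAGA
>IGHD6-19-SYN synthetic IGHD6-19-like D segment (QWL in reading frame 1)
CAATGGTTA
>IGHD3-16-SYN synthetic IGHD3-16-like D segment (YYDYVWGSY in reading frame 2)
GTATTATGATTACGTTTGGGGGAGTTAT
>IGHJ4-SYN synthetic IGHJ4-like J segment (FDYW GQGTLVTVSS)
TTTGACTACTGGGGCCAAGGGACCCTGGTCACCGTCTCTTCA
>IGHJ3-SYN synthetic IGHJ3-like J segment (AFDIW GQGTMVTVSS)
GCTTTTGATATCTGGGGCCAAGGGACAATGGTCACCGTCTCTTCA
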