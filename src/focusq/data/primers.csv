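gene,direction,sequence
IFNB1,F,CTTGGATTCCTACAAAGAAGCAGC
IFNB1,R,TCCTCCTTCTGGAACTGCTGCA
IFIT3,F,CGGAACAGCAGAGACACAGA
IFIT3,R,CGGAACAGCAGAGACACAGA
TNF,F,CTCTTCTGCCTGCTGCACTTTG
TNF,R,ATGGGCTACAGGCTTGTCACTC
TNFAIP3,F,GAAGCTTGTGGCGCTGAAAA
TNFAIP3,R,GAACGCCCCACATGTACTGA
ACTB,F,GCACTCTTCCAGCCTTCCTT
ACTB,R,AATGCCAGGGTACATGGTGG
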