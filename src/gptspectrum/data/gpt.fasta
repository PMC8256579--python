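>gpt Escherichia coli xanthine-guanine phosphoribosyltransferase CDS (lambda EG10 reporter)
ATGAGCGAAAAATACATCGTCACCTGGGACATGTTGCAGATCCATGCACGTAAACTCGCA
AGCCGACTGATGCCTTCTGAACAATGGAAAGGCATTATTGCCGTAAGCCGTGGCGGTCTG
GTACCGGGTGCGTTACTGGCGCGTGAACTGGGTATTCGTCATGTCGATACCGTTTGTATT
TCCAGCTACGATCACGACAACCAGCGCGAGCTTAAAGTGCTGAAACGCGCAGAAGGCGAT
GGCGAAGGCTTCATCGTTATTGATGACCTGGTGGATACCGGTGGTACTGCGGTTGCGATT
CGTGAAATGTATCCAAAAGCGCACTTTGTCACCATCTTCGCAAAACCGGCTGGTCGTCCG
CTGGTTGATGACTATGTTGTTGATATCCCGCAAGATACCTGGATTGAACAGCCGTGGGAT
ATGGGCGTCGTATTCGTCCCGCCAATCTCCGGTCGCTAA
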