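>KJ737374
GAACTTTATATTTTTTATTTGGAATTTGATCAGGACTAATTGGTTCTTCACTAAGAATTTTAATTCGATT
AGAATTAAGACAAATTAATTCAATCATTAATAATAATCAATTATATAATGTTATCATTACAATTCATGCA
TTTATTATAATTTTTTTTATAACTATACCAATTGTAATTGGTGGATTTGGAAATTGATTAATCCCTTTAA
TAATAGGATGCCCTGATATATCATTCCCACGATTAAATAATATTAGATTTTGAATACTTCCACCAGCATT
AATATTTATAATTATAAGTTTTATAATTAATAATGGAACAGGAACAGGATGAACAATTTACCCCCCTCTA
TCTAACAATATTGCCCATAATAATATTTCTGTTGACTTAACAATTTTTTCTCTACATTTAGCAGGAATCT
CATCAATTTTAGGAGCAATCAATTTTATTTGCACAATTATAAATATAATACCTAATAATATAAAAATTAA
TCAAATTCCTCTTTTCCCTTGATCTATTTTAATTACAGCAATCTTATTAATTTTATCTTTACCTGTATTA
GCAGGTGCAATTACTATACTTTTAACTGATCGAAATCTTAATACTTCATTTTTTGATCCTTCAGGAGGTG
GAGACCCTATCTTGTATCAACA
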