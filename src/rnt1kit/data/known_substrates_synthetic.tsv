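name	sequence	loop_start
SYN01	CCGATTGCATTAGAACAGATGTTCTAATCAAATCGG	16
SYN02	ACGCTTGCAACAGATTAGATAATCTGTTGCAAGCTT	16
SYN03	GCGATTCCATCCGATTAGATAATCGGATGGAATCGC	16
SYN04	CCGTTTACATCACGTGAGATCACGTGATGTAAACGG	16
SYN05	TCGACTGCACCATATTAGATAATATGGTAGAGTCGA	16
SYN06	CCTAGTACACCATATTAGATAATATGGTGTACTACG	16
SYN07	ACGAATGCATCATATTAGATAATATGATGCATTCGT	16
SYN08	AACCTTGCTTCACATTAGGTAATGTGAAGCAAGGTT	16
SYN09	ACGGTGGCAACAGATTAGGTAATCTGTTCACACCGT	16
SYN10	ACGATTGCAGCACAACAGGTGTTGTGCTGCAATCTT	16
SYN11	TCGATAGCATCGGTTTAGGTAAACCGATGCTATCGA	16
SYN12	ACAGTAATATCGAAGTAGGTACTTCGATATTACTGT	16
SYN13	ACGATCTCACCAGCTTAGGTAAGCTGGTTTGATCGT	16
SYN14	TCAGTCGCATCAGATTAGGTAATCTGATGCGACTCA	16
SYN15	TAGACTGCGTCGATTGAGTTCAATCGACGCAGTCTA	16
SYN16	ACGAGTGCAACAGCACAGTTGTGCTGTTGCACTCGT	16
SYN17	TAGATTACAGAAAATAAGTATATTTTCTCAAATCTA	16
SYN18	ACGATTGGATCAGATTAGTAAATCTGATCCAATCCT	16
SYN19	TCGGCTGCATCGGCTTAGTCAAGCCGATGCAGCCGA	16
SYN20	AGAATTGCATAAGAATAGTCATTCTTATGCAATTCT	16
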