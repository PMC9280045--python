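name	iupac	category
ARE	AAACCA	stress
MYC	CANNTG	stress
MYB	CAACTG	stress
LTR	CCGAAA	stress
ABRE	ACGTGKC	hormone
TCA	CCATCTTTTT	hormone
G-box	CACGTG	growth
GT1	GAAAAA	growth
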